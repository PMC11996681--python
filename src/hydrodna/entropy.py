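"""Solvent and solute entropy estimators.

Waters
------
Each permuted water site gets a *first-order translational* entropy: the
Schlitter formula applied to the 3x3 positional covariance of its oxygen
track with the mass of one water molecule,

    s = (R/2) ln det[ I + (k_B T e^2 / hbar^2) m Sigma ]   [J K^-1 mol^-1].

This is a quasi-harmonic proxy that orders sites by positional
restraint; it omits rotational terms and water-water correlations, so
absolute values are comparable only within the proxy's own scale.  The
interface bookkeeping then reads

    dS_solv = N (S_avg - S_bulk),

with N the number of interfacial waters, S_avg their mean entropy and
S_bulk a bulk-water reference (default 118 J K^-1 mol^-1; recompute it
from bulk waters of the same estimator when comparing magnitudes).

Solute
------
Schlitter's upper bound on conformational entropy from the mass-weighted
3N x 3N covariance of a least-squares-superposed selection, plus
residue-averaged RMSF profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import constants
from .permutation import PermutedWaterTrajectory
from .trajectory import Selection, Trajectory, TrajectoryError


@dataclass
class PerWaterEntropy:
    site_label: int
    s_trans: float                    # J K^-1 mol^-1
    covariance_eigenvalues: tuple[float, float, float]  # A^2
    n_frames: int
    degenerate: bool = False          # rank-deficient (pinned) covariance


@dataclass
class InterfaceEntropySummary:
    N: int
    S_avg: float | None
    S_total: float
    S_bulk: float
    delta_S_solv: float

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "S_avg": self.S_avg,
            "S_total": self.S_total,
            "S_bulk": self.S_bulk,
            "delta_S_solv": self.delta_S_solv,
        }


@dataclass
class SoluteEntropyReport:
    schlitter_upper_bound: float      # J K^-1 mol^-1
    temperature: float                # K
    atom_set: str
    n_frames: int
    insufficient_sampling: bool = False


def _schlitter_factor(temperature: float) -> float:
    """k_B T e^2 / hbar^2 in 1/(kg m^2)."""
    return (constants.BOLTZMANN_J_PER_K * temperature * constants.EULER_E ** 2
            / constants.PLANCK_HBAR_J_S ** 2)


def schlitter_from_covariance(cov_A2: np.ndarray, masses_u: np.ndarray,
                              temperature: float) -> float:
    """Schlitter entropy (J K^-1 mol^-1) from a 3N x 3N positional
    covariance in A^2 and per-atom masses in u (each mass enters three
    Cartesian components)."""
    cov = np.asarray(cov_A2, dtype=float) * constants.ANGSTROM_M ** 2
    m = np.repeat(np.asarray(masses_u, dtype=float), 3) * constants.ATOMIC_MASS_KG
    if cov.shape != (m.size, m.size):
        raise TrajectoryError(
            f"covariance shape {cov.shape} does not match {m.size} coordinates"
        )
    sqrt_m = np.sqrt(m)
    weighted = _schlitter_factor(temperature) * (sqrt_m[:, None] * cov * sqrt_m[None, :])
    sign, logdet = np.linalg.slogdet(np.eye(m.size) + weighted)
    if sign <= 0:
        raise TrajectoryError("mass-weighted covariance is not positive semi-definite")
    return 0.5 * constants.GAS_CONSTANT_J_PER_K_MOL * logdet


def per_water_entropy(
    permuted: PermutedWaterTrajectory,
    temperature: float = constants.TEMPERATURE_K,
    mass_u: float = constants.WATER_MASS_U,
) -> list[PerWaterEntropy]:
    """First-order translational entropy of every permuted water site.

    A rank-deficient (zero-variance) covariance is flagged degenerate;
    its determinant term is 1 along the pinned axes, so a fully pinned
    site reports exactly 0.
    """
    pos = permuted.site_positions  # (F, S, 3)
    n_frames = pos.shape[0]
    if n_frames < 2:
        raise TrajectoryError("per-water entropy needs at least 2 frames")
    out: list[PerWaterEntropy] = []
    for s in range(pos.shape[1]):
        x = pos[:, s, :]
        cov = np.cov(x.T, ddof=0) if n_frames > 1 else np.zeros((3, 3))
        cov = np.atleast_2d(cov)
        eig = np.linalg.eigvalsh(cov)
        eig = np.clip(eig, 0.0, None)
        degenerate = bool(np.any(eig <= 1e-12))
        s_trans = schlitter_from_covariance(cov, np.array([mass_u]), temperature)
        out.append(PerWaterEntropy(
            site_label=s,
            s_trans=float(s_trans),
            covariance_eigenvalues=tuple(float(e) for e in eig),
            n_frames=n_frames,
            degenerate=degenerate,
        ))
    return out


def interface_entropy_summary(
    entropies: list[PerWaterEntropy],
    interfacial: set[int],
    s_bulk: float = constants.S_BULK_J_PER_K_MOL,
) -> InterfaceEntropySummary:
    """Interface bookkeeping: N, S_avg, S_total = N*S_avg and
    dS_solv = N*(S_avg - s_bulk).  An empty interface yields N=0,
    S_avg undefined and dS_solv = 0."""
    by_site = {e.site_label: e for e in entropies}
    if not set(interfacial) <= set(by_site):
        raise TrajectoryError("interfacial set contains sites without entropies")
    n = len(interfacial)
    if n == 0:
        return InterfaceEntropySummary(N=0, S_avg=None, S_total=0.0,
                                       S_bulk=s_bulk, delta_S_solv=0.0)
    s_avg = float(np.mean([by_site[s].s_trans for s in interfacial]))
    return InterfaceEntropySummary(
        N=n,
        S_avg=s_avg,
        S_total=n * s_avg,
        S_bulk=s_bulk,
        delta_S_solv=n * (s_avg - s_bulk),
    )


# ---------------------------------------------------------------------------
# superposition and solute entropy
# ---------------------------------------------------------------------------

def _kabsch_fit(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``target`` (rotation +
    translation only); returns the transformed coordinates."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(mobile - mc) + tc


def superpose_frames(traj: Trajectory, selection: Selection,
                     fit_heavy_only: bool = True) -> np.ndarray:
    """Superpose every frame's selection onto the selection mean structure.

    The fit uses heavy atoms of the selection (configurable); the
    returned array is the full selection, shape (n_frames, n_sel, 3).
    Two passes: fit to the first frame, then refit to the resulting mean.
    """
    sel = selection.as_array()
    atoms = traj.topology.atoms
    if fit_heavy_only:
        fit_mask = np.array([not atoms[i].is_hydrogen for i in sel])
        if not fit_mask.any():
            fit_mask = np.ones(len(sel), dtype=bool)
    else:
        fit_mask = np.ones(len(sel), dtype=bool)
    coords = traj.coordinates()[:, sel, :]
    target = coords[0][fit_mask]
    for _pass in range(2):
        fitted = np.empty_like(coords)
        for f in range(coords.shape[0]):
            mob = coords[f]
            mc = mob[fit_mask].mean(axis=0)
            tc = target.mean(axis=0)
            rot, _ = Rotation.align_vectors(target - tc, mob[fit_mask] - mc)
            fitted[f] = rot.apply(mob - mc) + tc
        target = fitted.mean(axis=0)[fit_mask]
        coords = fitted
    return coords


_DEFAULT_MASSES_U = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "CL": 35.45, "MG": 24.305, "K": 39.098,
}


def atom_masses(traj: Trajectory, selection: Selection) -> np.ndarray:
    return np.array([
        _DEFAULT_MASSES_U.get(traj.topology.atoms[i].element, 12.011)
        for i in selection.as_array()
    ])


def schlitter_entropy(
    traj: Trajectory,
    atoms: Selection,
    temperature: float = constants.TEMPERATURE_K,
    masses_u: np.ndarray | None = None,
    superpose: bool = True,
) -> SoluteEntropyReport:
    """Schlitter upper bound on the conformational entropy of a selection.

    Frames are least-squares superposed onto the selection's mean
    structure before the covariance is formed (set ``superpose=False``
    for pre-aligned or toy inputs).  Fewer than 3x the atom count of
    frames flags the report as under-sampled.
    """
    if traj.n_frames < 2:
        raise TrajectoryError("Schlitter entropy needs at least 2 frames")
    if temperature <= 0:
        raise TrajectoryError("temperature must be positive")
    sel = atoms.as_array()
    if sel.size == 0:
        raise TrajectoryError("empty selection")
    coords = (superpose_frames(traj, atoms) if superpose
              else traj.coordinates()[:, sel, :])
    flat = coords.reshape(traj.n_frames, -1)
    cov = np.cov(flat.T, ddof=0)
    cov = np.atleast_2d(cov)
    if masses_u is None:
        masses_u = atom_masses(traj, atoms)
    s = schlitter_from_covariance(cov, masses_u, temperature)
    return SoluteEntropyReport(
        schlitter_upper_bound=float(s),
        temperature=temperature,
        atom_set=atoms.label,
        n_frames=traj.n_frames,
        insufficient_sampling=traj.n_frames < 3 * sel.size,
    )


_PROTEIN_MAIN_CHAIN = {"N", "CA", "C", "O"}
_DNA_BACKBONE = {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"}


def residue_rmsf(
    traj: Trajectory,
    selection: Selection,
    superpose: bool = True,
) -> list[dict]:
    """Residue-averaged RMSF after rigid-body superposition.

    Per-atom RMSF values are averaged within each residue, reported for
    all atoms and for the main-chain/backbone subset (protein N/CA/C/O,
    DNA phosphate-sugar atoms).
    """
    sel = selection.as_array()
    coords = (superpose_frames(traj, selection) if superpose
              else traj.coordinates()[:, sel, :])
    mean = coords.mean(axis=0)
    atom_rmsf = np.sqrt(((coords - mean) ** 2).sum(axis=-1).mean(axis=0))
    per_res: dict[tuple, dict] = {}
    for local_i, atom_i in enumerate(sel):
        rec = traj.topology.atoms[atom_i]
        entry = per_res.setdefault(rec.residue_key(), {"all": [], "main": []})
        entry["all"].append(atom_rmsf[local_i])
        backbone = (_PROTEIN_MAIN_CHAIN if rec.entity_class.value == "protein"
                    else _DNA_BACKBONE)
        if rec.atom_name in backbone:
            entry["main"].append(atom_rmsf[local_i])
    rows = []
    for (chain, seq, name), entry in sorted(per_res.items(),
                                            key=lambda kv: (kv[0][0], kv[0][1])):
        rows.append({
            "chain": chain,
            "residue_seq": seq,
            "residue_name": name,
            "rmsf_all_A": float(np.mean(entry["all"])),
            "rmsf_main_A": float(np.mean(entry["main"])) if entry["main"] else None,
            "n_atoms": len(entry["all"]),
        })
    return rows
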