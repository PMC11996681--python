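"""Synthetic complexes, trajectories and SELEX pools with planted truth.

These generators emulate the *statistical* structure the analysis
assumes, not the physics that produces it:

* a scaffold protein-DNA complex with water sites planted in three
  classes - pinned interfacial (tight Gaussians in the protein-DNA
  gap), pinned distal (tight Gaussians behind the protein) and bulk
  (resampled uniformly in the box each frame, i.e. memoryless rather
  than diffusing);
* frame-to-frame scrambling of water storage order, exercising the
  permutation-reduction stage with a known ground-truth relabeling;
* exact-geometry hydrogen-bond chains for bridge detection;
* SELEX read pools evolved by selection proportional to planted k-mer
  affinities, with expected fold changes computed analytically from the
  weights.

Every generator is deterministic for a given seed and returns its
ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants
from .selex import ReadPool, reverse_complement
from .trajectory import (AtomRecord, EntityClass, Frame, Selection, Topology,
                         Trajectory, TrajectoryError, WaterMolecule)

# scaffold geometry (A): protein contact plane and DNA axis flank the
# water gap symmetrically so a gap-centre water is within 4 A of both.
_PROTEIN_PLANE_X = -3.4
_DNA_AXIS_X = 3.4
_SITE_SPACING = 4.0       # >= 3x pinned sigma for clean label recovery
_PROTEIN_Z_STEP = 2.0
_DNA_Z_STEP = 1.7
_DISTAL_X = -9.4          # pinned but far from DNA
_MIN_PACKING = 2.4


@dataclass
class WaterGroundTruth:
    classes: list[str]            # per site: pinned_interfacial | pinned_noninterfacial | bulk
    sigma: np.ndarray             # per site per-axis generative sigma (A); nan for bulk
    centers: np.ndarray           # per site true centre (A); nan for bulk
    storage_to_site: np.ndarray | None = None   # (n_frames, n_waters) int
    box_lo: np.ndarray | None = None            # solvent region for bulk resampling
    box_lengths: np.ndarray | None = None

    def sites_of_class(self, cls: str) -> set[int]:
        return {i for i, c in enumerate(self.classes) if c == cls}


def make_scaffold_complex(
    n_protein: int = 60,
    n_dna: int = 40,
    n_interfacial_waters: int = 12,
    n_distal_waters: int = 0,
    n_bulk_waters: int = 50,
    seed: int = 0,
) -> tuple[Topology, Frame, WaterGroundTruth]:
    """Deterministic scaffold: a protein contact plane, a linear DNA
    axis ~7 A away and water sites planted in the gap, behind the
    protein, and in bulk.

    Interfacial site centres are within 4 A (hence also 5 A) of both a
    protein and a DNA atom by construction; an interfacial request that
    outruns the solute extent raises a geometric-infeasibility error.
    """
    if min(n_protein, n_dna, n_interfacial_waters, n_bulk_waters, n_distal_waters) < 0:
        raise TrajectoryError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    positions: list[tuple[float, float, float]] = []

    protein_z = (n_protein // 2) * _PROTEIN_Z_STEP
    dna_z = n_dna * _DNA_Z_STEP
    need_z = max(n_interfacial_waters - 1, 0) * _SITE_SPACING
    if n_interfacial_waters and (need_z > protein_z or need_z > dna_z):
        raise TrajectoryError(
            f"{n_interfacial_waters} interfacial sites need {need_z:.0f} A of "
            f"interface but solute spans only {min(protein_z, dna_z):.0f} A"
        )

    def add_atom(name, element, resname, resseq, chain, cls, pos):
        atoms.append(AtomRecord(
            atom_index=len(atoms), atom_name=name, element=element,
            residue_name=resname, residue_seq=resseq, chain_id=chain,
            entity_class=cls,
        ))
        positions.append(pos)

    prot_elements = ["C", "N", "O", "C"]
    for i in range(n_protein):
        z = (i // 2) * _PROTEIN_Z_STEP
        y = -1.5 if i % 2 == 0 else 1.5
        add_atom("CA" if i % 2 == 0 else "CB", prot_elements[i % 4], "GLY",
                 i // 2 + 1, "A", EntityClass.PROTEIN, (_PROTEIN_PLANE_X, y, z))
    dna_elements = ["P", "O", "C", "N"]
    for i in range(n_dna):
        add_atom("P" if i % 4 == 0 else f"C{i % 4}'", dna_elements[i % 4],
                 "DA", i // 4 + 1, "B", EntityClass.DNA,
                 (_DNA_AXIS_X, 0.0, i * _DNA_Z_STEP))

    classes: list[str] = []
    centers: list[tuple[float, float, float]] = []
    for i in range(n_interfacial_waters):
        centers.append((0.0, 0.0, i * _SITE_SPACING))
        classes.append("pinned_interfacial")
    for i in range(n_distal_waters):
        centers.append((_DISTAL_X, 0.0, i * _SITE_SPACING))
        classes.append("pinned_noninterfacial")

    z_max = max(protein_z, dna_z)
    box = (40.0, 30.0, z_max + 20.0)
    lo = np.array([-20.0, -15.0, -10.0])
    for _ in range(n_bulk_waters):
        while True:
            p = lo + rng.random(3) * np.array(box)
            # keep bulk starting points clear of the planted sites
            if not centers or np.min(np.linalg.norm(
                    np.array(centers) - p, axis=1)) > _MIN_PACKING:
                break
        centers.append(tuple(p))
        classes.append("bulk")

    for wi, c in enumerate(centers):
        add_atom("O", "O", "HOH", wi + 1, "W", EntityClass.WATER, c)

    waters = [WaterMolecule(a.atom_index, ())
              for a in atoms if a.entity_class is EntityClass.WATER]
    topology = Topology(atoms, waters, box=None)
    frame = Frame(np.array(positions), 0)
    sigma = np.full(len(classes), np.nan)
    truth = WaterGroundTruth(
        classes=classes,
        sigma=sigma,
        centers=np.array(centers, dtype=float),
        box_lo=lo,
        box_lengths=np.array(box),
    )
    return topology, frame, truth


def simulate_water_trajectory(
    topology: Topology,
    reference: Frame,
    truth: WaterGroundTruth,
    n_frames: int = 2000,
    pinned_sigma: float = 0.3,
    scramble_labels: bool = False,
    solute_jitter: float = 0.0,
    seed: int = 0,
) -> tuple[Trajectory, WaterGroundTruth]:
    """Sample a trajectory over the scaffold.

    Pinned waters are drawn i.i.d. Gaussian (per-axis ``pinned_sigma``)
    about their centres; bulk waters are resampled uniformly in the
    solvent box every frame; solute atoms are fixed or given Gaussian
    jitter.  With ``scramble_labels`` the water storage order is
    randomly permuted per frame and the ground-truth mapping recorded.
    """
    if n_frames < 2:
        raise TrajectoryError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    water_idx = topology.water_oxygen_indices()
    n_w = len(water_idx)
    if n_w != len(truth.classes):
        raise TrajectoryError("ground truth does not match topology waters")
    solute_idx = np.array([a.atom_index for a in topology.atoms
                           if a.entity_class is not EntityClass.WATER], dtype=int)
    pinned = np.array([c.startswith("pinned") for c in truth.classes])
    sigma = np.where(pinned, pinned_sigma, np.nan)
    lo = truth.box_lo if truth.box_lo is not None else np.array([-20.0, -15.0, -10.0])
    lengths = (truth.box_lengths if truth.box_lengths is not None
               else np.array([40.0, 30.0, 40.0]))

    # solvent region = box minus the excluded volume of solute atoms and
    # occupied hydration sites (waters cannot interpenetrate them)
    occupied = [reference.positions[solute_idx]] if solute_idx.size else []
    if pinned.any():
        occupied.append(truth.centers[pinned])
    from scipy.spatial import cKDTree
    excl_tree = cKDTree(np.vstack(occupied)) if occupied else None

    def sample_bulk(n: int) -> np.ndarray:
        pts = lo + rng.random((n, 3)) * lengths
        if excl_tree is not None:
            for _ in range(100):
                d, _i = excl_tree.query(pts, k=1)
                bad = d < _MIN_PACKING
                if not bad.any():
                    break
                pts[bad] = lo + rng.random((int(bad.sum()), 3)) * lengths
        return pts

    frames: list[Frame] = []
    storage_to_site = np.empty((n_frames, n_w), dtype=int)
    for f in range(n_frames):
        pos = reference.positions.copy()
        if solute_jitter > 0 and solute_idx.size:
            pos[solute_idx] += rng.normal(0.0, solute_jitter,
                                          (solute_idx.size, 3))
        site_pos = np.empty((n_w, 3))
        site_pos[pinned] = (truth.centers[pinned]
                            + rng.normal(0.0, pinned_sigma,
                                         (int(pinned.sum()), 3)))
        n_bulk = int((~pinned).sum())
        if n_bulk:
            site_pos[~pinned] = sample_bulk(n_bulk)
        perm = rng.permutation(n_w) if scramble_labels else np.arange(n_w)
        # storage slot j holds the water of true site perm[j]
        pos[water_idx] = site_pos[perm]
        storage_to_site[f] = perm
        frames.append(Frame(pos, f))

    out_truth = WaterGroundTruth(
        classes=list(truth.classes),
        sigma=sigma,
        centers=truth.centers.copy(),
        storage_to_site=storage_to_site,
        box_lo=truth.box_lo,
        box_lengths=truth.box_lengths,
    )
    return Trajectory(topology, frames), out_truth


def label_recovery(permutations: np.ndarray, truth: WaterGroundTruth,
                   sites: set[int] | None = None) -> float:
    """Fraction of (site, frame) pairs where the permuted label tracks
    the same ground-truth site as it did in the first frame."""
    if truth.storage_to_site is None:
        raise TrajectoryError("ground truth carries no storage mapping")
    gt = truth.storage_to_site
    anchor = gt[0][permutations[0]]        # true site behind each label at t=0
    mask = np.ones(anchor.shape, dtype=bool)
    if sites is not None:
        mask = np.isin(anchor, list(sites))
    hits = 0
    total = 0
    for f in range(permutations.shape[0]):
        current = gt[f][permutations[f]]
        hits += int((current[mask] == anchor[mask]).sum())
        total += int(mask.sum())
    return hits / total


# ---------------------------------------------------------------------------
# hydrogen-bond bridge fixtures
# ---------------------------------------------------------------------------

def _bridge_hydrogen_offset(bond_length: float, angle_deg: float,
                            oh: float = 0.96) -> tuple[float, float]:
    """In-plane hydrogen position (x, y) for a donor at the origin and an
    acceptor at (bond_length, 0) such that |DH| = oh and the D-H-A angle
    equals ``angle_deg`` exactly."""
    gamma = math.radians(angle_deg)
    ha = oh * math.cos(gamma) + math.sqrt(
        bond_length ** 2 - (oh * math.sin(gamma)) ** 2)
    x = (oh ** 2 - ha ** 2 + bond_length ** 2) / (2 * bond_length)
    y = math.sqrt(max(oh ** 2 - x ** 2, 0.0))
    return x, y


def make_bridge_fixture(
    order: int,
    bond_length: float = 2.8,
    angle_deg: float = 165.0,
) -> tuple[Topology, Frame, dict]:
    """Single protein donor, ``order`` chained waters and a DNA acceptor
    with every consecutive hydrogen bond at exactly the given geometry.

    Returns the topology, the frame and the expected bridge as a dict
    with keys protein_residue / nucleotide / water_chain / order.
    """
    if order not in (0, 1, 2, 3):
        raise TrajectoryError("order must be 0..3")
    hx, hy = _bridge_hydrogen_offset(bond_length, angle_deg)
    atoms: list[AtomRecord] = []
    positions: list[tuple[float, float, float]] = []

    def add_atom(name, element, resname, resseq, chain, cls, pos):
        atoms.append(AtomRecord(
            atom_index=len(atoms), atom_name=name, element=element,
            residue_name=resname, residue_seq=resseq, chain_id=chain,
            entity_class=cls,
        ))
        positions.append(pos)

    add_atom("OG", "O", "SER", 1, "A", EntityClass.PROTEIN, (0.0, 0.0, 0.0))
    add_atom("HG", "H", "SER", 1, "A", EntityClass.PROTEIN, (hx, hy, 0.0))
    for w in range(order):
        ox = (w + 1) * bond_length
        add_atom("O", "O", "HOH", w + 1, "W", EntityClass.WATER,
                 (ox, 0.0, 0.0))
        add_atom("H1", "H", "HOH", w + 1, "W", EntityClass.WATER,
                 (ox + hx, hy, 0.0))
        # spectator hydrogen pointing away from the chain
        add_atom("H2", "H", "HOH", w + 1, "W", EntityClass.WATER,
                 (ox, 0.0, 0.96))
    add_atom("N7", "N", "DA", 1, "B", EntityClass.DNA,
             ((order + 1) * bond_length, 0.0, 0.0))

    waters = []
    for a in atoms:
        if a.entity_class is EntityClass.WATER and a.element == "O":
            hs = tuple(b.atom_index for b in atoms
                       if b.entity_class is EntityClass.WATER
                       and b.is_hydrogen and b.residue_seq == a.residue_seq)
            waters.append(WaterMolecule(a.atom_index, hs))
    positions_arr = np.array(positions)
    from .trajectory import infer_bonds
    infer_bonds(atoms, positions_arr)
    topology = Topology(atoms, waters, box=None)
    frame = Frame(positions_arr, 0)
    expected = {
        "protein_residue": ("A", 1, "SER"),
        "nucleotide": ("B", 1, "DA"),
        "water_chain": tuple(range(order)),
        "order": order,
    }
    return topology, frame, expected


# ---------------------------------------------------------------------------
# SELEX pools
# ---------------------------------------------------------------------------

@dataclass
class SelexGroundTruth:
    """Planted selection weights.

    ``affinity`` maps k-mers to relative selection weights (background
    weight 1); ``temperature_model`` optionally maps a k-mer to a
    callable weight(T_celsius) that overrides ``affinity`` at a given
    temperature.  ``expected_fold_change`` is filled by the simulator:
    the exact conditional expectation of each planted k-mer's fold
    change given the realised input library.
    """
    affinity: dict[str, float]
    temperature_model: dict | None = None
    cycles: int = 1
    expected_fold_change: dict[str, float] = field(default_factory=dict)

    def weights_at(self, temperature_c: float | None) -> dict[str, float]:
        w = dict(self.affinity)
        if temperature_c is not None and self.temperature_model:
            for km, fn in self.temperature_model.items():
                w[km] = float(fn(temperature_c))
        if any(v <= 0 for v in w.values()):
            raise TrajectoryError("selection weights must be positive")
        return w


def default_two_optima_truth() -> SelexGroundTruth:
    """The study-condition landscape: an enthalpic optimum (TAAACG,
    weight 10), an entropic optimum (TAATTG, weight 8) and a few
    Hamming-1 shoulders at weight <= 4 over background 1."""
    return SelexGroundTruth(affinity={
        "TAAACG": 10.0,
        "TAATTG": 8.0,
        "TAAACA": 4.0,   # Hamming-1 shoulder of TAAACG
        "TAATTA": 3.0,   # Hamming-1 shoulder of TAATTG
    })


def default_temperature_truth() -> SelexGroundTruth:
    """Temperature series ground truth: the AC-containing optimum loses
    affinity with temperature while the TT-containing optimum is
    temperature-insensitive."""
    truth = default_two_optima_truth()
    truth.temperature_model = {
        "TAAACG": lambda t: 10.0 - 0.15 * t,   # 10 at 0 C -> 4 at 40 C
        "TAATTG": lambda t: 8.0,
    }
    return truth


def _random_reads(rng: np.random.Generator, n: int, length: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [bytes(row).decode() for row in lut[codes]]


def _read_weight(read: str, weights: dict[str, float]) -> float:
    w = 1.0
    rc = reverse_complement(read)
    for km, wk in weights.items():
        if km in read or km in rc:
            w = max(w, wk)
    return w


def simulate_selex_reads(
    truth: SelexGroundTruth,
    read_length: int = 26,
    n_reads_per_cycle: int = 100_000,
    cycles: int | None = None,
    temperature_c: float | None = None,
    seed: int = 0,
) -> tuple[list[ReadPool], SelexGroundTruth]:
    """Evolve read pools under single-hit multiplicative selection.

    Cycle 0 is a uniform random library; each following cycle resamples
    reads with probability proportional to the maximum planted weight of
    any k-mer occurrence in the read (either strand).  The returned
    ground truth carries the exact expected fold change of every planted
    k-mer after the final cycle, conditional on the realised cycle-0
    pool (selecting c times weights each read by w^c).
    """
    cycles = truth.cycles if cycles is None else cycles
    if cycles < 1:
        raise TrajectoryError("need at least one selection cycle")
    weights = truth.weights_at(temperature_c)
    rng = np.random.default_rng(seed)
    reads0 = _random_reads(rng, n_reads_per_cycle, read_length)
    condition = ({} if temperature_c is None
                 else {"temperature_C": temperature_c})
    pools = [ReadPool(reads0, cycle=0, condition=dict(condition))]

    w0 = np.array([_read_weight(r, weights) for r in reads0])
    reads = reads0
    w = w0
    for c in range(1, cycles + 1):
        p = w / w.sum()
        idx = rng.choice(len(reads), size=n_reads_per_cycle, replace=True, p=p)
        reads = [reads[i] for i in idx]
        w = w[idx]
        pools.append(ReadPool(reads, cycle=c, condition=dict(condition)))

    # exact conditional expectation: after c rounds the chance that an
    # original read survives is proportional to w^c
    wc = w0 ** cycles
    out_truth = SelexGroundTruth(
        affinity=dict(truth.affinity),
        temperature_model=truth.temperature_model,
        cycles=cycles,
    )
    k = len(next(iter(weights)))
    for km in weights:
        occ0 = np.array([r.count(km) + reverse_complement(r).count(km)
                         for r in reads0], dtype=float)
        base = occ0.sum() / n_reads_per_cycle
        if base == 0:
            continue
        expected = (wc * occ0).sum() / wc.sum()
        out_truth.expected_fold_change[km] = float(expected / base)
    return pools, out_truth
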