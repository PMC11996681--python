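"""Permutation reduction of water identities.

Water molecules are physically indistinguishable, so an MD engine's
labels carry no meaning: a label that tracks one hydration site in one
frame may sit in bulk in the next.  Permutation reduction relabels the
waters of every frame so that each label stays closest to a fixed
reference position, turning per-label statistics (mean position, RMSF,
positional covariance) into per-*site* statistics while leaving every
frame's set of coordinates untouched.

The per-frame relabeling is the linear sum assignment that minimises the
total oxygen-reference distance (Euclidean by default, optionally
squared), with gated costs so that a label keeps its in-gate occupant
rather than subsidising a long displacement of an exchanging bulk water.
References default to the initial (first-frame or crystallographic)
positions and stay fixed; an optional iterative mode re-centres each
reference on its site's assigned mean until self-consistent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .trajectory import Trajectory, TrajectoryError, pairwise_distances


class ReferenceMode(str, enum.Enum):
    FIRST_FRAME = "first_frame"
    CRYSTALLOGRAPHIC = "crystallographic"
    PROVIDED = "provided"


@dataclass
class PermutedWaterTrajectory:
    """Result of permutation reduction.

    ``permutations[f][s]`` is the water-molecule index (into
    ``topology.water_molecules``) assigned to site label ``s`` in frame
    ``f``; each row is a bijection.  ``site_positions[f, s]`` is the
    oxygen position of that water, i.e. the relabeled oxygen trajectory.
    """

    trajectory: Trajectory
    permutations: np.ndarray      # (n_frames, n_sites) int
    site_positions: np.ndarray    # (n_frames, n_sites, 3) A
    reference_positions: np.ndarray  # (n_sites, 3) A, final references
    n_iterations_used: int
    converged: bool

    @property
    def n_sites(self) -> int:
        return self.permutations.shape[1]

    @property
    def n_frames(self) -> int:
        return self.permutations.shape[0]


@dataclass
class MobilityTable:
    """Per-site mean position and RMSF from a permuted trajectory."""

    site_labels: np.ndarray       # (n_sites,) int
    mean_positions: np.ndarray    # (n_sites, 3) A
    rmsf: np.ndarray              # (n_sites,) A
    n_frames: int
    single_frame_warning: bool = False

    def to_rows(self) -> list[dict]:
        return [
            {
                "site_label": int(s),
                "mean_x": float(self.mean_positions[i, 0]),
                "mean_y": float(self.mean_positions[i, 1]),
                "mean_z": float(self.mean_positions[i, 2]),
                "rmsf_A": float(self.rmsf[i]),
                "n_frames": self.n_frames,
            }
            for i, s in enumerate(self.site_labels)
        ]


def _water_oxygen_coords(traj: Trajectory) -> np.ndarray:
    """(n_frames, n_waters, 3) oxygen coordinates in storage order."""
    ox = traj.topology.water_oxygen_indices()
    return traj.coordinates()[:, ox, :]


_GATE_PENALTY = 1.0e6


def assign_frame(oxygens: np.ndarray, references: np.ndarray,
                 box: tuple[float, float, float] | None = None,
                 cost: str = "linear",
                 gate: float | None = 2.5) -> tuple[np.ndarray, float]:
    """Optimal site->water assignment for one frame.

    Returns (assignment, total_cost): ``assignment[s]`` is the water
    index for site ``s``.  ``cost`` selects the per-pair cost as the
    Euclidean distance (``linear``, default) or its square
    (``squared``).  Linear costs obey the triangle inequality, so a
    label is never routed "through" another site's water to shorten a
    long bulk displacement - squared costs reward exactly that split and
    let freely exchanging waters steal the assignments of pinned sites.

    ``gate`` (A) adds a large constant to any pair farther apart than
    the gate, as in gated nearest-neighbour tracking: a displacement
    beyond the gate is treated as a water exchange and can never be
    preferred over keeping an in-gate occupant on its site.  Within the
    over-gate class pairs are still ranked by distance.  Set ``gate=None``
    to disable.  Ties are resolved deterministically by the solver
    (lowest site label first).
    """
    d = pairwise_distances(references, oxygens, box)
    cost_matrix = (d ** 2 if cost == "squared" else d).astype(float)
    if gate is not None:
        cost_matrix = cost_matrix + _GATE_PENALTY * (d > gate)
    row, col = linear_sum_assignment(cost_matrix)
    # rows come back sorted, so col[s] is the water for site s
    return col, float(cost_matrix[row, col].sum())


def permute_water_identities(
    traj: Trajectory,
    reference: ReferenceMode | str = ReferenceMode.FIRST_FRAME,
    reference_positions: np.ndarray | None = None,
    max_iterations: int = 50,
    tol: float = 0.01,
    reference_update: str = "fixed",
    cost: str = "linear",
    gate: float | None = 2.5,
) -> PermutedWaterTrajectory:
    """Relabel waters frame by frame via iterative linear sum assignment.

    Parameters
    ----------
    reference:
        ``first_frame`` initialises site references from the first
        frame's oxygen positions; ``crystallographic``/``provided``
        require ``reference_positions`` (one row per water).
    reference_update:
        ``fixed`` (default) keeps every label anchored to its initial
        reference position; assignment is then deterministic per frame
        and one sweep suffices.  ``mean`` re-centres each reference on
        its site's assigned mean and re-assigns until self-consistent;
        this sharpens well-sampled bound sites but lets the reference of
        an unbound (freely exchanging) water drift to the centroid of
        its wanderings, where it can shadow genuine sites - prefer
        ``fixed`` whenever bulk waters are in the selection.
    max_iterations, tol:
        For ``mean`` updates, iteration stops when no label changes in a
        full sweep, when the maximum site-mean shift drops below ``tol``
        (A), or after ``max_iterations`` sweeps.
    """
    reference = ReferenceMode(reference)
    if reference_update not in ("fixed", "mean"):
        raise TrajectoryError(f"unknown reference_update {reference_update!r}")
    n_waters = len(traj.topology.water_molecules)
    if n_waters == 0:
        raise TrajectoryError("permutation reduction requires at least one water")
    oxy = _water_oxygen_coords(traj)  # (F, W, 3)
    n_frames = oxy.shape[0]
    box = traj.topology.box

    if reference is ReferenceMode.FIRST_FRAME:
        refs = oxy[0].copy()
    else:
        if reference_positions is None:
            raise TrajectoryError(
                f"reference mode {reference.value!r} needs reference_positions"
            )
        refs = np.asarray(reference_positions, dtype=float).reshape(n_waters, 3).copy()

    perms = np.empty((n_frames, n_waters), dtype=int)
    prev_perms = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        for f in range(n_frames):
            perms[f], _ = assign_frame(oxy[f], refs, box, cost=cost, gate=gate)
        if reference_update == "fixed":
            converged = True
            break
        site_pos = np.take_along_axis(oxy, perms[:, :, None], axis=1)
        new_refs = site_pos.mean(axis=0)
        shift = np.linalg.norm(new_refs - refs, axis=1).max()
        labels_stable = prev_perms is not None and np.array_equal(perms, prev_perms)
        refs = new_refs
        if labels_stable or shift < tol:
            converged = True
            break
        prev_perms = perms.copy()

    site_pos = np.take_along_axis(oxy, perms[:, :, None], axis=1)
    return PermutedWaterTrajectory(
        trajectory=traj,
        permutations=perms,
        site_positions=site_pos,
        reference_positions=refs,
        n_iterations_used=iterations,
        converged=converged,
    )


def compute_mobility(permuted: PermutedWaterTrajectory) -> MobilityTable:
    """Mean position and RMSF per water site on the permuted oxygen tracks.

    RMSF is sqrt(mean over frames of |x(t) - x_mean|^2).  A single-frame
    input yields RMSF 0 with a warning flag.
    """
    pos = permuted.site_positions
    mean = pos.mean(axis=0)
    single = pos.shape[0] < 2
    if single:
        rmsf = np.zeros(pos.shape[1])
    else:
        rmsf = np.sqrt(((pos - mean) ** 2).sum(axis=-1).mean(axis=0))
    return MobilityTable(
        site_labels=np.arange(pos.shape[1]),
        mean_positions=mean,
        rmsf=rmsf,
        n_frames=pos.shape[0],
        single_frame_warning=single,
    )


@dataclass
class HalfComparison:
    first: object
    second: object
    abs_difference: float | None


def split_half_consistency(traj: Trajectory, analysis) -> HalfComparison:
    """Run ``analysis`` independently on the first and second halves of the
    frames; an equilibrated, well-sampled trajectory gives matching halves.

    ``analysis`` maps a Trajectory to a summary; when both summaries are
    numeric their absolute difference is reported.
    """
    if traj.n_frames < 4:
        raise TrajectoryError("split-half check needs at least 4 frames")
    mid = traj.n_frames // 2
    first = Trajectory(traj.topology, traj.frames[:mid])
    second = Trajectory(traj.topology, traj.frames[mid:])
    a, b = analysis(first), analysis(second)
    diff = None
    if isinstance(a, (int, float, np.floating, np.integer)) and isinstance(
            b, (int, float, np.floating, np.integer)):
        diff = abs(float(a) - float(b))
    return HalfComparison(first=a, second=b, abs_difference=diff)
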