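"""Interfacial-water identification and mobility classification.

A water is *interfacial* when its oxygen is simultaneously within a
cutoff of a protein atom and of a DNA atom.  Two modes are supported,
matching the two ways the criterion is applied in practice:

* ``instantaneous`` (default cutoff 5 A): the test is applied per frame
  and a site is interfacial if it qualifies in any frame (the fraction
  of qualifying frames is also reported);
* ``mean_position`` (default cutoff 4 A): the test is applied once to
  each site's trajectory-mean position against a reference structure.

Interfacial waters with an oxygen RMSF strictly below 1.9 A are
classified low-mobility.  Replica counts are summarised as mean and
standard error of the mean (n-1 denominator).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import constants
from .permutation import MobilityTable, PermutedWaterTrajectory
from .trajectory import Frame, Selection, Trajectory, TrajectoryError


class InterfaceMode(str, enum.Enum):
    INSTANTANEOUS = "instantaneous"
    MEAN_POSITION = "mean_position"


@dataclass
class InterfaceCriterion:
    cutoff: float
    mode: InterfaceMode
    partner_a: Selection  # protein
    partner_b: Selection  # dna

    def __post_init__(self) -> None:
        self.mode = InterfaceMode(self.mode)
        if self.cutoff <= 0:
            raise TrajectoryError("interface cutoff must be positive")
        if len(self.partner_a) == 0 or len(self.partner_b) == 0:
            raise TrajectoryError("interface partners must be non-empty")
        if self.partner_a.atom_indices & self.partner_b.atom_indices:
            raise TrajectoryError("interface partners must be disjoint")


@dataclass
class SiteClassification:
    site_label: int
    is_interfacial: bool
    interfacial_fraction: float
    rmsf: float
    is_low_mobility: bool


@dataclass
class InterfaceReport:
    sites: list[SiteClassification]
    cutoff: float
    mode: InterfaceMode
    rmsf_threshold: float

    @property
    def n_interfacial(self) -> int:
        return sum(s.is_interfacial for s in self.sites)

    @property
    def n_low_mobility(self) -> int:
        return sum(s.is_low_mobility for s in self.sites)

    @property
    def low_mobility_percentage(self) -> float:
        """Low-mobility share of the interfacial set, in percent."""
        n = self.n_interfacial
        return 100.0 * self.n_low_mobility / n if n else float("nan")

    def interfacial_set(self) -> set[int]:
        return {s.site_label for s in self.sites if s.is_interfacial}

    def low_mobility_set(self) -> set[int]:
        return {s.site_label for s in self.sites if s.is_low_mobility}


def _near_both(points: np.ndarray, tree_a: cKDTree, tree_b: cKDTree,
               cutoff: float) -> np.ndarray:
    da, _ = tree_a.query(points, k=1)
    db, _ = tree_b.query(points, k=1)
    return (da < cutoff) & (db < cutoff)


def find_interfacial_waters(
    source: PermutedWaterTrajectory | MobilityTable,
    criterion: InterfaceCriterion,
    reference_frame: Frame | None = None,
) -> tuple[set[int], np.ndarray]:
    """Identify interfacial water sites.

    Returns ``(site_labels, fractions)`` where ``fractions[s]`` is the
    fraction of frames in which site ``s`` met the criterion
    (``mean_position`` mode yields 0/1).

    ``instantaneous`` mode needs a :class:`PermutedWaterTrajectory` (the
    partner atoms are taken from the same frames); ``mean_position``
    mode accepts a :class:`MobilityTable` together with a
    ``reference_frame`` holding the partner coordinates.
    """
    if criterion.mode is InterfaceMode.INSTANTANEOUS:
        if not isinstance(source, PermutedWaterTrajectory):
            raise TrajectoryError(
                "instantaneous mode requires a PermutedWaterTrajectory"
            )
        traj = source.trajectory
        ia = criterion.partner_a.as_array()
        ib = criterion.partner_b.as_array()
        hits = np.zeros(source.n_sites)
        for f, frame in enumerate(traj.frames):
            tree_a = cKDTree(frame.positions[ia])
            tree_b = cKDTree(frame.positions[ib])
            hits += _near_both(source.site_positions[f], tree_a, tree_b,
                               criterion.cutoff)
        fractions = hits / source.n_frames
        labels = {int(s) for s in np.nonzero(fractions > 0)[0]}
        return labels, fractions

    if not isinstance(source, MobilityTable):
        raise TrajectoryError(
            "mean_position mode requires a MobilityTable "
            "(run compute_mobility first)"
        )
    if reference_frame is None:
        raise TrajectoryError("mean_position mode requires a reference frame")
    tree_a = cKDTree(reference_frame.positions[criterion.partner_a.as_array()])
    tree_b = cKDTree(reference_frame.positions[criterion.partner_b.as_array()])
    ok = _near_both(source.mean_positions, tree_a, tree_b, criterion.cutoff)
    labels = {int(s) for s in np.nonzero(ok)[0]}
    return labels, ok.astype(float)


def classify_low_mobility(
    mobility: MobilityTable,
    interfacial: set[int],
    rmsf_threshold: float = constants.RMSF_LOW_MOBILITY_A,
    interfacial_fractions: np.ndarray | None = None,
    criterion: InterfaceCriterion | None = None,
) -> InterfaceReport:
    """Classify sites: low mobility iff interfacial AND rmsf < threshold
    (both inequalities strict on the mobility side)."""
    known = set(int(s) for s in mobility.site_labels)
    if not set(interfacial) <= known:
        raise TrajectoryError("interfacial set contains unknown site labels")
    sites = []
    for i, label in enumerate(mobility.site_labels):
        label = int(label)
        inter = label in interfacial
        frac = (float(interfacial_fractions[i])
                if interfacial_fractions is not None else float(inter))
        rmsf = float(mobility.rmsf[i])
        sites.append(SiteClassification(
            site_label=label,
            is_interfacial=inter,
            interfacial_fraction=frac,
            rmsf=rmsf,
            is_low_mobility=inter and rmsf < rmsf_threshold,
        ))
    return InterfaceReport(
        sites=sites,
        cutoff=criterion.cutoff if criterion else float("nan"),
        mode=criterion.mode if criterion else InterfaceMode.INSTANTANEOUS,
        rmsf_threshold=rmsf_threshold,
    )


@dataclass
class ReplicaSummary:
    counts: list[int]
    mean: float
    sem: float | None
    n_replicas: int


def replica_summary(per_replica_counts) -> ReplicaSummary:
    """Mean and s.e.m. (sample s.d. / sqrt(n)) across replicas.

    A single replica returns its value with sem None.
    """
    counts = [float(c) for c in per_replica_counts]
    if not counts:
        raise TrajectoryError("replica_summary needs at least one replica")
    n = len(counts)
    mean = float(np.mean(counts))
    sem = float(np.std(counts, ddof=1) / np.sqrt(n)) if n > 1 else None
    return ReplicaSummary(counts=[c for c in per_replica_counts], mean=mean,
                          sem=sem, n_replicas=n)
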