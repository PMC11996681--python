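"""Hydrogen bonds and water-mediated protein-DNA bridges.

Geometric hydrogen-bond criterion: donor and acceptor are nitrogen or
oxygen atoms with fewer than four covalent bonds, the donor additionally
carries a bonded hydrogen; a bond is recognised when the donor-acceptor
distance is strictly below 3.0 A and the donor-hydrogen-acceptor angle
strictly above 120 degrees.

A *water bridge of order k* is a hydrogen-bond path from a protein polar
atom to a DNA polar atom through exactly k distinct water molecules
(k = 0 is a direct hydrogen bond); orders 0-3 are enumerated.  Bridge
occurrence is averaged over frames and summed per amino-acid/nucleotide
pair; a pair is *stable* when bridged in strictly more than 5% of
frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import constants
from .trajectory import (EntityClass, Frame, Selection, Topology,
                         Trajectory, TrajectoryError)


@dataclass(frozen=True)
class DonorHydrogen:
    donor: int
    hydrogen: int


@dataclass
class HBond:
    donor_atom: int
    hydrogen_atom: int | None
    acceptor_atom: int
    d_a_distance: float
    d_h_a_angle: float | None
    frame_index: int


@dataclass(frozen=True)
class WaterBridge:
    protein_residue: tuple[str, int, str]
    nucleotide: tuple[str, int, str]
    water_chain: tuple[int, ...]   # water-molecule indices, protein side first
    frame_index: int

    @property
    def order(self) -> int:
        return len(self.water_chain)


@dataclass
class BridgeOccupancy:
    protein_residue: tuple[str, int, str]
    nucleotide: tuple[str, int, str]
    occurrence_fraction: float
    fraction_by_order: dict[int, float]
    stable: bool
    representative_chain: tuple[int, ...] | None = None


def donors_acceptors(topology: Topology
                     ) -> tuple[list[DonorHydrogen], list[int]]:
    """Polar-atom bookkeeping.

    Acceptors: N and O atoms with fewer than four covalent bonds.
    Donors: acceptors that additionally carry at least one bonded
    hydrogen, returned once per (donor, hydrogen) pair.
    """
    donors: list[DonorHydrogen] = []
    acceptors: list[int] = []
    for atom in topology.atoms:
        if atom.element not in ("N", "O"):
            continue
        if len(atom.bonded_to) >= 4:
            continue
        acceptors.append(atom.atom_index)
        for j in sorted(atom.bonded_to):
            if topology.atoms[j].is_hydrogen:
                donors.append(DonorHydrogen(atom.atom_index, j))
    return donors, acceptors


def detect_hbonds(
    frame: Frame,
    donors: list[DonorHydrogen],
    acceptors: list[int],
    cutoff: float = constants.HBOND_DA_CUTOFF_A,
    angle_min: float = constants.HBOND_DHA_MIN_DEG,
    distance_only: bool = False,
) -> list[HBond]:
    """All hydrogen bonds in one frame.

    ``distance_only=True`` opts in to an O...O/N distance criterion for
    hydrogen-less topologies: every acceptor-acceptor pair within the
    cutoff counts as bonded and the angle is not evaluated.  The flag is
    recorded by leaving ``hydrogen_atom`` and ``d_h_a_angle`` as None.
    """
    pos = frame.positions
    out: list[HBond] = []
    if distance_only:
        pts = pos[np.array(acceptors)]
        tree = cKDTree(pts)
        for i, j in sorted(tree.query_pairs(cutoff)):
            d = float(np.linalg.norm(pts[i] - pts[j]))
            if d < cutoff:
                out.append(HBond(acceptors[i], None, acceptors[j], d, None,
                                 frame.frame_index))
        return out
    if not donors:
        raise TrajectoryError(
            "no donors with hydrogens; use distance_only=True for "
            "hydrogen-less topologies"
        )
    acc = np.array(acceptors)
    tree = cKDTree(pos[acc])
    for dh in donors:
        dpos = pos[dh.donor]
        hpos = pos[dh.hydrogen]
        for k in tree.query_ball_point(dpos, cutoff):
            a = int(acc[k])
            if a == dh.donor:
                continue
            da = float(np.linalg.norm(pos[a] - dpos))
            if not da < cutoff:
                continue
            v1 = dpos - hpos
            v2 = pos[a] - hpos
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                continue
            cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
            angle = float(np.degrees(np.arccos(cosang)))
            if angle > angle_min:
                out.append(HBond(dh.donor, dh.hydrogen, a, da, angle,
                                 frame.frame_index))
    return out


def _atom_owner(topology: Topology, water_of_atom: dict[int, int],
                atom_index: int) -> tuple[str, object]:
    """Map an atom to its bridge-graph node: ('water', molecule index) or
    ('protein'|'dna'|other, atom index)."""
    if atom_index in water_of_atom:
        return ("water", water_of_atom[atom_index])
    return (topology.atoms[atom_index].entity_class.value, atom_index)


def hbond_graph(topology: Topology, hbonds: list[HBond]) -> nx.Graph:
    """Undirected graph over polar protein/DNA atoms and water molecules
    (one node per water).  Ions and 'other' entities are excluded."""
    water_of_atom: dict[int, int] = {}
    for wi, w in enumerate(topology.water_molecules):
        water_of_atom[w.oxygen_index] = wi
        for h in w.hydrogen_indices:
            water_of_atom[h] = wi
    g = nx.Graph()
    for hb in hbonds:
        u = _atom_owner(topology, water_of_atom, hb.donor_atom)
        v = _atom_owner(topology, water_of_atom, hb.acceptor_atom)
        if u == v:
            continue
        if u[0] in ("ion", "other") or v[0] in ("ion", "other"):
            continue
        g.add_edge(u, v)
    return g


def find_water_bridges(
    frame_hbonds: list[HBond],
    topology: Topology,
    max_order: int = constants.BRIDGE_MAX_ORDER,
    frame_index: int = 0,
) -> list[WaterBridge]:
    """Enumerate protein-DNA bridges of order 0..max_order in one frame.

    Paths run from a protein polar atom to a DNA polar atom on the
    hydrogen-bond graph with every intermediate vertex a water molecule;
    waters may not repeat within a path.  Each distinct water chain is
    one bridge; a residue pair may carry several per frame.
    """
    g = hbond_graph(topology, frame_hbonds)
    bridges: list[WaterBridge] = []
    protein_nodes = [n for n in g if n[0] == "protein"]
    for p in protein_nodes:
        p_res = topology.atoms[p[1]].residue_key()
        # DFS over water chains of length 0..max_order
        stack = [(p, ())]
        while stack:
            node, chain = stack.pop()
            for nb in g.neighbors(node):
                if nb[0] == "dna":
                    bridges.append(WaterBridge(
                        protein_residue=p_res,
                        nucleotide=topology.atoms[nb[1]].residue_key(),
                        water_chain=chain,
                        frame_index=frame_index,
                    ))
                elif nb[0] == "water" and nb[1] not in chain:
                    if len(chain) < max_order:
                        stack.append((nb, chain + (nb[1],)))
    # deduplicate identical (pair, chain) records arising from multiple
    # polar atoms of the same residues
    seen = set()
    unique = []
    for b in bridges:
        key = (b.protein_residue, b.nucleotide, b.water_chain)
        if key not in seen:
            seen.add(key)
            unique.append(b)
    return unique


def bridge_occupancy(
    per_frame_bridges: list[list[WaterBridge]],
    n_frames: int | None = None,
    stability_threshold: float = constants.BRIDGE_STABILITY_FRACTION,
) -> list[BridgeOccupancy]:
    """Trajectory-averaged bridge occupancy per residue-nucleotide pair.

    The pair-level fraction counts frames with at least one bridge of
    any order; per-order fractions are kept alongside.  ``stable`` is
    strict: fraction > threshold.
    """
    if n_frames is None:
        n_frames = len(per_frame_bridges)
    if n_frames < 1:
        raise TrajectoryError("bridge occupancy needs at least one frame")
    frames_with: dict[tuple, set[int]] = {}
    frames_by_order: dict[tuple, dict[int, set[int]]] = {}
    representative: dict[tuple, tuple[int, ...]] = {}
    for f, bridges in enumerate(per_frame_bridges):
        for b in bridges:
            pair = (b.protein_residue, b.nucleotide)
            frames_with.setdefault(pair, set()).add(f)
            frames_by_order.setdefault(pair, {}).setdefault(b.order, set()).add(f)
            representative.setdefault(pair, b.water_chain)
    out = []
    for pair, frames in sorted(frames_with.items()):
        frac = len(frames) / n_frames
        by_order = {
            k: len(frames_by_order[pair].get(k, set())) / n_frames
            for k in range(0, constants.BRIDGE_MAX_ORDER + 1)
        }
        out.append(BridgeOccupancy(
            protein_residue=pair[0],
            nucleotide=pair[1],
            occurrence_fraction=frac,
            fraction_by_order=by_order,
            stable=frac > stability_threshold,
            representative_chain=representative.get(pair),
        ))
    return out


def trajectory_bridges(
    traj: Trajectory,
    cutoff: float = constants.HBOND_DA_CUTOFF_A,
    angle_min: float = constants.HBOND_DHA_MIN_DEG,
    max_order: int = constants.BRIDGE_MAX_ORDER,
    distance_only: bool = False,
) -> list[list[WaterBridge]]:
    """Convenience: hydrogen bonds and bridges for every frame."""
    donors, acceptors = donors_acceptors(traj.topology)
    out = []
    for frame in traj.frames:
        hb = detect_hbonds(frame, donors, acceptors, cutoff=cutoff,
                           angle_min=angle_min, distance_only=distance_only)
        out.append(find_water_bridges(hb, traj.topology, max_order=max_order,
                                      frame_index=frame.frame_index))
    return out
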