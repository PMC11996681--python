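"""Hydrogen-bond detection, water-bridge enumeration and occupancy."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

import hydrodna as hd
from hydrodna.bridges import (DonorHydrogen, bridge_occupancy, detect_hbonds,
                              donors_acceptors, find_water_bridges,
                              hbond_graph)
from hydrodna.synthetic import make_bridge_fixture
from hydrodna.trajectory import (AtomRecord, EntityClass, Frame, Topology,
                                 TrajectoryError, WaterMolecule)


def geometry_frame(d_a: float, angle_deg: float):
    """Donor at origin with one hydrogen, acceptor at (d_a, 0, 0), the
    hydrogen placed for an exact D-H-A angle."""
    from hydrodna.synthetic import _bridge_hydrogen_offset
    hx, hy = _bridge_hydrogen_offset(d_a, angle_deg, oh=0.96)
    atoms = [
        AtomRecord(0, "OG", "O", "SER", 1, "A", EntityClass.PROTEIN,
                   bonded_to={1}),
        AtomRecord(1, "HG", "H", "SER", 1, "A", EntityClass.PROTEIN,
                   bonded_to={0}),
        AtomRecord(2, "N7", "N", "DA", 1, "B", EntityClass.DNA),
    ]
    topo = Topology(atoms, [])
    frame = Frame(np.array([[0, 0, 0], [hx, hy, 0], [d_a, 0, 0]]), 0)
    return topo, frame


class TestDonorsAcceptors:
    def test_water_oxygen_donor_twice_and_acceptor(self):
        topo, frame, _ = make_bridge_fixture(1)
        donors, acceptors = donors_acceptors(topo)
        w = topo.water_molecules[0]
        w_donors = [d for d in donors if d.donor == w.oxygen_index]
        assert len(w_donors) == 2
        assert w.oxygen_index in acceptors

    def test_amide_nitrogen_donor_and_acceptor(self):
        atoms = [
            AtomRecord(0, "N", "N", "GLY", 1, "A", EntityClass.PROTEIN,
                       bonded_to={1, 2, 3}),
            AtomRecord(1, "H", "H", "GLY", 1, "A", EntityClass.PROTEIN,
                       bonded_to={0}),
            AtomRecord(2, "CA", "C", "GLY", 1, "A", EntityClass.PROTEIN,
                       bonded_to={0}),
            AtomRecord(3, "C", "C", "GLY", 1, "A", EntityClass.PROTEIN,
                       bonded_to={0}),
        ]
        donors, acceptors = donors_acceptors(Topology(atoms, []))
        assert DonorHydrogen(0, 1) in donors
        assert 0 in acceptors

    def test_quaternary_nitrogen_excluded(self):
        """Four covalent bonds disqualify both roles."""
        atoms = [AtomRecord(0, "N", "N", "LYS", 1, "A", EntityClass.PROTEIN,
                            bonded_to={1, 2, 3, 4})]
        atoms += [AtomRecord(i, f"H{i}", "H", "LYS", 1, "A",
                             EntityClass.PROTEIN, bonded_to={0})
                  for i in range(1, 5)]
        donors, acceptors = donors_acceptors(Topology(atoms, []))
        assert donors == [] and acceptors == []


class TestDetectHbonds:
    @pytest.mark.parametrize("d_a, angle, found", [
        (2.8, 160.0, True),
        (3.2, 175.0, False),   # distance not < 3 A
        (2.7, 110.0, False),   # angle not > 120 deg
    ])
    def test_geometric_criteria(self, d_a, angle, found):
        topo, frame = geometry_frame(d_a, angle)
        donors, acceptors = donors_acceptors(topo)
        hbonds = detect_hbonds(frame, donors, acceptors)
        assert bool(hbonds) is found
        if found:
            hb = hbonds[0]
            assert hb.d_a_distance == pytest.approx(d_a)
            assert hb.d_h_a_angle == pytest.approx(angle, abs=1e-6)

    def test_thresholds_strict(self):
        """A distance of exactly 3.0 A is rejected (strict <); an angle
        just below 120 deg is rejected (strict >)."""
        topo, frame = geometry_frame(3.0, 150.0)
        donors, acceptors = donors_acceptors(topo)
        assert detect_hbonds(frame, donors, acceptors) == []
        topo, frame = geometry_frame(2.8, 119.999999)
        donors, acceptors = donors_acceptors(topo)
        assert detect_hbonds(frame, donors, acceptors) == []

    def test_distance_only_mode(self):
        """Hydrogen-less topologies need the explicit O...O opt-in."""
        atoms = [
            AtomRecord(0, "O", "O", "SER", 1, "A", EntityClass.PROTEIN),
            AtomRecord(1, "N7", "N", "DA", 1, "B", EntityClass.DNA),
        ]
        topo = Topology(atoms, [])
        frame = Frame(np.array([[0, 0, 0], [2.5, 0, 0.0]]), 0)
        donors, acceptors = donors_acceptors(topo)
        with pytest.raises(TrajectoryError):
            detect_hbonds(frame, donors, acceptors)
        hbonds = detect_hbonds(frame, donors, acceptors, distance_only=True)
        assert len(hbonds) == 1
        assert hbonds[0].hydrogen_atom is None


class TestBridges:
    @pytest.mark.parametrize("order", [0, 1, 2, 3])
    def test_fixture_order_detected(self, order):
        """Constructed chains of each order yield exactly one bridge of
        the planted order between the planted residue pair."""
        topo, frame, expected = make_bridge_fixture(order)
        donors, acceptors = donors_acceptors(topo)
        hbonds = detect_hbonds(frame, donors, acceptors)
        assert len(hbonds) == order + 1
        bridges = find_water_bridges(hbonds, topo)
        assert len(bridges) == 1
        b = bridges[0]
        assert b.order == expected["order"]
        assert b.water_chain == expected["water_chain"]
        assert b.protein_residue == expected["protein_residue"]
        assert b.nucleotide == expected["nucleotide"]

    def test_perturbed_middle_water_breaks_bridge(self):
        """Displacing the chain's middle water by 1.5 A breaks it."""
        topo, frame, _ = make_bridge_fixture(3)
        mid_oxygen = topo.water_molecules[1].oxygen_index
        pos = frame.positions.copy()
        pos[mid_oxygen] += (0.0, 1.5, 0.0)
        moved = Frame(pos, 0)
        donors, acceptors = donors_acceptors(topo)
        bridges = find_water_bridges(detect_hbonds(moved, donors, acceptors),
                                     topo)
        assert bridges == []

    def test_order_cap(self):
        """A 3-water chain is invisible at max_order 2; raising the cap
        never removes lower-order bridges."""
        topo, frame, _ = make_bridge_fixture(3)
        donors, acceptors = donors_acceptors(topo)
        hbonds = detect_hbonds(frame, donors, acceptors)
        assert find_water_bridges(hbonds, topo, max_order=2) == []
        low = {(b.protein_residue, b.nucleotide, b.water_chain)
               for b in find_water_bridges(hbonds, topo, max_order=1)}
        high = {(b.protein_residue, b.nucleotide, b.water_chain)
                for b in find_water_bridges(hbonds, topo, max_order=3)}
        assert low <= high

    def test_graph_symmetry(self):
        """Bridges are identical when protein and DNA roles swap (the
        H-bond graph is undirected)."""
        topo, frame, _ = make_bridge_fixture(2)
        donors, acceptors = donors_acceptors(topo)
        hbonds = detect_hbonds(frame, donors, acceptors)
        forward = find_water_bridges(hbonds, topo)
        # swap entity classes in a copied topology
        from copy import deepcopy
        swapped = deepcopy(topo)
        for a in swapped.atoms:
            if a.entity_class is EntityClass.PROTEIN:
                a.entity_class = EntityClass.DNA
            elif a.entity_class is EntityClass.DNA:
                a.entity_class = EntityClass.PROTEIN
        backward = find_water_bridges(hbonds, swapped)
        assert [(b.water_chain[::-1], b.order) for b in backward] == \
            [(b.water_chain, b.order) for b in forward]

    def test_matches_exhaustive_path_search(self):
        """On random small H-bond graphs, the DFS enumeration equals
        brute-force simple-path search with water-only interiors."""
        rng = np.random.default_rng(17)
        for trial in range(20):
            n_prot, n_dna, n_wat = 2, 2, rng.integers(1, 5)
            atoms = []
            for i in range(n_prot):
                atoms.append(AtomRecord(len(atoms), "O", "O", "SER", i + 1,
                                        "A", EntityClass.PROTEIN))
            for i in range(n_dna):
                atoms.append(AtomRecord(len(atoms), "N7", "N", "DA", i + 1,
                                        "B", EntityClass.DNA))
            waters = []
            for i in range(n_wat):
                idx = len(atoms)
                atoms.append(AtomRecord(idx, "O", "O", "HOH", i + 1, "W",
                                        EntityClass.WATER))
                waters.append(WaterMolecule(idx, ()))
            topo = Topology(atoms, waters)
            # random hydrogen-bond list over the polar atoms
            hbonds = []
            indices = list(range(len(atoms)))
            for u, v in itertools.combinations(indices, 2):
                if rng.random() < 0.4:
                    hbonds.append(hd.HBond(u, None, v, 2.8, 160.0, 0))
            got = {(b.protein_residue, b.nucleotide, b.water_chain)
                   for b in find_water_bridges(hbonds, topo, max_order=3)}

            g = hbond_graph(topo, hbonds)
            expected = set()
            prot_nodes = [n for n in g if n[0] == "protein"]
            dna_nodes = [n for n in g if n[0] == "dna"]
            for p, d in itertools.product(prot_nodes, dna_nodes):
                for path in nx.all_simple_paths(g, p, d, cutoff=4):
                    interior = path[1:-1]
                    if all(x[0] == "water" for x in interior):
                        expected.add((
                            topo.atoms[p[1]].residue_key(),
                            topo.atoms[d[1]].residue_key(),
                            tuple(x[1] for x in interior)))
            assert got == expected, f"trial {trial}"


class TestOccupancy:
    def _bridge(self, frame_index):
        return hd.WaterBridge(("A", 1, "SER"), ("B", 1, "DA"), (0,),
                              frame_index)

    @pytest.mark.parametrize("n_bridged, stable", [(6, True), (5, False)])
    def test_five_percent_rule_strict(self, n_bridged, stable):
        """6/100 frames is stable, exactly 5/100 is not (strict > 0.05)."""
        per_frame = [[self._bridge(f)] if f < n_bridged else []
                     for f in range(100)]
        occ = bridge_occupancy(per_frame, 100)
        assert len(occ) == 1
        assert occ[0].occurrence_fraction == pytest.approx(n_bridged / 100)
        assert occ[0].stable is stable

    def test_never_bridged_absent(self):
        occ = bridge_occupancy([[] for _ in range(10)], 10)
        assert occ == []

    def test_pair_fraction_counts_any_order_once(self):
        """Two bridges of different orders in one frame count that frame
        once at pair level, with per-order breakdown kept."""
        b0 = hd.WaterBridge(("A", 1, "SER"), ("B", 1, "DA"), (), 0)
        b1 = hd.WaterBridge(("A", 1, "SER"), ("B", 1, "DA"), (0,), 0)
        occ = bridge_occupancy([[b0, b1], []], 2)
        assert occ[0].occurrence_fraction == pytest.approx(0.5)
        assert occ[0].fraction_by_order[0] == pytest.approx(0.5)
        assert occ[0].fraction_by_order[1] == pytest.approx(0.5)
        assert occ[0].fraction_by_order[2] == 0.0
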