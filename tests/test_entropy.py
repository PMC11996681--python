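"""Solvent/solute entropy estimators and the interface bookkeeping
identity."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import hydrodna as hd
from hydrodna import constants as C
from hydrodna.entropy import (PerWaterEntropy, _schlitter_factor,
                              interface_entropy_summary,
                              schlitter_from_covariance)
from hydrodna.trajectory import (AtomRecord, EntityClass, Frame, Selection,
                                 Topology, Trajectory, TrajectoryError)
from conftest import water_only_trajectory


def analytic_1d_schlitter(mass_u, sigma2_A2, temperature):
    alpha = (_schlitter_factor(temperature) * mass_u * C.ATOMIC_MASS_KG
             * sigma2_A2 * C.ANGSTROM_M ** 2)
    return 0.5 * C.GAS_CONSTANT_J_PER_K_MOL * math.log1p(alpha)


class TestPerWaterEntropy:
    def test_zero_variance_site_is_zero(self):
        """A pinned site has unit determinant, hence s = 0, flagged."""
        traj = water_only_trajectory([[(1.0, 2.0, 3.0)]] * 20)
        ents = hd.per_water_entropy(hd.permute_water_identities(traj))
        assert ents[0].s_trans == 0.0
        assert ents[0].degenerate

    def test_matches_isotropic_closed_form(self):
        """Isotropic Gaussian site: s equals 3x the 1D analytic value
        within the Monte-Carlo error of the covariance estimate."""
        rng = np.random.default_rng(3)
        sigma, n = 0.5, 20000
        frames = [[rng.normal(0, sigma, 3)] for _ in range(n)]
        traj = water_only_trajectory(frames)
        ents = hd.per_water_entropy(hd.permute_water_identities(traj))
        expected = 3 * analytic_1d_schlitter(C.WATER_MASS_U, sigma ** 2,
                                             C.TEMPERATURE_K)
        assert ents[0].s_trans == pytest.approx(expected, rel=0.02)

    def test_monotone_in_dispersion(self):
        rng = np.random.default_rng(4)
        frames = [[(0, 0, 0) + rng.normal(0, 0.2, 3),
                   (20, 0, 0) + rng.normal(0, 1.0, 3)] for _ in range(500)]
        traj = water_only_trajectory(frames)
        ents = hd.per_water_entropy(hd.permute_water_identities(traj))
        assert ents[0].s_trans < ents[1].s_trans

    def test_entropy_orders_like_mobility(self):
        """Spearman correlation between per-site RMSF and s_trans is
        >= 0.9 across sigma from 0.1 to 3 A."""
        rng = np.random.default_rng(5)
        sigmas = np.linspace(0.1, 3.0, 12)
        centers = [(12.0 * i, 0, 0) for i in range(len(sigmas))]
        frames = []
        for _ in range(400):
            frames.append([np.asarray(c) + rng.normal(0, s, 3)
                           for c, s in zip(centers, sigmas)])
        traj = water_only_trajectory(frames)
        permuted = hd.permute_water_identities(traj, gate=None)
        mob = hd.compute_mobility(permuted)
        ents = hd.per_water_entropy(permuted)
        rho = spearmanr(mob.rmsf, [e.s_trans for e in ents]).statistic
        assert rho >= 0.9


class TestInterfaceSummary:
    def test_direct_arithmetic(self):
        """{80, 100} vs bulk 118: S_avg 90, dS = 2*(90-118) = -56."""
        ents = [PerWaterEntropy(0, 80.0, (0, 0, 0), 10),
                PerWaterEntropy(1, 100.0, (0, 0, 0), 10)]
        s = interface_entropy_summary(ents, {0, 1}, s_bulk=118.0)
        assert s.N == 2
        assert s.S_avg == pytest.approx(90.0)
        assert s.S_total == pytest.approx(180.0)
        assert s.delta_S_solv == pytest.approx(-56.0)

    def test_empty_interface(self):
        s = interface_entropy_summary([], set())
        assert (s.N, s.S_avg, s.delta_S_solv) == (0, None, 0.0)

    def test_bulk_equality_gives_zero(self):
        ents = [PerWaterEntropy(i, 118.0, (0, 0, 0), 10) for i in range(7)]
        s = interface_entropy_summary(ents, set(range(7)), s_bulk=118.0)
        assert s.delta_S_solv == pytest.approx(0.0, abs=1e-12)

    def test_identity_holds_on_synthetic_reports(self, permuted):
        """dS_solv = N*(S_avg - S_bulk) to 1e-9 on every report."""
        ents = hd.per_water_entropy(permuted)
        for subset in (set(), {0}, {0, 1, 2}, set(range(len(ents)))):
            s = interface_entropy_summary(ents, subset)
            expected = s.N * (s.S_avg - s.S_bulk) if s.N else 0.0
            assert abs(s.delta_S_solv - expected) < 1e-9

    def test_ac_like_more_negative_than_tt_like(self):
        """More, tighter interfacial sites give a strictly more negative
        solvent-entropy change."""
        def delta_s(n_pinned, seed):
            topo, frame, truth = hd.make_scaffold_complex(
                n_interfacial_waters=n_pinned, n_bulk_waters=20, seed=seed)
            traj, _ = hd.simulate_water_trajectory(
                topo, frame, truth, n_frames=150, pinned_sigma=0.3,
                seed=seed + 1)
            permuted = hd.permute_water_identities(traj)
            mob = hd.compute_mobility(permuted)
            crit = hd.InterfaceCriterion(
                4.0, "mean_position", topo.selection("protein"),
                topo.selection("dna"))
            labels, _ = hd.find_interfacial_waters(
                mob, crit, reference_frame=frame)
            ents = hd.per_water_entropy(permuted)
            return interface_entropy_summary(ents, labels).delta_S_solv

        assert delta_s(12, 61) < delta_s(4, 71)


class TestSchlitter:
    def test_identical_frames_zero_entropy(self):
        traj = water_only_trajectory([[(0, 0, 0), (5, 0, 0)]] * 10)
        sel = Selection({0, 1}, "waters")
        rep = hd.schlitter_entropy(traj, sel, superpose=False)
        assert rep.schlitter_upper_bound == pytest.approx(0.0, abs=1e-9)

    def test_harmonic_oscillator_closed_form(self):
        """A classical 1D harmonic oscillator sampled from its Boltzmann
        distribution matches the analytic Schlitter value."""
        rng = np.random.default_rng(6)
        m_u, T = 12.0, 300.0
        sigma2 = 0.04  # A^2, i.e. k = kB*T/sigma2
        n = 5000
        x = rng.normal(0, math.sqrt(sigma2), n)
        frames = [[(xi, 0.0, 0.0)] for xi in x]
        traj = water_only_trajectory(frames)
        rep = hd.schlitter_entropy(traj, Selection({0}, "osc"),
                                   temperature=T,
                                   masses_u=np.array([m_u]),
                                   superpose=False)
        expected = analytic_1d_schlitter(m_u, sigma2, T)
        assert rep.schlitter_upper_bound == pytest.approx(expected, rel=0.02)

    def test_doubling_fluctuations_increases_entropy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.3, (200, 2, 3))
        small = water_only_trajectory([list(map(tuple, f)) for f in x])
        large = water_only_trajectory([list(map(tuple, 2 * f)) for f in x])
        sel = Selection({0, 1}, "pair")
        s_small = hd.schlitter_entropy(small, sel, superpose=False)
        s_large = hd.schlitter_entropy(large, sel, superpose=False)
        assert s_large.schlitter_upper_bound > s_small.schlitter_upper_bound

    def test_split_half_convergence(self):
        """First/second-half estimates agree within 5% at 5000 frames on
        the harmonic test system."""
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.2, 5000)
        traj = water_only_trajectory([[(xi, 0.0, 0.0)] for xi in x])

        def schlitter(t):
            return hd.schlitter_entropy(
                t, Selection({0}, "osc"), superpose=False).schlitter_upper_bound

        res = hd.split_half_consistency(traj, schlitter)
        assert abs(res.first - res.second) / res.first < 0.05

    def test_temperature_and_frame_guards(self):
        traj = water_only_trajectory([[(0, 0, 0)]])
        with pytest.raises(TrajectoryError):
            hd.schlitter_entropy(traj, Selection({0}))
        traj2 = water_only_trajectory([[(0, 0, 0)], [(1, 0, 0)]])
        with pytest.raises(TrajectoryError):
            hd.schlitter_entropy(traj2, Selection({0}), temperature=-1.0)


class TestResidueRmsf:
    def _protein_trajectory(self, frames_xyz, names=("CA", "CB")):
        n = len(frames_xyz[0])
        atoms = []
        for i in range(n):
            atoms.append(AtomRecord(i, names[i % len(names)], "C", "GLY",
                                    i // 2 + 1, "A", EntityClass.PROTEIN))
        topo = Topology(atoms, [])
        frames = [Frame(np.asarray(p, float), i)
                  for i, p in enumerate(frames_xyz)]
        return Trajectory(topo, frames), topo

    def test_rigid_translation_removed(self):
        """A rigidly translated residue has zero RMSF after
        superposition."""
        base = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [3, 3, 3.0]])
        frames = [base + (f * 2.0, 0, 0) for f in range(10)]
        traj, topo = self._protein_trajectory(frames)
        rows = hd.residue_rmsf(traj, topo.selection("protein"))
        assert all(r["rmsf_all_A"] < 1e-9 for r in rows)

    def test_residue_mean_of_atom_rmsf(self):
        """Two atoms with RMSF 0.4 and 0.6 average to residue 0.5."""
        rng = np.random.default_rng(9)
        n = 4000
        a = rng.choice([-0.4, 0.4], n)
        b = rng.choice([-0.6, 0.6], n)
        frames = [np.array([[ai, 0, 0], [20 + bi, 0, 0]])
                  for ai, bi in zip(a, b)]
        traj, topo = self._protein_trajectory(frames)
        rows = hd.residue_rmsf(traj, topo.selection("protein"),
                               superpose=False)
        assert rows[0]["rmsf_all_A"] == pytest.approx(0.5, abs=0.02)

    def test_flexible_terminal_residues_rank_highest(self):
        """Planted high-flexibility terminal residues dominate the
        per-residue RMSF ranking."""
        rng = np.random.default_rng(10)
        n_res, n_frames = 6, 300
        base = np.array([[3.0 * i, 0, 0] for i in range(2 * n_res)])
        sig = np.full(2 * n_res, 0.1)
        sig[:2] = sig[-2:] = 1.2  # first and last residue flexible
        frames = [base + rng.normal(0, 1, base.shape) * sig[:, None]
                  for _ in range(n_frames)]
        traj, topo = self._protein_trajectory(frames)
        rows = hd.residue_rmsf(traj, topo.selection("protein"),
                               superpose=False)
        ranked = sorted(rows, key=lambda r: -r["rmsf_all_A"])
        top2 = {r["residue_seq"] for r in ranked[:2]}
        assert top2 == {1, n_res}
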