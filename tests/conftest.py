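import numpy as np
import pytest

import hydrodna as hd


@pytest.fixture(scope="session")
def small_scaffold():
    """Scaffold with 4 interfacial, 2 distal and 8 bulk waters."""
    return hd.make_scaffold_complex(
        n_interfacial_waters=4, n_distal_waters=2, n_bulk_waters=8, seed=11)


@pytest.fixture(scope="session")
def small_trajectory(small_scaffold):
    topo, frame, truth = small_scaffold
    traj, t2 = hd.simulate_water_trajectory(
        topo, frame, truth, n_frames=120, pinned_sigma=0.3,
        scramble_labels=True, seed=12)
    return traj, t2


@pytest.fixture(scope="session")
def permuted(small_trajectory):
    traj, _ = small_trajectory
    return hd.permute_water_identities(traj)


@pytest.fixture(scope="session")
def two_optima_pools():
    """Small SELEX simulation (20k reads) with the two-optima landscape."""
    truth = hd.default_two_optima_truth()
    pools, ft = hd.simulate_selex_reads(truth, n_reads_per_cycle=20_000, seed=21)
    return pools, ft


def water_only_trajectory(frames_xyz):
    """Topology of bare water oxygens plus the given coordinate frames."""
    from hydrodna.trajectory import (AtomRecord, EntityClass, Frame, Topology,
                                     Trajectory, WaterMolecule)
    n = len(frames_xyz[0])
    atoms = [AtomRecord(i, "O", "O", "HOH", i + 1, "W", EntityClass.WATER)
             for i in range(n)]
    topo = Topology(atoms, [WaterMolecule(i, ()) for i in range(n)])
    frames = [Frame(np.asarray(p, float), i) for i, p in enumerate(frames_xyz)]
    return Trajectory(topo, frames)
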