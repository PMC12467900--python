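import numpy as np
import pytest

from platonet.dataset import (
    NormalizationStats,
    assemble,
    leave_extremes_out,
    load_dataset,
    random_split,
    save_dataset,
)
from platonet.simulate import Trajectory, capillary_number


def toy_trajectories(n_traj=4, n_snap=6, n_v=30, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(-1, 1, (n_v, 3))
    trajs = []
    ks = np.linspace(0.0003, 0.0030, n_traj)
    for K in ks:
        pos = np.empty((n_snap, n_v, 3))
        pos[0] = x0
        for s in range(1, n_snap):
            pos[s] = x0 + 0.1 * s * rng.normal(size=(n_v, 3)) / np.sqrt(K * 1e4)
        trajs.append(
            Trajectory(
                K=float(K), K_reduced=K * 1000, Ca=capillary_number(float(K)),
                sigma_w=50.0, times=np.arange(n_snap, dtype=float),
                positions=pos, seed=1, jeffery_T=n_snap - 1.0,
                duration=n_snap - 1.0, shear_rate=0.25, major_diameter=4.0,
            )
        )
    return trajs


class TestAssemble:
    def test_sample_count_is_product(self):
        ds = assemble(toy_trajectories())
        assert len(ds) == 4 * 6 * 30

    def test_t0_targets_are_zero(self):
        ds = assemble(toy_trajectories())
        at0 = ds.trunk[:, 3] == 0.0
        assert at0.sum() == 4 * 30
        assert np.all(ds.target[at0] == 0.0)

    def test_t_hat_in_unit_interval(self):
        ds = assemble(toy_trajectories())
        assert ds.trunk[:, 3].min() == 0.0
        assert ds.trunk[:, 3].max() == 1.0

    def test_branch_carries_sigma_and_k(self):
        ds = assemble(toy_trajectories())
        assert set(np.unique(ds.branch[:, 0])) == {50.0}
        assert len(np.unique(ds.branch[:, 1])) == 4

    def test_inconsistent_vertex_count_rejected(self):
        trajs = toy_trajectories()
        bad = toy_trajectories(n_v=10)
        with pytest.raises(ValueError):
            assemble([trajs[0], bad[0]])


class TestRandomSplit:
    def test_sizes_at_default_fraction(self):
        ds = assemble(toy_trajectories())
        tr, va, m = random_split(ds, 0.9, seed=1)
        assert len(tr) == round(0.9 * len(ds))
        assert len(tr) + len(va) == len(ds)
        assert m["n_train"] == len(tr)

    def test_partition_disjoint_exhaustive(self):
        ds = assemble(toy_trajectories())
        key = np.array([ds.traj_index, ds.snap_index, ds.vertex_index]).T
        tr, va, _ = random_split(ds, 0.8, seed=2)
        k_tr = {tuple(r) for r in np.array(
            [tr.traj_index, tr.snap_index, tr.vertex_index]).T}
        k_va = {tuple(r) for r in np.array(
            [va.traj_index, va.snap_index, va.vertex_index]).T}
        assert not k_tr & k_va
        assert len(k_tr | k_va) == len(ds)

    def test_every_k_in_training(self):
        ds = assemble(toy_trajectories())
        tr, _, _ = random_split(ds, 0.9, seed=3)
        assert set(np.unique(tr.traj_index)) == {0, 1, 2, 3}

    def test_deterministic_by_seed(self):
        ds = assemble(toy_trajectories())
        tr1, _, _ = random_split(ds, 0.9, seed=4)
        tr2, _, _ = random_split(ds, 0.9, seed=4)
        assert np.array_equal(tr1.trunk, tr2.trunk)

    def test_empty_input_rejected(self):
        ds = assemble(toy_trajectories())
        empty = ds.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            random_split(empty, 0.9, seed=0)


class TestLeaveExtremesOut:
    def test_default_sweep_split(self):
        trajs = toy_trajectories(n_traj=10)
        kept, held = leave_extremes_out(trajs)
        assert len(kept) == 8 and len(held) == 2
        held_K = sorted(t.K for t in held)
        assert held_K[0] == pytest.approx(0.0003)
        assert held_K[1] == pytest.approx(0.0030)
        held_Ca = sorted(t.Ca for t in held)
        assert round(held_Ca[0], 4) == pytest.approx(0.0770, abs=5e-5)
        assert round(held_Ca[1], 4) == pytest.approx(0.7698, abs=5e-5)

    def test_minimal_three_levels(self):
        kept, held = leave_extremes_out(toy_trajectories(n_traj=3))
        assert len(kept) == 1 and len(held) == 2

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            leave_extremes_out(toy_trajectories(n_traj=2))


class TestNormalization:
    def test_midpoint_maps_to_half(self):
        stats = NormalizationStats(
            branch_min=np.array([0.0, 2.0]), branch_max=np.array([0.0, 4.0]),
            trunk_min=np.zeros(4), trunk_max=np.ones(4),
        )
        out = stats.normalize_branch(np.array([[0.0, 3.0]]))
        assert out[0, 1] == pytest.approx(0.5)

    def test_degenerate_channel_maps_to_zero(self):
        ds = assemble(toy_trajectories())
        stats = NormalizationStats.fit(ds)
        normed = stats.normalize_branch(ds.branch)
        assert np.all(normed[:, 0] == 0.0)  # sigma_w is constant (50 Pa)

    def test_round_trip_identity(self):
        ds = assemble(toy_trajectories())
        stats = NormalizationStats.fit(ds)
        back = stats.denormalize_trunk(stats.normalize_trunk(ds.trunk))
        assert np.allclose(back, ds.trunk, rtol=1e-12, atol=1e-12)

    def test_train_only_stats_exclude_extremes(self):
        trajs = toy_trajectories(n_traj=5)
        kept, _ = leave_extremes_out(trajs)
        stats_kept = NormalizationStats.fit(assemble(kept))
        stats_all = NormalizationStats.fit(assemble(trajs))
        assert stats_kept.branch_max[1] < stats_all.branch_max[1]
        assert stats_kept.branch_min[1] > stats_all.branch_min[1]

    def test_sample_count_conserved(self):
        ds = assemble(toy_trajectories())
        stats = NormalizationStats.fit(ds)
        assert len(stats.normalize(ds)) == len(ds)


class TestStorage:
    def test_h5_round_trip(self, tmp_path):
        ds = assemble(toy_trajectories())
        stats = NormalizationStats.fit(ds)
        path = save_dataset(ds, tmp_path / "d.h5", stats=stats,
                            manifest={"seed": 1})
        ds2, stats2, manifest = load_dataset(path)
        assert np.array_equal(ds.branch, ds2.branch)
        assert np.array_equal(ds.target, ds2.target)
        assert np.allclose(stats2.trunk_max, stats.trunk_max)
        assert manifest == {"seed": 1}
        assert ds2.diameter == ds.diameter
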