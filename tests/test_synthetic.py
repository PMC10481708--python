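import numpy as np
import pytest

from fcnc import (
    ConfigError,
    DistanceMatrix,
    FiltrationConfig,
    SimulationConfig,
    build_simplex_stream,
    generate_group_timeseries,
    generate_point_cloud,
    homology_ranks_bruteforce,
    planted_truth,
    reduce_boundary_matrix,
)
from fcnc.synthetic import population_distance, target_correlation

RING6 = (0, 1, 2, 3, 4, 5)


def small_config(**kw):
    base = dict(n_scans_a=2, n_scans_b=2, n_regions=12, n_timepoints=50, seed=3)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateGroupTimeseries:
    def test_same_seed_is_byte_identical(self):
        a1, b1 = generate_group_timeseries(small_config())
        a2, b2 = generate_group_timeseries(small_config())
        for s1, s2 in zip(a1 + b1, a2 + b2):
            assert s1.scan_id == s2.scan_id
            np.testing.assert_array_equal(s1.values, s2.values)

    def test_different_seed_differs(self):
        a1, _ = generate_group_timeseries(small_config(seed=3))
        a2, _ = generate_group_timeseries(small_config(seed=4))
        assert not np.array_equal(a1[0].values, a2[0].values)

    def test_independence_limit(self):
        """With all correlations zero, off-diagonal sample correlations vanish."""
        cfg = small_config(
            n_scans_a=1, n_scans_b=1, within_cycle_corr=0.0,
            background_corr=0.0, n_timepoints=5000,
        )
        a, _ = generate_group_timeseries(cfg)
        r = np.corrcoef(a[0].values, rowvar=False)
        off = r[~np.eye(cfg.n_regions, dtype=bool)]
        assert np.abs(off).max() < 0.2
        assert abs(off.mean()) < 0.01

    def test_sample_correlation_converges_to_population(self):
        """Long scans recover the (projected) target correlation matrix."""
        cfg = SimulationConfig(
            n_scans_a=1, n_scans_b=1, n_regions=90, n_timepoints=10_000,
            planted_cycles_a=(RING6,), within_cycle_corr=0.8,
            background_corr=0.1, seed=12,
        )
        a, _ = generate_group_timeseries(cfg)
        target = target_correlation(cfg, cfg.planted_cycles_a)
        sample = np.corrcoef(a[0].values, rowvar=False)
        assert np.abs(sample - target).max() <= 0.05

    def test_planted_ring_population_homology(self):
        """The planted 6-ring is a genuine 1-cycle of the population metric.

        Ring-adjacent pairs end up far more correlated than chords, so the
        brute-force homology of the population VR complex restricted to the
        ring has beta1 = 1 at an intermediate scale.
        """
        cfg = SimulationConfig(
            n_scans_a=1, n_scans_b=1, n_regions=90, n_timepoints=500,
            planted_cycles_a=(RING6,), within_cycle_corr=0.9,
            background_corr=0.05, seed=0,
        )
        d = population_distance(cfg, "A")
        ring_d = d[np.ix_(RING6, RING6)]
        # adjacency beats chords decisively in the projected population metric
        assert ring_d[0, 1] < 0.5 < ring_d[0, 2]
        dm = DistanceMatrix(ring_d, [str(i) for i in RING6])
        stream = build_simplex_stream(dm, FiltrationConfig(d_max=2, t_max=2.0))
        assert homology_ranks_bruteforce(stream, 0.5) == (1, 1)
        # the reduction agrees
        barcode = reduce_boundary_matrix(stream)
        alive = [
            iv for iv in barcode.dim(1) if iv.birth <= 0.5 < iv.death
        ]
        assert len(alive) == 1

    def test_ring_adjacency_only_not_filled_clique(self):
        cfg = small_config(planted_cycles_a=(RING6,))
        sigma = target_correlation(cfg, cfg.planted_cycles_a)
        assert sigma[0, 1] > 2.0 * sigma[0, 3]  # adjacent pair >> opposite pair


class TestPlantedTruth:
    def test_identical_rings_give_empty(self):
        cfg = small_config(planted_cycles_a=((1, 2, 3),), planted_cycles_b=((1, 2, 3),))
        assert planted_truth(cfg) == []

    def test_one_sided_ring(self):
        cfg = small_config(planted_cycles_a=((1, 2, 3, 4),))
        assert planted_truth(cfg) == [1, 2, 3, 4]

    def test_overlapping_ring_sets(self):
        cfg = small_config(
            planted_cycles_a=((1, 2, 3),), planted_cycles_b=((1, 2, 3), (4, 5, 6))
        )
        assert planted_truth(cfg) == [4, 5, 6]

    def test_rotated_ring_is_the_same_ring(self):
        cfg = small_config(planted_cycles_a=((1, 2, 3),), planted_cycles_b=((2, 3, 1),))
        assert planted_truth(cfg) == []


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(planted_cycles_a=((1, 2),)),
            dict(planted_cycles_a=((1, 1, 2),)),
            dict(planted_cycles_a=((0, 5, 99),)),
            dict(within_cycle_corr=1.0),
            dict(background_corr=-0.1),
            dict(n_timepoints=2),
            dict(noise_sd=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            small_config(**kw)


class TestPointCloud:
    def test_circle_distances_symmetric_zero_diagonal(self):
        pts = generate_point_cloud(10, "circle", noise_sd=0.0).to_numpy()
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)

    def test_circle_has_one_persistent_loop(self):
        """A noiseless 10-point circle carries exactly one positive-length 1-D bar."""
        pts = generate_point_cloud(10, "circle", noise_sd=0.0).to_numpy()
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d)
        stream = build_simplex_stream(dm, FiltrationConfig(d_max=2, t_max=2.0))
        barcode = reduce_boundary_matrix(stream)
        positive = [iv for iv in barcode.dim(1) if iv.death > iv.birth]
        assert len(positive) == 1

    def test_unknown_shape_rejected(self):
        with pytest.raises(ConfigError, match="shape"):
            generate_point_cloud(5, "torus")

    def test_deterministic_under_seed(self):
        a = generate_point_cloud(20, "uniform_square", 0.1, seed=5)
        b = generate_point_cloud(20, "uniform_square", 0.1, seed=5)
        assert a.equals(b)
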