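import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fcnc import (
    BettiCurve,
    bh_fdr,
    betti_curve_group_test,
    compare_groups,
    ks_two_sample,
    mann_whitney_u,
)
from fcnc.errors import DataError


def brute_force_bh(p):
    """Independent step-up oracle: literal definition on sorted order statistics."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)), 1.0
        )
    return q


class TestMannWhitney:
    def test_identical_samples_full_ties(self):
        x = [2.0, 2.0, 2.0]
        u, p = mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2.0)
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(2.0 / 20.0)

    def test_exact_equals_enumeration_oracle(self):
        """Exact mode reproduces direct enumeration of all label assignments."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n1, n2 = rng.integers(2, 7, size=2)
            pooled = np.round(rng.normal(size=n1 + n2), 1)  # induce ties
            x, y = pooled[:n1], pooled[n1:]
            u_obs, p = mann_whitney_u(x, y)
            mu = n1 * n2 / 2.0

            def u_of(idx):
                ranks = sps.rankdata(pooled)
                return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

            devs = [
                abs(u_of(idx) - mu)
                for idx in itertools.combinations(range(n1 + n2), n1)
            ]
            expected = np.mean(
                [d >= abs(u_obs - mu) - 1e-12 for d in devs]
            )
            assert p == pytest.approx(expected)

    def test_approximation_close_to_exact(self):
        """Normal approximation with continuity/tie correction tracks the exact
        p-value on small samples."""
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(100):
            x = rng.normal(size=6)
            y = rng.normal(loc=rng.uniform(0, 1.5), size=6)
            _, p_exact = mann_whitney_u(x, y)
            p_approx = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
            diffs.append(abs(p_exact - p_approx))
        assert np.mean(diffs) < 0.01
        assert np.max(diffs) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            mann_whitney_u([], [1.0])


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.003, 0.006, 0.005), (0.006, 0.006, 0.006)),
            ((0.035, 0.010, 0.008), (0.035, 0.015, 0.015)),
            ((0.05,), (0.05,)),
        ],
    )
    def test_known_triples(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = rng.uniform(size=m)
            np.testing.assert_array_equal(bh_fdr(p), brute_force_bh(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(2, 30)))
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_fdr(p), q_sm)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_qvalues_bounded_and_order_preserving(self, p):
        q = bh_fdr(p)
        assert np.all((q >= 0) & (q <= 1))
        assert np.all(q >= min(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(DataError):
            bh_fdr([0.1, 1.5])


class TestKsTwoSample:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.D == 0.0

    def test_disjoint_supports(self):
        r = ks_two_sample([0.0, 1.0], [5.0, 6.0, 7.0])
        assert r.D == 1.0

    def test_z_scaling(self):
        x = np.arange(8.0)
        y = np.arange(8.0) + 4.0  # D = 0.5 by construction
        r = ks_two_sample(x, y)
        assert r.D == pytest.approx(0.5)
        assert r.Z == pytest.approx(1.0)

    def test_d_matches_scipy(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(3, 40)))
            y = rng.normal(loc=0.3, size=int(rng.integers(3, 40)))
            assert ks_two_sample(x, y).D == pytest.approx(
                sps.ks_2samp(x, y, method="asymp").statistic
            )


def make_features(counts_by_group, thresholds=(0.7, 0.8, 0.9)):
    """counts_by_group: {group: {scan_id: count}} replicated over thresholds."""
    rows = []
    for group, scans in counts_by_group.items():
        for scan_id, count in scans.items():
            for t in thresholds:
                rows.append(
                    dict(
                        scan_id=scan_id, group=group, threshold=t,
                        feature_type="region", feature="r0", count=count,
                    )
                )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_never_significant(self):
        counts = {f"s{k}": k for k in range(6)}
        feats = make_features(
            {"A": counts, "B": {f"t{k}": v for k, v in counts.items()}}
        )
        out = compare_groups(feats)
        assert np.allclose(out["p_value"], 1.0)
        assert not out["significant"].any()

    def test_single_scan_group_rejected(self):
        feats = make_features({"A": {"s0": 1}, "B": {"t0": 1, "t1": 2}})
        with pytest.raises(DataError, match="at least 2"):
            compare_groups(feats)

    def test_within_feature_family_matches_bh_on_triples(self):
        rng = np.random.default_rng(5)
        feats = []
        for region in ("r0", "r1"):
            for group, loc in (("A", 0.0), ("B", 1.0)):
                for k in range(8):
                    for t in (0.7, 0.8, 0.9):
                        feats.append(
                            dict(
                                scan_id=f"{group}{k}", group=group, threshold=t,
                                feature_type="region", feature=region,
                                count=float(rng.normal(loc + t, 1.0)),
                            )
                        )
        out = compare_groups(pd.DataFrame(feats), fdr_scope="within_feature")
        for _, sub in out.groupby("feature"):
            np.testing.assert_allclose(
                sub["q_value"].to_numpy(), bh_fdr(sub["p_value"].to_numpy())
            )


class TestBettiCurveGroupTest:
    def grid(self):
        return np.linspace(0.0, 0.9, 10)

    def curve(self, beta1, scan_id=""):
        g = self.grid()
        return BettiCurve(g, np.ones_like(g, dtype=int), np.asarray(beta1), scan_id)

    def test_identical_curves_give_zero_d(self):
        curves = [self.curve(np.arange(10)) for _ in range(3)]
        r0, r1 = betti_curve_group_test(curves, curves)
        assert r0.D == 0.0 and r1.D == 0.0

    def test_shifted_beta1_mass(self):
        """Group B identical to A but with beta1 shifted by +1 everywhere: the
        ECDF gap equals the step of the discrete support."""
        a = [self.curve(np.zeros(10)), self.curve(np.ones(10))]
        b = [self.curve(np.ones(10)), self.curve(np.full(10, 2.0))]
        _, r1 = betti_curve_group_test(a, b)
        # pooled A is half 0s half 1s; pooled B half 1s half 2s -> D = 0.5
        assert r1.D == pytest.approx(0.5)

    def test_z_d_consistency(self):
        rng = np.random.default_rng(21)
        a = [self.curve(rng.integers(0, 5, 10)) for _ in range(4)]
        b = [self.curve(rng.integers(0, 6, 10)) for _ in range(3)]
        r0, r1 = betti_curve_group_test(a, b)
        n1 = n2 = None
        n1, n2 = 4 * 10, 3 * 10
        for r in (r0, r1):
            if r.D > 0:
                assert r.Z / r.D == pytest.approx(
                    np.sqrt(n1 * n2 / (n1 + n2)), abs=1e-12
                )

    def test_grid_mismatch_rejected(self):
        a = [self.curve(np.zeros(10))]
        g = np.linspace(0.0, 1.0, 10)
        b = [BettiCurve(g, np.ones(10, dtype=int), np.zeros(10))]
        with pytest.raises(DataError, match="grid"):
            betti_curve_group_test(a, b)
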