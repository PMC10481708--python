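"""Two-group statistics for FCNC features and Betti curves.

The battery mirrors standard nonparametric practice for small
neuroimaging groups:

* Mann-Whitney U per feature and threshold, two-sided. For combined sample
  sizes up to 12 the p-value comes from exact enumeration of all label
  assignments (which also handles ties correctly by permutation); larger
  samples use the normal approximation with tie and continuity correction.
* Benjamini-Hochberg step-up FDR. The default family is the set of
  thresholds *within one feature* (m = number of thresholds, typically 3),
  i.e. each region's three p-values are corrected together; a global family
  across all features and thresholds is available via ``fdr_scope``.
* Two-sample Kolmogorov-Smirnov on pooled Betti-curve values, reporting
  D = sup |ECDF_a - ECDF_b|, Z = D * sqrt(n_a n_b / (n_a + n_b)) and the
  asymptotic two-sided p from the Kolmogorov distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .errors import ConfigError, DataError
from .homology import BettiCurve

__all__ = [
    "KsResult",
    "mann_whitney_u",
    "bh_fdr",
    "ks_two_sample",
    "compare_groups",
    "betti_curve_group_test",
]

_EXACT_LIMIT = 12  # combined sample size up to which U is enumerated exactly


@dataclass(frozen=True)
class KsResult:
    """Two-sample KS summary: max ECDF gap D, scaled statistic Z, asymptotic p."""

    D: float
    Z: float
    p: float


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for the x sample, via midranks (ties get average rank)."""
    n1 = len(x)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for x, p).

    Exact enumeration of all C(n1+n2, n1) group labelings when
    n1 + n2 <= 12 (two-sided p = proportion of labelings with |U - n1 n2/2|
    at least the observed deviation); otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("Mann-Whitney samples must be nonempty")
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if n1 + n2 <= _EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min over j >= i of p_(j) * m / j on the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise DataError("p_values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ks_two_sample(x, y) -> KsResult:
    """Two-sample Kolmogorov-Smirnov with the asymptotic p-value.

    D is the exact sup of |ECDF_x - ECDF_y| over the pooled values;
    Z = D * sqrt(n1 n2 / (n1 + n2)); p = Q_KS(Z), the Kolmogorov survival
    function.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise DataError("KS samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n1
    cdf_y = np.searchsorted(y, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    z = d * math.sqrt(n1 * n2 / (n1 + n2))
    return KsResult(d, z, float(special.kolmogorov(z)))


def compare_groups(
    features: pd.DataFrame,
    alpha: float = 0.05,
    fdr_scope: str = "within_feature",
) -> pd.DataFrame:
    """Per-feature, per-threshold two-group comparison of FCNC counts.

    ``features`` is the long-format table from
    :func:`fcnc.features.per_scan_feature_table` (columns scan_id, group,
    threshold, feature_type, feature, count) with exactly two groups.
    Returns one row per (feature_type, feature, threshold) with group means
    and SDs, the U statistic, p, BH q and a boolean significance column.

    ``fdr_scope`` chooses the BH family: ``"within_feature"`` corrects each
    feature's p-values across its thresholds (m = number of thresholds);
    ``"global"`` corrects all rows jointly.
    """
    if fdr_scope not in ("within_feature", "global"):
        raise ConfigError(f"unknown fdr_scope {fdr_scope!r}")
    required = {"scan_id", "group", "threshold", "feature_type", "feature", "count"}
    missing = required - set(features.columns)
    if missing:
        raise DataError(f"feature table missing columns: {sorted(missing)}")
    groups = sorted(features["group"].unique())
    if len(groups) != 2:
        raise DataError(f"need exactly two groups, got {groups}")
    ga, gb = groups
    n_a = features.loc[features["group"] == ga, "scan_id"].nunique()
    n_b = features.loc[features["group"] == gb, "scan_id"].nunique()
    if n_a < 2 or n_b < 2:
        raise DataError("each group needs at least 2 scans")

    rows = []
    for (ftype, feat, thr), sub in features.groupby(
        ["feature_type", "feature", "threshold"], sort=True
    ):
        xa = sub.loc[sub["group"] == ga, "count"].to_numpy(dtype=float)
        xb = sub.loc[sub["group"] == gb, "count"].to_numpy(dtype=float)
        u, p = mann_whitney_u(xa, xb)
        rows.append(
            {
                "feature_type": ftype,
                "feature": feat,
                "threshold": thr,
                "mean_a": xa.mean(),
                "sd_a": xa.std(ddof=1),
                "mean_b": xb.mean(),
                "sd_b": xb.std(ddof=1),
                "n_a": len(xa),
                "n_b": len(xb),
                "U": u,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if fdr_scope == "global":
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    else:
        out["q_value"] = np.nan
        for _, idx in out.groupby(["feature_type", "feature"]).groups.items():
            out.loc[idx, "q_value"] = bh_fdr(out.loc[idx, "p_value"].to_numpy())
    out["significant"] = out["q_value"] < alpha
    return out


def betti_curve_group_test(
    curves_a: list[BettiCurve], curves_b: list[BettiCurve]
) -> tuple[KsResult, KsResult]:
    """KS comparison of pooled Betti-number distributions, dims 0 and 1.

    Within each group, every scan's Betti values at every grid point are
    pooled into one sample per dimension; the two groups' pooled samples
    are then compared with :func:`ks_two_sample`.
    """
    if not curves_a or not curves_b:
        raise DataError("both groups need at least one Betti curve")
    grid = curves_a[0].grid
    for c in curves_a + curves_b:
        if len(c.grid) != len(grid) or not np.allclose(c.grid, grid):
            raise DataError("Betti curves do not share a common grid")
    pool = lambda curves, attr: np.concatenate([getattr(c, attr) for c in curves])
    res0 = ks_two_sample(pool(curves_a, "beta0"), pool(curves_b, "beta0"))
    res1 = ks_two_sample(pool(curves_a, "beta1"), pool(curves_b, "beta1"))
    return res0, res1
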