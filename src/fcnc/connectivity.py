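"""Functional connectivity from ROI time series.

A scan is a table of region-averaged signals P(j) = {P_1(j), ..., P_n(j)},
one column per brain region. Functional connectivity between regions i and
j is the sample Pearson correlation of their signal columns,

    m_ij = corr(P_i, P_j),

and the metric fed to the Vietoris-Rips filtration is

    d(P_i, P_j) = 1 - corr(P_i, P_j),

so strongly positively correlated regions are close (d near 0) and
anti-correlated regions are far (d near 2). Note d is symmetric with zero
diagonal but does not in general satisfy the triangle inequality; nothing
downstream assumes it does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import default_labels
from .errors import DataError, ZeroVarianceError

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "DistanceMatrix",
    "pearson_fc",
    "corr_to_distance",
    "read_scan",
    "write_scan",
    "read_matrix",
    "write_matrix",
]


def _check_labels(labels: list[str], n: int) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise DataError(f"expected {n} region labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise DataError(f"duplicate region labels: {', '.join(dupes)}")
    return labels


@dataclass
class RoiTimeSeries:
    """One scan's region-averaged signals: rows are time points, columns regions."""

    values: np.ndarray
    region_labels: list[str] | None = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("time series must be a 2-D array (time x regions)")
        if self.values.shape[0] < 3:
            raise DataError(
                f"need at least 3 time points, got {self.values.shape[0]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"scan {self.scan_id!r} contains non-finite values")
        if self.region_labels is None:
            self.region_labels = default_labels(self.n_regions)
        self.region_labels = _check_labels(self.region_labels, self.n_regions)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def zero_variance_labels(self) -> list[str]:
        """Labels of regions whose signal is constant over time."""
        sd = self.values.std(axis=0)
        return [lab for lab, s in zip(self.region_labels, sd) if s == 0.0]

    def reorder(self, labels: list[str]) -> "RoiTimeSeries":
        """Return a copy with columns permuted into the given label order."""
        pos = {lab: k for k, lab in enumerate(self.region_labels)}
        missing = [lab for lab in labels if lab not in pos]
        if missing or len(labels) != self.n_regions:
            raise DataError(
                f"scan {self.scan_id!r}: region labels do not match requested order"
            )
        idx = [pos[lab] for lab in labels]
        return RoiTimeSeries(self.values[:, idx], list(labels), self.scan_id)


def _check_square(m: np.ndarray, what: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DataError(f"{what} must be square, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise DataError(f"{what} contains non-finite values")
    if not np.allclose(m, m.T, atol=1e-12, rtol=0.0):
        raise DataError(f"{what} is not symmetric")
    return m


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson-correlation matrix with unit diagonal."""

    r: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = _check_square(self.r, "connectivity matrix")
        n = self.r.shape[0]
        if not self.region_labels:
            self.region_labels = default_labels(n)
        self.region_labels = _check_labels(self.region_labels, n)
        if np.any(np.abs(self.r) > 1.0 + 1e-12):
            raise DataError("correlations outside [-1, 1]")
        if not np.all(np.diag(self.r) == 1.0):
            raise DataError("connectivity diagonal must be exactly 1")

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarity matrix with zero diagonal; entries in [0, 2]."""

    d: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = _check_square(self.d, "distance matrix")
        n = self.d.shape[0]
        if not self.region_labels:
            self.region_labels = default_labels(n)
        self.region_labels = _check_labels(self.region_labels, n)
        if np.any(self.d < -1e-12) or np.any(self.d > 2.0 + 1e-12):
            raise DataError("distances must lie in [0, 2]")
        if not np.all(np.diag(self.d) == 0.0):
            raise DataError("distance diagonal must be exactly 0")

    @property
    def n_regions(self) -> int:
        return self.d.shape[0]


def pearson_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson functional-connectivity matrix of one scan.

    Raises :class:`ZeroVarianceError` (listing the offending labels) if any
    region has constant signal, rather than silently emitting NaN or 0.
    """
    bad = ts.zero_variance_labels()
    if bad:
        raise ZeroVarianceError(bad)
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, list(ts.region_labels))


def corr_to_distance(c: ConnectivityMatrix) -> DistanceMatrix:
    """Elementwise d_ij = 1 - r_ij, with an exactly-zero diagonal.

    Negative correlations map to d > 1; with the usual filtration cap
    t_max = 0.9 such pairs never form an edge.
    """
    d = 1.0 - c.r
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(c.region_labels))


# ---------------------------------------------------------------------------
# Delimited-text I/O


def write_scan(ts: RoiTimeSeries, path) -> None:
    """Write one scan as TSV: header row of region labels, one row per time point."""
    pd.DataFrame(ts.values, columns=ts.region_labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_scan(path, scan_id: str = "") -> RoiTimeSeries:
    """Read a scan written by :func:`write_scan` (or any labelled TSV of signals)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed file: surface path context
        raise DataError(f"cannot parse scan file {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise DataError(f"scan file {path} has no columns")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        raise DataError(f"scan file {path}: non-numeric columns {bad}")
    return RoiTimeSeries(values, [str(c) for c in df.columns], scan_id or str(path))


def write_matrix(m, path) -> None:
    """Write a connectivity or distance matrix as TSV with label header row/column."""
    arr = m.r if isinstance(m, ConnectivityMatrix) else m.d
    pd.DataFrame(arr, index=m.region_labels, columns=m.region_labels).to_csv(
        path, sep="\t", float_format="%.17g"  # full precision: these feed the filtration
    )


def read_matrix(path, kind: str = "distance"):
    """Read a matrix written by :func:`write_matrix`; ``kind`` is 'distance' or 'connectivity'."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise DataError(f"cannot parse matrix file {path}: {exc}") from exc
    if list(df.index) != list(df.columns):
        raise DataError(f"matrix file {path}: row and column labels differ")
    labels = [str(c) for c in df.columns]
    if kind == "distance":
        return DistanceMatrix(df.to_numpy(), labels)
    if kind == "connectivity":
        return ConnectivityMatrix(df.to_numpy(), labels)
    raise ValueError(f"unknown matrix kind {kind!r}")
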