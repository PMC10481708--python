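"""Functional-connectivity neural circuit (FCNC) features from 1-D barcodes.

An FCNC is a 1-dimensional cycle in a scan's VR complex, localised by the
representative edge set of its persistence interval. At a threshold delta
the scan's FCNC set is *cumulative in births*: every dim-1 interval with
birth <= delta counts, whether or not the hole has already filled in. This
makes per-region counts non-decreasing in delta, which is the behaviour the
features are designed to have (a circuit that existed at a smaller scale is
still a circuit of the network at a larger one).

Two summaries are derived per scan and threshold:

* per-region involvement — for each region, the number of circuits whose
  representative touches it;
* length counts — the number of circuits with a given number of edges
  (e.g. "medium-length" circuits of length 8).

Both depend on the representative-cycle convention of the reduction
(reduced-column cycle at birth); a different localisation of the same bars
could shift individual counts. That caveat is inherent to localising
homology classes and is documented rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .homology import Barcode

__all__ = [
    "FcncRecord",
    "extract_fcnc",
    "region_counts",
    "count_by_length",
    "per_scan_feature_table",
]


@dataclass(frozen=True)
class FcncRecord:
    """One 1-dimensional cycle counted at a threshold."""

    scan_id: str
    threshold: float
    cycle_id: int
    member_regions: frozenset[int]
    length: int  # number of edges in the representative
    birth: float
    death: float

    def __post_init__(self) -> None:
        if self.length < 3:
            raise DataError(f"cycle of length {self.length} < 3 is impossible")
        if self.length < len(self.member_regions):
            raise DataError("representative has more regions than edges")


def extract_fcnc(barcode: Barcode, delta: float, scan_id: str = "") -> list[FcncRecord]:
    """All circuits born at or below delta, with their representatives.

    Records are ordered by (birth, death); cycle_id numbers them within the
    scan/threshold batch.
    """
    t_max = barcode.config.t_max
    if not (0.0 <= delta <= t_max):
        raise ConfigError(f"threshold {delta} outside [0, {t_max}]")
    scan_id = scan_id or barcode.scan_id
    records = []
    ivs = sorted(barcode.dim(1), key=lambda iv: (iv.birth, iv.death))
    for k, iv in enumerate(ivs):
        if iv.birth <= delta:
            rep = iv.representative or ()
            members = frozenset(v for edge in rep for v in edge)
            records.append(
                FcncRecord(
                    scan_id, delta, k, members, len(rep), iv.birth, iv.death
                )
            )
    return records


def region_counts(records: list[FcncRecord], n_regions: int) -> np.ndarray:
    """Per-region circuit involvement for one scan/threshold batch.

    ``counts[r]`` is the number of records whose member regions contain r.
    """
    counts = np.zeros(n_regions, dtype=np.int64)
    for rec in records:
        for r in rec.member_regions:
            if not (0 <= r < n_regions):
                raise DataError(f"region index {r} outside [0, {n_regions})")
            counts[r] += 1
    return counts


def count_by_length(records: list[FcncRecord], length: int) -> int:
    """Number of circuits with exactly the given number of edges."""
    if length < 3:
        raise ConfigError("cycle length must be >= 3")
    return sum(1 for rec in records if rec.length == length)


def per_scan_feature_table(
    barcodes: list[tuple[str, str, Barcode]],
    thresholds: list[float],
    lengths: list[int],
    n_regions: int,
    region_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format feature table across scans, thresholds and feature kinds.

    ``barcodes`` is a list of (scan_id, group, Barcode). Output columns:
    scan_id, group, threshold, feature_type ('region' or 'length'),
    feature (region label or cycle length), count.
    """
    ids = [sid for sid, _, _ in barcodes]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate scan ids in feature table input")
    if region_labels is not None and len(region_labels) != n_regions:
        raise DataError("region_labels length does not match n_regions")
    labels = region_labels or [str(r) for r in range(n_regions)]
    rows = []
    for scan_id, group, barcode in barcodes:
        for delta in thresholds:
            records = extract_fcnc(barcode, delta, scan_id)
            counts = region_counts(records, n_regions)
            for r in range(n_regions):
                rows.append(
                    {
                        "scan_id": scan_id,
                        "group": group,
                        "threshold": delta,
                        "feature_type": "region",
                        "feature": labels[r],
                        "count": int(counts[r]),
                    }
                )
            for length in lengths:
                rows.append(
                    {
                        "scan_id": scan_id,
                        "group": group,
                        "threshold": delta,
                        "feature_type": "length",
                        "feature": str(int(length)),
                        "count": count_by_length(records, length),
                    }
                )
    return pd.DataFrame(rows)


def feature_schema() -> pd.DataFrame:
    """Column documentation for the feature table, written alongside exports."""
    return pd.DataFrame(
        [
            ("scan_id", "scan identifier, unique within a run"),
            ("group", "group label (two groups per run)"),
            ("threshold", "filtration threshold delta at which circuits are counted"),
            ("feature_type", "'region' (per-region involvement) or 'length' (circuits of a given edge count)"),
            ("feature", "region label, or cycle length as a string"),
            ("count", "number of circuits: touching the region, or of that length"),
        ],
        columns=["column", "meaning"],
    )
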