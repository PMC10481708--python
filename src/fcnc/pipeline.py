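"""End-to-end orchestration: simulate/load -> connectivity -> filtration ->
persistence -> FCNC features -> group statistics.

A run is described by a :class:`RunConfig` (loadable from YAML). Input
modes:

* ``synthetic`` — generate two groups from a :class:`SimulationConfig`;
* ``files`` — read a manifest table (scan_id, group, path) of ROI
  time-series TSVs;
* ``distance`` — read pre-computed distance matrices listed in a manifest,
  bypassing the connectivity stage (useful for toy geometric inputs).

Outputs are plain delimited text in a deterministic layout under the run's
output directory; identical config and seed give identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    DistanceMatrix,
    RoiTimeSeries,
    corr_to_distance,
    pearson_fc,
    read_matrix,
    read_scan,
    write_matrix,
)
from .errors import ConfigError, DataError
from .features import feature_schema, per_scan_feature_table
from .filtration import FiltrationConfig, build_simplex_stream
from .homology import Barcode, betti_curve, reduce_boundary_matrix
from .stats import betti_curve_group_test, compare_groups
from .synthetic import SimulationConfig, generate_group_timeseries, write_scans

__all__ = ["RunConfig", "run_pipeline", "read_timeseries_manifest", "analyze_scans"]

log = logging.getLogger("fcnc")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    input_mode: str = "synthetic"  # synthetic | files | distance
    simulation: SimulationConfig | None = None
    manifest_path: str | None = None
    filtration: FiltrationConfig = field(default_factory=FiltrationConfig)
    thresholds: tuple[float, ...] = (0.7, 0.8, 0.9)
    medium_length: int = 8
    alpha: float = 0.05
    fdr_scope: str = "within_feature"
    output_dir: str = "fcnc_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "files", "distance"):
            raise ConfigError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "synthetic" and self.simulation is None:
            raise ConfigError("synthetic mode requires a simulation section")
        if self.input_mode in ("files", "distance") and not self.manifest_path:
            raise ConfigError(f"{self.input_mode} mode requires manifest_path")
        for t in self.thresholds:
            if not (0.0 < t <= self.filtration.t_max):
                raise ConfigError(
                    f"threshold {t} outside (0, t_max={self.filtration.t_max}]"
                )
        if self.medium_length < 3:
            raise ConfigError("medium_length must be >= 3")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        try:
            sim = raw.pop("simulation", None)
            filt = raw.pop("filtration", None)
            kwargs = dict(raw)
            if sim is not None:
                sim = dict(sim)
                for key in ("planted_cycles_a", "planted_cycles_b"):
                    if key in sim:
                        sim[key] = tuple(tuple(ring) for ring in sim[key])
                kwargs["simulation"] = SimulationConfig(**sim)
            if filt is not None:
                kwargs["filtration"] = FiltrationConfig(**dict(filt))
            if "thresholds" in kwargs:
                kwargs["thresholds"] = tuple(float(t) for t in kwargs["thresholds"])
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc


def read_timeseries_manifest(path) -> list[tuple[str, str, RoiTimeSeries]]:
    """Read a manifest of scans; returns (scan_id, group, time series) triples.

    All scans must share one region-label set (scans with permuted columns
    are reordered to the first scan's label order) and there must be
    exactly two groups.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"manifest {path} does not exist")
    manifest = pd.read_csv(path, sep="\t")
    required = {"scan_id", "group", "path"}
    if not required.issubset(manifest.columns):
        raise DataError(f"manifest {path} must have columns {sorted(required)}")
    groups = sorted(manifest["group"].astype(str).unique())
    if len(groups) != 2:
        raise DataError(f"manifest must define exactly 2 groups, found {groups}")
    if manifest["scan_id"].duplicated().any():
        dupes = manifest.loc[manifest["scan_id"].duplicated(), "scan_id"].tolist()
        raise DataError(f"duplicate scan ids in manifest: {dupes}")
    out = []
    canonical: list[str] | None = None
    for row in manifest.itertuples(index=False):
        scan_path = Path(str(row.path))
        if not scan_path.is_absolute():
            scan_path = path.parent / scan_path
        ts = read_scan(scan_path, str(row.scan_id))
        if canonical is None:
            canonical = list(ts.region_labels)
        elif set(ts.region_labels) != set(canonical):
            raise DataError(
                f"scan {row.scan_id}: region labels differ from first scan"
            )
        elif ts.region_labels != canonical:
            ts = ts.reorder(canonical)
        out.append((str(row.scan_id), str(row.group), ts))
    return out


def scan_barcode(ts: RoiTimeSeries, filtration: FiltrationConfig) -> Barcode:
    """Connectivity -> distance -> VR stream -> barcode for one scan."""
    d = corr_to_distance(pearson_fc(ts))
    return distance_barcode(d, filtration, ts.scan_id)


def distance_barcode(
    d: DistanceMatrix, filtration: FiltrationConfig, scan_id: str = ""
) -> Barcode:
    stream = build_simplex_stream(d, filtration)
    barcode = reduce_boundary_matrix(stream)
    barcode.scan_id = scan_id
    return barcode


def analyze_scans(
    scans: list[tuple[str, str, RoiTimeSeries]],
    filtration: FiltrationConfig,
    thresholds,
    lengths,
    alpha: float = 0.05,
    fdr_scope: str = "within_feature",
) -> dict:
    """In-memory core of the pipeline, shared by :func:`run_pipeline` and tests.

    Returns a dict with barcodes, per-group Betti curves, the feature
    table, the comparison table and the KS results.
    """
    if not scans:
        raise DataError("no scans to analyze")
    labels = scans[0][2].region_labels
    n_regions = scans[0][2].n_regions
    barcodes = []
    curves: dict[str, list] = {}
    for scan_id, group, ts in scans:
        bc = scan_barcode(ts, filtration)
        barcodes.append((scan_id, group, bc))
        curves.setdefault(group, []).append(betti_curve(bc))
    groups = sorted(curves)
    if len(groups) != 2:
        raise DataError(f"need exactly two groups, got {groups}")
    features = per_scan_feature_table(
        barcodes, list(thresholds), list(lengths), n_regions, labels
    )
    comparison = compare_groups(features, alpha=alpha, fdr_scope=fdr_scope)
    ks0, ks1 = betti_curve_group_test(curves[groups[0]], curves[groups[1]])
    return {
        "groups": groups,
        "region_labels": labels,
        "barcodes": barcodes,
        "curves": curves,
        "features": features,
        "comparison": comparison,
        "ks": {"dim0": ks0, "dim1": ks1},
    }


def _mean_curve_table(curves: dict[str, list]) -> pd.DataFrame:
    grid = next(iter(curves.values()))[0].grid
    data = {"delta": grid}
    for group in sorted(curves):
        data[f"beta0_mean_{group}"] = np.mean([c.beta0 for c in curves[group]], axis=0)
        data[f"beta1_mean_{group}"] = np.mean([c.beta1 for c in curves[group]], axis=0)
    return pd.DataFrame(data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute one full run and write its artifacts; returns a summary dict."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.input_mode == "synthetic":
        sim = config.simulation
        if config.seed != sim.seed:
            sim = SimulationConfig(**{**asdict(sim), "seed": config.seed})
        log.info("simulating %d + %d scans", sim.n_scans_a, sim.n_scans_b)
        group_a, group_b = generate_group_timeseries(sim)
        write_scans((group_a, group_b), outdir / "scans")
        scans = [(ts.scan_id, "A", ts) for ts in group_a] + [
            (ts.scan_id, "B", ts) for ts in group_b
        ]
    elif config.input_mode == "files":
        scans = read_timeseries_manifest(config.manifest_path)
    else:  # distance mode: manifest points at distance-matrix TSVs
        manifest = pd.read_csv(config.manifest_path, sep="\t")
        required = {"scan_id", "group", "path"}
        if not required.issubset(manifest.columns):
            raise DataError(
                f"manifest must have columns {sorted(required)}"
            )
        scans = []
        base = Path(config.manifest_path).parent
        for row in manifest.itertuples(index=False):
            p = Path(str(row.path))
            dmat = read_matrix(p if p.is_absolute() else base / p, "distance")
            scans.append((str(row.scan_id), str(row.group), dmat))

    matdir = outdir / "matrices"
    bcdir = outdir / "barcodes"
    matdir.mkdir(exist_ok=True)
    bcdir.mkdir(exist_ok=True)

    if config.input_mode == "distance":
        barcodes, curves = [], {}
        labels = scans[0][2].region_labels
        n_regions = scans[0][2].n_regions
        for scan_id, group, dmat in scans:
            write_matrix(dmat, matdir / f"{scan_id}_d.tsv")
            bc = distance_barcode(dmat, config.filtration, scan_id)
            bc.write(bcdir / f"{scan_id}_barcode.tsv")
            barcodes.append((scan_id, group, bc))
            curves.setdefault(group, []).append(betti_curve(bc))
        groups = sorted(curves)
        if len(groups) != 2:
            raise DataError(f"need exactly two groups, got {groups}")
        features = per_scan_feature_table(
            barcodes,
            list(config.thresholds),
            [config.medium_length],
            n_regions,
            labels,
        )
        comparison = compare_groups(
            features, alpha=config.alpha, fdr_scope=config.fdr_scope
        )
        ks0, ks1 = betti_curve_group_test(curves[groups[0]], curves[groups[1]])
        result = {
            "groups": groups,
            "region_labels": labels,
            "barcodes": barcodes,
            "curves": curves,
            "features": features,
            "comparison": comparison,
            "ks": {"dim0": ks0, "dim1": ks1},
        }
    else:
        for scan_id, _group, ts in scans:
            c = pearson_fc(ts)
            write_matrix(c, matdir / f"{scan_id}_r.tsv")
            write_matrix(corr_to_distance(c), matdir / f"{scan_id}_d.tsv")
        result = analyze_scans(
            scans,
            config.filtration,
            config.thresholds,
            [config.medium_length],
            alpha=config.alpha,
            fdr_scope=config.fdr_scope,
        )
        for scan_id, _group, bc in result["barcodes"]:
            bc.write(bcdir / f"{scan_id}_barcode.tsv")

    _mean_curve_table(result["curves"]).to_csv(
        outdir / "betti_curves_mean.tsv", sep="\t", index=False, float_format="%.10g"
    )
    result["features"].to_csv(
        outdir / "features.tsv", sep="\t", index=False, float_format="%.10g"
    )
    feature_schema().to_csv(outdir / "features_schema.tsv", sep="\t", index=False)
    comparison = result["comparison"]
    comparison[comparison["feature_type"] == "region"].to_csv(
        outdir / "comparison_regions.tsv", sep="\t", index=False, float_format="%.6g"
    )
    comparison[comparison["feature_type"] == "length"].to_csv(
        outdir / "comparison_lengths.tsv", sep="\t", index=False, float_format="%.6g"
    )
    ks0, ks1 = result["ks"]["dim0"], result["ks"]["dim1"]
    pd.DataFrame(
        [
            {"dimension": 0, "D": ks0.D, "Z": ks0.Z, "p": ks0.p},
            {"dimension": 1, "D": ks1.D, "Z": ks1.Z, "p": ks1.p},
        ]
    ).to_csv(outdir / "ks_tests.tsv", sep="\t", index=False, float_format="%.6g")

    sig = comparison[comparison["significant"]]
    summary = {
        "version": __version__,
        "seed": config.seed,
        "input_mode": config.input_mode,
        "n_scans": len(scans),
        "groups": result["groups"],
        "n_regions": len(result["region_labels"]),
        "thresholds": list(config.thresholds),
        "medium_length": config.medium_length,
        "alpha": config.alpha,
        "fdr_scope": config.fdr_scope,
        "significant_regions": sorted(
            sig.loc[sig["feature_type"] == "region", "feature"].unique().tolist()
        ),
        "significant_lengths": sorted(
            sig.loc[sig["feature_type"] == "length", "feature"].unique().tolist()
        ),
        "ks": {
            "dim0": {"D": ks0.D, "Z": ks0.Z, "p": ks0.p},
            "dim1": {"D": ks1.D, "Z": ks1.Z, "p": ks1.p},
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    result["summary"] = summary
    return result
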