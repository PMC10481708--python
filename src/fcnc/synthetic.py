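"""Synthetic two-group ROI time series with known topological ground truth.

Each group is drawn from a zero-mean multivariate normal whose population
correlation matrix embeds "planted rings": cyclically ordered sets of
regions whose *ring-adjacent* pairs get an elevated correlation
(``within_cycle_corr``) while every other pair — including the ring's
chords — stays at ``background_corr``. Because only ring-adjacent pairs are
strengthened, the planted structure is a genuine 1-cycle in the resulting
correlation geometry (short ring edges, long chords), not a filled clique,
so the 1-dimensional Betti number of the population Vietoris-Rips complex
picks it up by construction.

A requested combination of correlations need not be positive semidefinite
(a ring with strong adjacency and weak chords typically is not); the target
matrix is then projected to the nearest PSD matrix by eigenvalue clipping
and renormalised to unit diagonal. The realised ring correlations are
therefore attenuated relative to the request — :func:`target_correlation`
returns the matrix actually used, which is also the population truth that
tests should compare against.

The generator deliberately omits hemodynamics, spatial noise and motion:
it emulates only the covariance structure of region-averaged signals, with
a single population matrix per group (no within-group heterogeneity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import RoiTimeSeries
from .atlas import default_labels
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "target_correlation",
    "generate_group_timeseries",
    "generate_point_cloud",
    "planted_truth",
    "write_scans",
]

_PSD_CLIP = 1e-10  # eigenvalue floor for the nearest-PSD projection


Ring = tuple[int, ...]


def _ring_edges(ring: Ring) -> set[frozenset[int]]:
    """Ring-adjacency edges of a cyclically ordered region tuple."""
    k = len(ring)
    return {frozenset((ring[i], ring[(i + 1) % k])) for i in range(k)}


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for a two-group simulation.

    Defaults mirror a resting-state acquisition on the 90-region AAL
    parcellation with 137 volumes of which the first 10 are discarded,
    hence 127 retained time points per scan.
    """

    n_scans_a: int
    n_scans_b: int
    n_regions: int = 90
    n_timepoints: int = 127
    planted_cycles_a: tuple[Ring, ...] = ()
    planted_cycles_b: tuple[Ring, ...] = ()
    within_cycle_corr: float = 0.8
    background_corr: float = 0.1
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "planted_cycles_a",
            tuple(tuple(int(v) for v in ring) for ring in self.planted_cycles_a),
        )
        object.__setattr__(
            self,
            "planted_cycles_b",
            tuple(tuple(int(v) for v in ring) for ring in self.planted_cycles_b),
        )
        if self.n_scans_a < 1 or self.n_scans_b < 1:
            raise ConfigError("each group needs at least one scan")
        if self.n_regions < 1:
            raise ConfigError("n_regions must be positive")
        if self.n_timepoints < 3:
            raise ConfigError("n_timepoints must be at least 3")
        if not (0.0 <= self.within_cycle_corr < 1.0):
            raise ConfigError("within_cycle_corr must lie in [0, 1)")
        if not (0.0 <= self.background_corr < 1.0):
            raise ConfigError("background_corr must lie in [0, 1)")
        if self.noise_sd <= 0.0:
            raise ConfigError("noise_sd must be positive")
        for ring in self.planted_cycles_a + self.planted_cycles_b:
            if len(set(ring)) < 3 or len(set(ring)) != len(ring):
                raise ConfigError(f"ring {ring} must list >= 3 distinct regions")
            if min(ring) < 0 or max(ring) >= self.n_regions:
                raise ConfigError(
                    f"ring {ring} has region indices outside [0, {self.n_regions})"
                )
        # fail fast if the projection cannot produce a usable matrix
        for rings in (self.planted_cycles_a, self.planted_cycles_b):
            target_correlation(self, rings)


def target_correlation(config: SimulationConfig, rings: tuple[Ring, ...]) -> np.ndarray:
    """Population correlation matrix for one group, after PSD projection.

    Builds the requested matrix (unit diagonal, ``within_cycle_corr`` on
    ring-adjacent pairs, ``background_corr`` elsewhere), clips negative
    eigenvalues at 1e-10, and renormalises to unit diagonal. Raises
    :class:`ConfigError` if the projected matrix still fails the PSD check.
    """
    n = config.n_regions
    sigma = np.full((n, n), config.background_corr)
    np.fill_diagonal(sigma, 1.0)
    for ring in rings:
        for e in _ring_edges(ring):
            i, j = tuple(e)
            sigma[i, j] = sigma[j, i] = config.within_cycle_corr
    w, v = np.linalg.eigh(sigma)
    if w.min() < _PSD_CLIP:
        w = np.clip(w, _PSD_CLIP, None)
        sigma = (v * w) @ v.T
        scale = 1.0 / np.sqrt(np.diag(sigma))
        sigma = sigma * scale[:, None] * scale[None, :]
        sigma = (sigma + sigma.T) / 2.0
        np.fill_diagonal(sigma, 1.0)
        wmin = np.linalg.eigvalsh(sigma).min()
        if wmin < -1e-8:
            raise ConfigError(
                "covariance not PSD after projection "
                f"(min eigenvalue {wmin:.3e}) for within_cycle_corr="
                f"{config.within_cycle_corr}, background_corr="
                f"{config.background_corr}, rings={rings}"
            )
    return sigma


def _sample_scans(
    rng: np.random.Generator,
    config: SimulationConfig,
    rings: tuple[Ring, ...],
    n_scans: int,
    prefix: str,
    labels: list[str],
) -> list[RoiTimeSeries]:
    sigma = target_correlation(config, rings)
    w, v = np.linalg.eigh(sigma)
    factor = v * np.sqrt(np.clip(w, 0.0, None))  # Sigma = factor @ factor.T
    scans = []
    for k in range(n_scans):
        z = rng.standard_normal((config.n_timepoints, config.n_regions))
        x = config.noise_sd * (z @ factor.T)
        scans.append(RoiTimeSeries(x, list(labels), f"{prefix}{k:03d}"))
    return scans


def generate_group_timeseries(
    config: SimulationConfig,
) -> tuple[list[RoiTimeSeries], list[RoiTimeSeries]]:
    """Draw both groups' scans; identical configs (same seed) give identical output."""
    rng = np.random.default_rng(config.seed)
    labels = default_labels(config.n_regions)
    group_a = _sample_scans(
        rng, config, config.planted_cycles_a, config.n_scans_a, "A", labels
    )
    group_b = _sample_scans(
        rng, config, config.planted_cycles_b, config.n_scans_b, "B", labels
    )
    return group_a, group_b


def planted_truth(config: SimulationConfig) -> list[int]:
    """Regions expected to differ between groups.

    The union of regions belonging to rings planted in exactly one group;
    rings are identified by their ring-adjacency edge sets, so listing the
    same cycle starting from a different member does not make it "differ".
    """
    edges_a = {frozenset(_ring_edges(r)) for r in config.planted_cycles_a}
    edges_b = {frozenset(_ring_edges(r)) for r in config.planted_cycles_b}
    regions: set[int] = set()
    for ring in config.planted_cycles_a:
        if frozenset(_ring_edges(ring)) not in edges_b:
            regions.update(ring)
    for ring in config.planted_cycles_b:
        if frozenset(_ring_edges(ring)) not in edges_a:
            regions.update(ring)
    return sorted(regions)


def generate_point_cloud(
    n: int, shape: str, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Toy 2-D point clouds with known homology, as an (x, y) coordinate table.

    Shapes: ``circle`` (n points evenly spaced on the unit circle plus
    Gaussian jitter — one persistent 1-cycle), ``two_blobs`` (two Gaussian
    clusters — two components, no cycle), ``uniform_square`` (uniform on
    the unit square — no structure).
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if shape == "circle":
        theta = 2.0 * np.pi * np.arange(n) / n
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        pts = pts + noise_sd * rng.standard_normal((n, 2))
    elif shape == "two_blobs":
        centers = np.array([[0.0, 0.0], [4.0, 0.0]])
        which = np.arange(n) % 2
        pts = centers[which] + max(noise_sd, 1e-12) * rng.standard_normal((n, 2))
    elif shape == "uniform_square":
        pts = rng.uniform(0.0, 1.0, size=(n, 2))
        pts = pts + noise_sd * rng.standard_normal((n, 2))
    else:
        raise ConfigError(f"unknown point-cloud shape {shape!r}")
    return pd.DataFrame(pts, columns=["x", "y"])


def write_scans(
    groups: tuple[list[RoiTimeSeries], list[RoiTimeSeries]],
    outdir,
) -> "pd.DataFrame":
    """Write one TSV per scan plus a manifest table (scan_id, group, path).

    Returns the manifest as a DataFrame; it is also written to
    ``outdir/manifest.tsv``.
    """
    from pathlib import Path

    from .connectivity import write_scan

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for group_name, scans in zip(("A", "B"), groups):
        for ts in scans:
            path = outdir / f"{ts.scan_id}.tsv"
            write_scan(ts, path)
            rows.append({"scan_id": ts.scan_id, "group": group_name, "path": str(path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest


def population_distance(config: SimulationConfig, group: str = "A") -> np.ndarray:
    """Population distance matrix 1 - Sigma for one group's (projected) correlation."""
    rings = config.planted_cycles_a if group == "A" else config.planted_cycles_b
    sigma = target_correlation(config, rings)
    d = 1.0 - sigma
    np.fill_diagonal(d, 0.0)
    return d
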