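"""Filtered Vietoris-Rips complexes up to dimension 2.

The VR complex at scale delta contains every vertex, every edge [ab] with
d(a, b) <= delta, and every higher simplex all of whose edges are present.
Sweeping delta from 0 to t_max yields a nested family
VR(Z, d0) <= VR(Z, d1) <= ... — a filtered simplicial complex. Each simplex
enters at its filtration value: 0 for vertices, d_ij for edges, and the
maximum of the three edge values for triangles.

Exact pairwise distances are used as filtration values; the evenly spaced
grid (``divisions``) is only a reporting device for Betti curves, so
persistence intervals stay exact. Simplices are ordered by
(filtration value, dimension, lexicographic vertices), which makes the
boundary-matrix reduction and its representative cycles reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import DistanceMatrix
from .errors import ConfigError, DataError

__all__ = [
    "FiltrationConfig",
    "FilteredSimplex",
    "SimplexStream",
    "build_simplex_stream",
    "simplex_count",
]


@dataclass(frozen=True)
class FiltrationConfig:
    """VR construction parameters: maximum simplex dimension, maximum
    filtration value and number of grid divisions for Betti-curve sampling."""

    d_max: int = 2
    t_max: float = 0.9
    divisions: int = 450

    def __post_init__(self) -> None:
        if self.d_max not in (1, 2):
            raise ConfigError("d_max must be 1 or 2")
        if not self.t_max > 0:
            raise ConfigError("t_max must be positive")
        if self.divisions < 1:
            raise ConfigError("divisions must be >= 1")

    def grid(self) -> np.ndarray:
        """divisions+1 evenly spaced filtration values on [0, t_max]."""
        return np.linspace(0.0, self.t_max, self.divisions + 1)


@dataclass(frozen=True)
class FilteredSimplex:
    """A simplex (sorted vertex tuple) with the scale at which it enters."""

    vertices: tuple[int, ...]
    filtration_value: float

    @property
    def dim(self) -> int:
        return len(self.vertices) - 1


class SimplexStream:
    """Ordered filtered simplices of a VR complex, up to dimension 2.

    Internally vertices, edges and triangles are kept as arrays in stream
    order (value, then dimension, then lexicographic vertices); iteration
    yields :class:`FilteredSimplex` objects in that global order.
    """

    def __init__(
        self,
        n_vertices: int,
        edges: np.ndarray,
        edge_values: np.ndarray,
        triangles: np.ndarray,
        triangle_values: np.ndarray,
        config: FiltrationConfig,
    ) -> None:
        self.n_vertices = int(n_vertices)
        self.edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        self.edge_values = np.asarray(edge_values, dtype=float)
        self.triangles = np.asarray(triangles, dtype=np.int64).reshape(-1, 3)
        self.triangle_values = np.asarray(triangle_values, dtype=float)
        self.config = config

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def __len__(self) -> int:
        return self.n_vertices + self.n_edges + self.n_triangles

    def __iter__(self):
        for v in range(self.n_vertices):
            yield FilteredSimplex((v,), 0.0)
        simplices = [
            (val, 1, (int(u), int(v)))
            for (u, v), val in zip(self.edges, self.edge_values)
        ] + [
            (val, 2, (int(a), int(b), int(c)))
            for (a, b, c), val in zip(self.triangles, self.triangle_values)
        ]
        simplices.sort()
        for val, _dim, verts in simplices:
            yield FilteredSimplex(verts, float(val))

    def validate(self) -> None:
        """Check face closure and ordering invariants; raise DataError on violation."""
        if np.any(np.diff(self.edge_values) < 0) or np.any(
            np.diff(self.triangle_values) < 0
        ):
            raise DataError("simplex stream not sorted by filtration value")
        edge_val = {
            (int(u), int(v)): val
            for (u, v), val in zip(self.edges, self.edge_values)
        }
        for (a, b, c), val in zip(self.triangles, self.triangle_values):
            faces = [(int(a), int(b)), (int(a), int(c)), (int(b), int(c))]
            for f in faces:
                if f not in edge_val:
                    raise DataError(f"triangle {(a, b, c)} missing edge {f}")
                if edge_val[f] > val:
                    raise DataError(
                        f"triangle {(a, b, c)} enters before its edge {f}"
                    )
            if val != max(edge_val[f] for f in faces):
                raise DataError(
                    f"triangle {(a, b, c)} value is not the max of its edges"
                )

    def to_table(self) -> pd.DataFrame:
        """Stream as a table: dim, v0, v1, v2 (blank where absent), filtration_value."""
        rows = [
            {
                "dim": s.dim,
                "v0": s.vertices[0],
                "v1": s.vertices[1] if s.dim >= 1 else pd.NA,
                "v2": s.vertices[2] if s.dim >= 2 else pd.NA,
                "filtration_value": s.filtration_value,
            }
            for s in self
        ]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False, float_format="%.10g")


def build_simplex_stream(
    d: DistanceMatrix, config: FiltrationConfig | None = None
) -> SimplexStream:
    """Filtered VR complex of a distance matrix, truncated at t_max.

    Vertices enter at 0; edges with d_ij <= t_max enter at d_ij; when
    d_max = 2, every triangle whose three edges are present enters at the
    maximum of its edge values. Triangles are found by intersecting the
    thresholded neighbour sets of each edge's endpoints, which is far
    cheaper than cubic enumeration on dense 90-node matrices.
    """
    config = config or FiltrationConfig()
    dm = d.d
    n = dm.shape[0]

    iu, ju = np.triu_indices(n, k=1)
    vals = dm[iu, ju]
    keep = vals <= config.t_max
    ei, ej, ev = iu[keep], ju[keep], vals[keep]
    order = np.lexsort((ej, ei, ev))
    ei, ej, ev = ei[order], ej[order], ev[order]
    edges = np.column_stack([ei, ej])

    if config.d_max >= 2 and len(ei) > 0:
        adj = (dm <= config.t_max) & ~np.eye(n, dtype=bool)
        tri_rows = []
        for a, b in edges:
            common = np.flatnonzero(adj[a] & adj[b])
            common = common[common > b]  # each triple once, via its two smallest vertices
            for c in common:
                tri_rows.append((a, b, c))
        if tri_rows:
            tris = np.array(tri_rows, dtype=np.int64)
            tv = np.maximum(
                dm[tris[:, 0], tris[:, 1]],
                np.maximum(dm[tris[:, 0], tris[:, 2]], dm[tris[:, 1], tris[:, 2]]),
            )
            torder = np.lexsort((tris[:, 2], tris[:, 1], tris[:, 0], tv))
            tris, tv = tris[torder], tv[torder]
        else:
            tris = np.empty((0, 3), dtype=np.int64)
            tv = np.empty(0)
    else:
        tris = np.empty((0, 3), dtype=np.int64)
        tv = np.empty(0)

    return SimplexStream(n, edges, ev, tris, tv, config)


def simplex_count(stream: SimplexStream, delta: float, dim: int) -> int:
    """Number of simplices of the given dimension with filtration value <= delta."""
    if dim > stream.config.d_max:
        raise ConfigError(f"dim {dim} exceeds d_max {stream.config.d_max}")
    if not (0.0 <= delta <= stream.config.t_max):
        raise ConfigError(f"delta {delta} outside [0, {stream.config.t_max}]")
    if dim == 0:
        return stream.n_vertices
    if dim == 1:
        return int(np.searchsorted(stream.edge_values, delta, side="right"))
    return int(np.searchsorted(stream.triangle_values, delta, side="right"))
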