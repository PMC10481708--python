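"""Persistence barcodes in dimensions 0 and 1, with representative 1-cycles.

The computation is the standard persistence pairing by column reduction of
the boundary matrix over GF(2), processed block-by-block in dimension:

* Edge columns (boundary = their two endpoint vertices) are reduced against
  earlier edge columns. A column that ends nonzero pairs its pivot vertex
  with the edge — a 0-dimensional death: two connected branches merge and,
  by the elder rule, the younger one dies. A column that reduces to zero
  means the edge closed a loop; the set of edges accumulated during its
  reduction is a 1-cycle born at that edge's filtration value and is kept
  as the class representative.
* Triangle columns (boundary = their three edges) are reduced against
  earlier triangle columns. A nonzero final column pairs its pivot edge —
  necessarily a loop-creating one — with the triangle: the 1-dimensional
  hole fills in at the triangle's value.

Classes never killed below t_max are right-censored with death = infinity.
Columns are Python integers used as GF(2) bit vectors (bit k = row k in
stream order), so column addition is a single XOR.

Two independent oracles are provided for cross-validation: connected-
component counting on the thresholded graph, and Betti numbers from GF(2)
ranks of the boundary matrices of the sub-complex at a fixed scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .connectivity import DistanceMatrix
from .errors import DataError
from .filtration import FiltrationConfig, SimplexStream

__all__ = [
    "PersistenceInterval",
    "Barcode",
    "BettiCurve",
    "reduce_boundary_matrix",
    "betti_curve",
    "connected_components_at",
    "homology_ranks_bruteforce",
]


@dataclass(frozen=True)
class PersistenceInterval:
    """One Betti interval (delta_start, delta_end).

    For dim 0 the representative is the vertex that opened the connected
    branch; for dim 1 it is a tuple of edges (vertex pairs) forming a cycle
    present at the birth scale.
    """

    dim: int
    birth: float
    death: float  # math.inf encodes "still open at t_max"
    representative: tuple[tuple[int, int], ...] | int | None = None

    @property
    def length(self) -> float:
        return self.death - self.birth


@dataclass
class Barcode:
    """All persistence intervals of one filtration, dims 0 and 1."""

    intervals: list[PersistenceInterval]
    n_vertices: int
    config: FiltrationConfig = field(default_factory=FiltrationConfig)
    scan_id: str = ""

    def dim(self, k: int) -> list[PersistenceInterval]:
        return [iv for iv in self.intervals if iv.dim == k]

    def to_table(self, representatives: bool = True) -> pd.DataFrame:
        rows = []
        for iv in self.intervals:
            rep = ""
            if representatives and iv.dim == 1 and iv.representative:
                rep = ";".join(f"{u}-{v}" for u, v in iv.representative)
            elif representatives and iv.dim == 0:
                rep = str(iv.representative)
            row = {
                "dim": iv.dim,
                "birth": iv.birth,
                "death": "inf" if math.isinf(iv.death) else iv.death,
            }
            if representatives:
                row["representative"] = rep
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, path, representatives: bool = True) -> None:
        self.to_table(representatives).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


@dataclass
class BettiCurve:
    """Betti numbers sampled on the reporting grid, half-open convention."""

    grid: np.ndarray
    beta0: np.ndarray
    beta1: np.ndarray
    scan_id: str = ""


def _decode_edges(bits: int, edges: np.ndarray) -> tuple[tuple[int, int], ...]:
    out = []
    while bits:
        low = bits.bit_length() - 1
        out.append((int(edges[low, 0]), int(edges[low, 1])))
        bits ^= 1 << low
    return tuple(sorted(out))


def reduce_boundary_matrix(stream: SimplexStream, validate: bool = False) -> Barcode:
    """Persistence pairing of a filtered VR stream over GF(2).

    Every vertex opens a 0-dimensional interval at 0 (so the number of
    dim-0 intervals always equals n_vertices); merging edges close them,
    loop-creating edges open dim-1 intervals, triangles close those.
    Zero-length intervals (birth == death) are recorded; the half-open
    Betti-curve convention drops them automatically.
    """
    if validate:
        stream.validate()
    edges = stream.edges
    evals = stream.edge_values

    # --- edge block: rows are vertices (all born at 0, row = index) -------
    pivot_v: dict[int, int] = {}  # pivot vertex -> edge index
    red_col: dict[int, int] = {}  # edge index -> reduced vertex column
    chain: dict[int, int] = {}  # edge index -> GF(2) edge chain of the column
    cycle_rep: dict[int, int] = {}  # loop-creating edge -> cycle bits at birth
    dim0_death: dict[int, float] = {}  # killed vertex -> death value
    for ei in range(len(edges)):
        col = (1 << int(edges[ei, 0])) | (1 << int(edges[ei, 1]))
        ch = 1 << ei
        while col:
            low = col.bit_length() - 1
            other = pivot_v.get(low)
            if other is None:
                break
            col ^= red_col[other]
            ch ^= chain[other]
        if col:
            pivot_v[low] = ei
            red_col[ei] = col
            chain[ei] = ch
            dim0_death[low] = float(evals[ei])
        else:
            cycle_rep[ei] = ch  # a 1-cycle containing edge ei, born here

    intervals: list[PersistenceInterval] = []
    for v in range(stream.n_vertices):
        intervals.append(
            PersistenceInterval(0, 0.0, dim0_death.get(v, math.inf), v)
        )

    # --- triangle block: rows are edges in stream order -------------------
    pivot_e: dict[int, int] = {}  # pivot edge index -> reduced triangle column
    dim1_death: dict[int, float] = {}
    tris = stream.triangles
    tvals = stream.triangle_values
    if len(tris):
        eindex = {
            (int(u), int(v)): k for k, (u, v) in enumerate(edges)
        }
        for ti in range(len(tris)):
            a, b, c = (int(x) for x in tris[ti])
            col = (
                (1 << eindex[(a, b)])
                | (1 << eindex[(a, c)])
                | (1 << eindex[(b, c)])
            )
            while col:
                low = col.bit_length() - 1
                other = pivot_e.get(low)
                if other is None:
                    break
                col ^= other
            if col:
                if low not in cycle_rep:  # impossible for a valid stream
                    raise DataError(
                        "reduction pivot is not a loop-creating edge; "
                        "stream violates face closure"
                    )
                pivot_e[low] = col
                dim1_death[low] = float(tvals[ti])

    for ei, rep in cycle_rep.items():
        intervals.append(
            PersistenceInterval(
                1,
                float(evals[ei]),
                dim1_death.get(ei, math.inf),
                _decode_edges(rep, edges),
            )
        )

    intervals.sort(key=lambda iv: (iv.dim, iv.birth, iv.death))
    return Barcode(intervals, stream.n_vertices, stream.config)


def betti_curve(barcode: Barcode, config: FiltrationConfig | None = None) -> BettiCurve:
    """Sample beta_0 and beta_1 on the reporting grid.

    At each grid value delta, beta_k counts dim-k intervals with
    birth <= delta < death, matching the convention that a hole appearing
    at delta_start remains open for delta_start <= delta < delta_end.
    """
    config = config or barcode.config
    grid = config.grid()

    def counts(k: int) -> np.ndarray:
        ivs = barcode.dim(k)
        births = np.sort([iv.birth for iv in ivs])
        deaths = np.sort([iv.death for iv in ivs if math.isfinite(iv.death)])
        born = np.searchsorted(births, grid, side="right")
        dead = np.searchsorted(deaths, grid, side="right")
        return (born - dead).astype(np.int64)

    return BettiCurve(grid, counts(0), counts(1), barcode.scan_id)


def connected_components_at(d: DistanceMatrix, delta: float) -> int:
    """Union-find style oracle: components of the graph with edges d_ij <= delta."""
    if delta < 0:
        raise DataError("delta must be nonnegative")
    adj = (d.d <= delta) & ~np.eye(d.n_regions, dtype=bool)
    n_comp, _ = _cc(csr_matrix(adj), directed=False)
    return int(n_comp)


def _gf2_rank(rows: list[int]) -> int:
    """Rank of a GF(2) matrix given as integer bit-rows."""
    rank = 0
    pivots: list[int] = []
    for row in rows:
        for p in pivots:
            if row & (1 << (p.bit_length() - 1)):
                row ^= p
        if row:
            pivots.append(row)
            pivots.sort(key=int.bit_length, reverse=True)
            rank += 1
    return rank


def homology_ranks_bruteforce(stream: SimplexStream, delta: float) -> tuple[int, int]:
    """Betti numbers of the sub-complex at delta from GF(2) boundary ranks.

    beta0 = V - rank(d1); beta1 = (E - rank(d1)) - rank(d2). Independent of
    the reduction: plain Gaussian elimination on the sub-complex, used as a
    validation oracle.
    """
    n = stream.n_vertices
    emask = stream.edge_values <= delta
    edges = stream.edges[emask]
    tmask = stream.triangle_values <= delta
    tris = stream.triangles[tmask]

    d1 = [(1 << int(u)) | (1 << int(v)) for u, v in edges]
    r1 = _gf2_rank(d1)

    eindex = {(int(u), int(v)): k for k, (u, v) in enumerate(edges)}
    d2 = [
        (1 << eindex[(int(a), int(b))])
        | (1 << eindex[(int(a), int(c))])
        | (1 << eindex[(int(b), int(c))])
        for a, b, c in tris
    ]
    r2 = _gf2_rank(d2)

    beta0 = n - r1
    beta1 = (len(d1) - r1) - r2
    return beta0, beta1
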