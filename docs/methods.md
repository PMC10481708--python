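# Methods

## From signals to a metric space

A scan is a table of region-averaged signals P(j) = {P₁(j), …, P_n(j)},
j = 1 … 90 for the AAL-90 parcellation. Functional connectivity is the
sample Pearson correlation m_ij = corr(P_i, P_j); the dissimilarity fed to
the filtration is d_ij = 1 − m_ij ∈ [0, 2]. Properties relied on downstream:
d is symmetric with zero diagonal and is invariant to positive-slope affine
rescaling of any region's signal. It is **not** a metric (no triangle
inequality), and nothing in the Vietoris–Rips construction assumes one.
Regions with constant signal make the correlation undefined; they raise an
error naming the offending labels rather than being silently imputed,
because in practice they indicate a degenerate simulation or a broken
extraction. Negative correlations map to d > 1 and therefore never form
edges under the default t_max = 0.9; the cap implicitly restricts edges to
pairs with r ≥ 0.1.

## The filtration

VR(Z, δ) contains all vertices, each edge [ab] with d(a,b) ≤ δ, and each
triangle whose three edges are present. Defaults: maximum simplex dimension
d_max = 2 (sufficient for β₀ and β₁), maximum filtration value t_max = 0.9,
and 450 grid divisions. Exact pairwise distances are the filtration values;
the grid is used only to sample Betti curves, so persistence intervals are
exact and the grid resolution never changes the barcode. Ties in filtration
value are broken by dimension, then lexicographic vertex order, making the
reduction and its representatives deterministic. Triangles are enumerated
by intersecting the thresholded neighbour sets of each edge's endpoints
(O(E·deg) rather than O(n³) on dense 90-node matrices), and each triangle's
value is computed as the exact maximum of its stored edge values — asserted
as equality, not approximately, in the tests.

## Persistence and representatives

Standard persistence pairing over GF(2), by column reduction with columns
stored as integer bit vectors (XOR = column addition). The dimension blocks
are processed separately, which is equivalent to the global algorithm
because boundary columns of dimension k only interact with columns of the
same dimension. Every vertex opens a 0-dimensional class at 0 (elder rule:
the count of dim-0 intervals always equals the number of vertices); an edge
either merges two branches — killing the younger — or closes a loop, in
which case the chain of edges accumulated during its reduction is recorded
as the class representative at birth. Triangles kill the loop class whose
pivot edge they reduce to. Classes alive at t_max get death = ∞
(right-censoring by the truncated filtration).

Conventions:

* **Half-open intervals.** A hole born at δ_start is counted for
  δ_start ≤ δ < δ_end. Zero-length intervals (birth = death, e.g. a
  diagonal edge and the triangles it completes entering together) are
  recorded in the barcode but contribute nothing to Betti curves.
* **Representatives are the reduced-column cycle at birth**, not a
  shortest cycle. They are guaranteed to be GF(2) cycles (every vertex has
  even incidence) with all edges born no later than the class, but they may
  be non-simple and are not unique invariants of the bar — any feature that
  localises homology classes inherits this dependence. Shortest-cycle
  tightening is out of scope.

Two independent oracles validate the reduction exactly on random instances:
β₀ against connected components of the thresholded graph, and (β₀, β₁)
against GF(2) ranks of the boundary matrices of the frozen sub-complex
(β₀ = V − rank ∂₁, β₁ = E − rank ∂₁ − rank ∂₂).

## FCNC features

At a threshold δ, the circuits of a scan are **all dim-1 intervals with
birth ≤ δ**, regardless of death. This cumulative-birth convention — rather
than "alive at δ" — makes per-region counts non-decreasing in δ, matching
the intended reading that a circuit present at a small scale remains a
circuit of the network at any larger scale; alive-counts would instead fall
as holes fill in. Per-region counts tally the circuits whose representative
touches the region; length counts tally circuits with a given number of
representative edges. "Medium length" is a configuration parameter
(default 8), not an inferred quantity.

## Statistics

* **Mann–Whitney U**, two-sided, per feature × threshold. For combined
  sample sizes ≤ 12 the p-value is computed by exact enumeration of all
  C(n₁+n₂, n₁) label assignments — a permutation formulation that handles
  ties exactly (identical samples give p = 1) — otherwise by the normal
  approximation with tie and continuity correction (scipy).
* **Benjamini–Hochberg step-up FDR.** The default family is *within one
  feature across its thresholds* (m = number of thresholds, typically 3):
  each region's three p-values are corrected together. This family is the
  natural per-region report but gives no control over the number of regions
  flagged under a global null; `fdr_scope="global"` corrects all features ×
  thresholds jointly and is what the simulation-recovery harness uses for
  its type-I guarantee.
* **Kolmogorov–Smirnov** on Betti curves: within each group, every scan's
  Betti value at every grid point is pooled into one sample per dimension;
  D = sup|ECDF_a − ECDF_b|, Z = D·√(n₁n₂/(n₁+n₂)), p asymptotic. Pooling
  grid points inflates the effective sample size (values at nearby δ are
  highly dependent), so the KS p-values are descriptive of curve separation
  rather than strictly calibrated; the per-feature U tests carry the
  inferential weight.
* Scans, not subjects, are the sampling unit; when subjects contribute
  repeated scans the independence assumption is only approximate. This is
  documented rather than corrected.

## Synthetic generator

Each group's scans are i.i.d. zero-mean multivariate normal time series
(rows independent in time — no autocorrelation) with a single population
correlation matrix: unit diagonal, `background_corr` (default 0.1)
everywhere, and `within_cycle_corr` (default 0.8) on *ring-adjacent* pairs
of each planted cycle. Adjacency-only elevation keeps the ring's chords at
background, so the planted structure is a genuine 1-cycle of the population
correlation geometry, not a filled clique. Defaults of 90 regions and 127
time points mirror a typical resting-state acquisition (137 volumes with
the first 10 discarded).

A ring-structured request is typically not positive semidefinite (a k-ring
adjacency matrix has eigenvalue −2, so strong adjacency with weak chords
pushes the minimum eigenvalue negative). The target is projected to the
nearest PSD matrix by clipping eigenvalues at 1e-10 and renormalising to
unit diagonal; the projection attenuates the realised ring correlation
(e.g. a request of 0.8 over background 0.1 realises ≈ 0.66) while leaving
ring edges far shorter than chords, so the planted β₁ ground truth is
preserved. `target_correlation` exposes the projected matrix, and all
population-level tests compare against it. The generator deliberately omits
hemodynamic response, temporal autocorrelation, spatial noise, motion and
within-group heterogeneity (one Σ per group); passing tests therefore
demonstrate correctness of the topological and statistical machinery under
the stated covariance model, not robustness to realistic fMRI artifacts.

## Problem sizes in the test suite

The oracle-equivalence checks run 200 random 10–15-point instances at five
scales each. The recovery study uses 20 replicates of 20 vs 20 scans with
one planted 6-ring (within 0.8, background 0.1, 200 time points), testing
planted-region detection at q < 0.05 with `fdr_scope="global"`, and the
type-I side reuses each replicate's barcodes under permuted group labels.
These sizes give stable pass/fail behaviour (binomial error on 20
replicates) at roughly two minutes for the whole study on one core; a
single 90-region scan takes ≈ 0.1 s end to end through persistence.

## Known limitations

* β₂ and higher homology, persistence images/landscapes and witness or
  sparsified complexes are out of scope.
* Representative-dependence of per-region counts (above) is the largest
  interpretive choice; it is isolated behind the feature-extraction
  interface.
* The generator's single-Σ-per-group model ignores within-group FC
  heterogeneity; group differences in real cohorts are noisier than the
  simulation suggests.
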