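# fcnc — topological analysis of functional connectivity networks

`fcnc` studies resting-state brain networks through persistent homology.
Starting from region-averaged time series on a parcellation such as AAL-90,
it builds the Pearson functional-connectivity matrix

    m_ij = corr(P_i, P_j),

turns it into the dissimilarity d(P_i, P_j) = 1 − m_ij, and sweeps a
threshold δ over the resulting metric to obtain a filtered Vietoris–Rips
complex VR(Z, δ₀) ⊆ VR(Z, δ₁) ⊆ … (maximum simplex dimension 2, maximum
filtration value t_max = 0.9, 450 grid divisions by default). Boundary-matrix
reduction over GF(2) yields the barcode: β₀ intervals track connected
branches, β₁ intervals track 1-dimensional holes. Each β₁ class carries a
representative cycle — a closed chain of regions with mutually correlated
signals — which we call a **functional connectivity neural circuit (FCNC)**.

From the barcodes the package derives, per scan and per threshold δ ∈
{0.7, 0.8, 0.9}: the number of circuits touching each region, and the
number of circuits of a given length (edge count). Two groups of scans
(e.g. patients vs. controls) are then compared with two-sample
Mann–Whitney *U* tests plus Benjamini–Hochberg FDR correction per feature,
and with two-sample Kolmogorov–Smirnov tests on the pooled Betti curves.

Because clinical scans cannot ship with a package, `fcnc` includes a
synthetic generator that draws Gaussian time series whose population
correlation matrix embeds "planted rings" — cycles of regions with elevated
adjacent correlation against a uniform background — giving every stage a
known topological ground truth. It is intended for methodologists who want
a tested, reproducible β₁-based FC pipeline, and for simulation studies of
its statistical behaviour.

## Worked example

Simulate 15 + 15 scans of 90 regions (127 time points each, background
correlation 0.1) with one 6-region ring planted in group A only — adjacent
ring pairs requested at correlation 0.8 — and run the full pipeline:

```yaml
# run.yaml
input_mode: synthetic
seed: 7
output_dir: out
simulation:
  n_scans_a: 15
  n_scans_b: 15
  n_regions: 90
  n_timepoints: 127
  planted_cycles_a: [[44, 46, 54, 56, 74, 78]]
  within_cycle_corr: 0.8
  background_corr: 0.1
```

```console
$ fcnc run -c run.yaml
30 scans, 90 regions; significant regions: Caudate_L, Cuneus_L, Fusiform_L,
Heschl_L, Lingual_L, Pallidum_L, Postcentral_L, Rectus_L, SupraMarginal_L
```

The planted ring used regions 44, 46, 54, 56, 74, 78 — Cuneus_L, Lingual_L,
Fusiform_L, Postcentral_L, Pallidum_L, Heschl_L — and all six are flagged
at q < 0.05 (three additional regions pass under the default per-region FDR
family; use `fdr_scope: global` for a stricter joint correction). The
comparison table mirrors the per-region statistics, e.g.:

```
feature    threshold  mean_a  sd_a   mean_b  sd_b   U      p_value    q_value
Cuneus_L   0.7        2.40    2.38   0.00    0.00   225.0  5.14e-07   2e-06
Cuneus_L   0.8        68.7    76.6   13.1    10.3   184.0  3.22e-03   4.8e-03
Cuneus_L   0.9        302.6   306.1  73.9    54.7   180.5  5.10e-03   5.1e-03
```

Read: at δ = 0.7 group A scans contain on average 2.4 circuits touching
Cuneus_L while group B contains none (the planted ring closes early, around
the ring-edge distance); at larger δ both groups accumulate background
circuits but the group difference persists. Counts are cumulative in δ, so
they never decrease across thresholds. The run directory also contains
per-scan correlation/distance matrices and barcodes, mean Betti curves per
group, the long-format feature table, and `ks_tests.tsv` with the
Kolmogorov–Smirnov comparison of pooled Betti values (here D = 0.358 in
dimension 0 and D = 0.321 in dimension 1, both p ≈ 0).

The same analysis is available as a library — see
`fcnc.pipeline.analyze_scans` — and piecewise: `fcnc simulate`,
`fcnc persistence` (distance matrix → barcode), `fcnc stats` (feature
table → comparison tables).

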