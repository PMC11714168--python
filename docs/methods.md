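# Methods

## Model

`citmic` scores the infiltration of cell types in a bulk expression sample
by network centrality rather than by direct marker enrichment. The model
rests on two assumptions:

1. **Functional coupling.** Two cell types that participate in the same GO
   biological processes, through shared genes, interact ("crosstalk") in
   the tissue; the strength of that coupling in a given sample scales with
   the expression of the shared genes.
2. **Centrality ≈ activity.** A cell type connected to many other cell
   types through strongly expressed shared functions is more active/more
   infiltrated in that sample's microenvironment.

Per sample, the pipeline is:

- **Bipartite weights.** For cell set *C* and GO set *G*:
  `W(C,G) = J(C,G) · med{GEP_x : x ∈ C∩G}` with `J` the Jaccard
  coefficient. `W = 0` exactly when `C∩G = ∅`. The Jaccard factor is
  sample-independent and computed once per cohort; only the median factor
  is recomputed per sample (the implementation precomputes per-pair
  overlap index arrays, grouped by overlap size, so the per-sample work is
  a handful of vectorised median calls).
- **One-mode projection.** `R = W·Wᵀ` with the diagonal overwritten to 0.
  Symmetry is enforced exactly (`(R+Rᵀ)/2`) to guard against float
  summation order.
- **Centrality.** The column-stochastic transition matrix `P` normalises
  each cell's incident weights; the stationary distribution of
  `π ← r·u + (1−r)·P·π` (uniform restart vector `u = 1/n`) is found by
  fixed-point iteration from `π₀ = u`. This is deterministic — the "random
  walk" is never sampled — and converges linearly at rate `(1−r)`.
- **Normalization.** Raw stationary scores are heavy-tailed; `log10`
  followed by per-sample min-max maps each sample's scores onto [0, 1].

Samples are scored independently: cohort composition affects results only
through the gene-prevalence filter, which is applied once, before scoring.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_set_size`, `max_set_size` | 15, 350 | GO-BP size band (genes per set); smaller sets give unstable medians, larger ones are uninformative catch-alls |
| `prevalence_fraction` | 0.5 | keep genes expressed in ≥ 50% of samples; `None` disables |
| `expressed_threshold` | 0.0 | "expressed" = value strictly above this on the supplied log scale; the input scale is log-like (log2(TPM+1), log2(FPKM+1)), unitless |
| `restrict_sets_to_universe` | True | intersect all gene sets with the measured genes so Jaccard and medians live in the same universe; disable only for sensitivity analysis |
| `min_overlap` | 1 | minimum \|C∩G\| to form a cell–GO edge; any shared gene counts |
| `restart_prob` | 0.15 | restart mass of the walk, the conventional damping complement; rankings are stable across 0.05–0.5 (tested) |
| `tol`, `max_iter` | 1e-10, 1000 | L1 fixed-point convergence; non-convergence returns a flagged result with a warning |
| `dangling_policy` | `uniform_redistribute` | isolated cells get a uniform transition column, keeping every score positive so log10 is defined; `self_restart` leaves the column zero instead |

## Design choices at genuinely open points

- **Order of transforms.** Min-max normalization is applied to the
  log10-transformed scores (not the raw scores); the log transform is
  introduced precisely to tame the power-law tail before comparing within
  a sample.
- **Even-sized overlaps** use the standard midpoint-average sample median.
- **Constant columns** (all cells tied, including the single-cell n=1
  case) would make min-max 0/0; they map to 0.5 with a prominent warning.
- **Duplicate gene rows** in input tables are collapsed by keeping the row
  with the highest mean — deterministic and biased toward the
  better-detected probe/transcript.
- **Universe restriction before weighting.** Signature and GO sets are
  intersected with the post-filter measured genes; mixing curated-set
  sizes with measured-gene medians would make the two factors of `W`
  inconsistent.
- **Solid-tumor exclusion list.** Only the explicitly documented cell
  types (pro-B cells, hematopoietic stem cells, common lymphoid
  progenitors) are packaged; the list is user-extensible because the
  reference enumeration is open-ended.
- **Orientation.** The estimator follows the scikit-learn convention
  (samples × genes in, samples × cells out); file I/O and the pipeline
  functions keep the bioinformatics genes × samples / cells × samples
  orientation.

## Synthetic data

The generator (`citmic.simulate`) emulates the structure the model
assumes: a gene universe, signature sets, GO-like sets drawing a fraction
`overlap_rate` of their members from the pooled signature genes, log-normal
baseline expression (parameters 1.0/0.5 on the log scale, mimicking the
positive skew of log2(TPM+1) values), and optional spikes that add a known
δ to one cell type's *exclusive* signature genes (genes in exactly one
cell set, so ground truth is unambiguous) in one sample.

It does **not** emulate: realistic mixture proportions or reference
single-cell profiles, gene–gene correlation structure, batch effects,
technical dropout, or symbol aliasing. Passing spike-recovery tests on
synthetic cohorts therefore shows the pipeline responds correctly to
expression shifts of signature genes — not that scores equal true cell
fractions in real tissue, which requires external ground truth (flow
cytometry) outside this package's scope.

The packaged default collections are likewise synthetic stand-ins: they
reproduce the reference collection's documented structure (86 cell types —
40 lymphoid, 15 myeloid, 11 stem, 11 stromal, 9 other — and a size-filtered
GO-BP collection sharing genes with the signatures) with generated gene
symbols. Real analyses should supply curated GMTs.

## Test problem sizes

Equation-level tests run on a fixed 3-cell/2-GO fixture checked by hand;
centrality is validated against a dense closed-form solve on 1000 random
networks of 2–8 nodes; cohort-level and spike-in tests use synthetic
cohorts of 6–8 cell types, 30–40 GO sets, 400–600 genes and 3–5 samples,
with 100 seeded replicates for the statistical recovery check (spike
δ = 6, about four baseline standard deviations — a strong, unambiguous
infiltration shift; recovery degrades gracefully at smaller effects). These
sizes keep the whole suite in seconds while leaving every matrix
non-trivial.

## Known limitations

- InScores are *relative within a sample*: cross-sample comparison is
  meaningful per cell type after normalization, but absolute cell
  fractions are not identifiable.
- Cell types with heavily overlapping signatures receive correlated
  scores; the crosstalk projection shares weight through common GO terms
  by design.
- The method inherits the coverage of the supplied signature and GO
  collections; unmeasured or unrepresented cell types are invisible.
- The CT-TME risk score only evaluates a user-supplied linear model;
  coefficient fitting (Cox regression) is deliberately out of scope.
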