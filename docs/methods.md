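# Methods

This note documents the model underlying `crinet`, the defaults of every
tunable that matters, the design choices made where the method leaves
room, and the limits of what the synthetic benchmarks demonstrate.

## Model and assumptions

The method assumes (i) miRNAs repress their targets, so true
miRNA-target pairs are anticorrelated in expression across samples;
(ii) ceRNA partners share miRNA regulators and up-regulate each other,
so they are positively correlated once copy-number effects are removed;
(iii) joint miRNA pressure on a gene set is summarised by the collective
regulation statistic CR(S) = corr(Σ ER, Σ Exp), which is strongly
negative for genuinely co-regulated sets; and (iv) observed correlation
networks contain transitive (amplified) edges that a series model
`G_obs = G_dir + G_dir² + …` can separate from direct ones.

Expression inputs are non-negative normalised abundances (FPKM-like for
genes, RPM-like for miRNAs) over a shared sample set; the CNA matrix is
gene-centric and may be negative. Binding scores follow the weighted
context++ convention: more negative = stronger predicted binding.

## Parameter defaults

| parameter | default | role |
|---|---|---|
| low-expression rule | FPKM < 1 resp. RPM = 0 in ≥ 15 % of samples | drop unexpressed entities |
| top score fraction | 0.40 | discard the weak tail of the binding-score table |
| weight floor | 0.01 | keep normalised weights strictly positive (IR/ER divide by weight sums) |
| miRNA-target correlation | < −0.1 | repression screen |
| log-IR abundance cut | 80th percentile of ln IR > −4.89 | expression-sufficiency screen |
| ER correlation | < −0.01 | gene-level regulation screen |
| consensus | 1000 resamples (targets), 100 (pairs), ≥ 99 % pass | bootstrap robustness |
| hypergeometric alpha | 0.01 | common-regulator screen |
| partial correlation | > 0.55, p < 0.01 | ceRNA co-expression screen |
| CR threshold | < −0.01 | collective-regulation screen |
| deconvolution | retain top 1/3, largest direct eigenvalue 0.9 | indirect-edge pruning |
| group fractions | 0.90 members / 0.90 neighbours | group validity |
| Walktrap walk length | 4 | community detection |

The −4.89 log-IR cut and the 0.55 partial-correlation threshold are
data-derived quantities in the reference analysis; both are exposed in
`PipelineConfig` and can be recomputed from the current dataset
(`log_ir_threshold="auto"` takes the third quartile of ln IR;
`auto_partial_corr_min=True` takes the third quartile of the positive
partial correlations).

## Design choices where the method is open

* **Correlation type.** Pearson throughout — CR is defined with the
  Pearson correlation, and the same reading is applied to the −0.1 and
  −0.01 screens.
* **Logarithm and percentile.** The IR cut uses the natural log;
  percentiles interpolate linearly between order statistics
  (rank h = (n−1)p + 1). IR = 0 maps to −∞ and simply counts as the
  smallest order statistic.
* **Low-expression rule.** Read as two independent criteria (genes by
  the FPKM threshold, miRNAs by exact zeros), matching per-datatype
  preprocessing.
* **Score normalisation.** Class-wise z-scores are rescaled into [−1, 1]
  by dividing by the global max |z| (a scaling, not a clipping), then
  min-max-mapped onto [0.01, 1] with orientation "stronger binding →
  larger weight". A zero-variance class gets z = 0; a globally constant
  score table degenerates to all weights = 1.
* **Top-fraction selection** is global across RNA classes and keeps
  boundary ties, making it order-independent.
* **Partial correlation** conditions on both genes' own CNA vectors via
  per-gene OLS residuals (intercept included); significance uses
  t = ρ√((n−4)/(1−ρ²)) on n−4 degrees of freedom (two fitted
  covariates). A constant CNA vector removes only the mean, so the
  statistic reduces exactly to the Pearson correlation.
* **Consensus streams.** Each stage draws one shared set of resample
  index multiplicities (a multinomial count matrix) used for every
  record, so per-record pass fractions are comparable and the whole run
  is reproducible from one master seed (per-stage substreams are
  spawned from it). The coefficient thresholds (not the p-values) are
  re-evaluated per resample; a resample with a zero-variance vector
  counts as a failure.
* **Deconvolution scaling.** β is the largest value keeping every mapped
  eigenvalue βλ/(1+βλ) within ±0.9 (the series stays convergent).
  Edges with non-positive deconvolved score are removed *before* the
  top-third cut — they carry no direct evidence under the series model,
  which is also why the final edge count can fall below a third of the
  input. Ranking ties within a relative tolerance of 1e−9 are kept
  together, so exact ties (e.g. all-equal weights) are never broken
  arbitrarily by floating-point noise.
* **Group conditions.** "Stronger regulation" means
  corr(Exp(g), ER(g)) − CR(group) > 0 per member (positive when the
  group CR is more negative). The neighbour-correlation sub-condition
  reuses the pairwise 0.55 threshold on the plain Pearson correlation of
  summed member expression; group expression is the per-sample sum of
  member expression, mirroring the CR summation. Group-neighbour edges
  inherit the maximum absorbed member-edge weight. Undefined
  correlations always count as condition failures.
* **Refinement bookkeeping.** `iterations` counts community-detection
  invocations. Every re-split either strictly shrinks a community or
  dissolves it, so the loop terminates; empirically it stays below
  2·|V| invocations.

## Synthetic data: what it emulates, what it does not

`SyntheticSpec` defaults define the package's reference conditions:
200 genes, 30 miRNAs, 300 samples, 20 planted ceRNA pairs, 40 weaker
"decoy" co-regulated pairs, Gaussian noise σ = 3 and a CNA effect of 3
(per-gene standard-normal copy-number profiles scaled by the effect).
miRNA expression is i.i.d. log-normal (log-mean 3, log-sd 0.5 —
RPM-like, median ≈ 20); gene expression is
`baseline − 0.8·Σ weight·Exp(miRNA) + CNA + noise`, truncated at zero,
with baselines in [150, 200] so that truncation is essentially never
active. Each planted unit shares one 4-miRNA regulator set (pairwise
overlap between units ≤ 2, so distinct units cannot pass the
common-regulator screen against each other), and both members carry
identical binding weights, making them exactly affinely related at zero
noise. Decoy pairs use the same construction with weaker binding
(raw scores −0.40…−0.30 vs −0.62…−0.42): they pass the pairwise screens
but at lower partial correlation, emulating the weaker, partially
indirect co-regulation that the deconvolution + top-third step is meant
to down-rank. Background genes carry nine weak random regulators each
(scores −0.25…−0.02), which keeps the planted interactions inside the
top-40 % score cut instead of being the entire table.

This generator validates the machinery, not the biology: it contains no
heavy-tailed expression, no batch structure, no correlated miRNAs, no
discrete CNA segments, and its ceRNA signal is linear-additive. Passing
the recovery benchmarks therefore shows the screens and the
deconvolution ranking behave as designed under their own model
assumptions — not that the thresholds are optimal for any particular
tumour dataset.

## Problem sizes and numerics

The test-suite and the acceptance script run the full cascade at the
reference scale (200×30×300, ~1200 interactions), which completes in a
few seconds: bootstrap correlations are computed as moment products
with a multinomial count matrix (one matrix multiplication per moment),
and the pair-stage resamples re-fit the per-gene CNA regressions on
each resample. Brute-force oracle comparisons use systems of ≤ 10
genes, ≤ 5 miRNAs and ≤ 20 samples at tolerance 1e−10; the
deconvolution closed form is checked against an independent
eigendecomposition at 1e−8.

Degenerate inputs are handled explicitly: constant expression vectors
drop the record (correlation undefined), zero IR denominators yield
IR = 0 for that sample, regulator-less genes get ER ≡ 0 and are
excluded from the candidate set, and an empty stage output raises an
error naming the stage and its governing threshold rather than
propagating an empty network.

## Known limitations

* All-pairs screening is quadratic in the candidate-gene count; the
  hypergeometric pre-screen keeps the correlation stage tractable but
  genuinely genome-wide runs (≫10⁴ candidates) need batching.
* Deconvolution operates on the dense adjacency; networks beyond ~10⁴
  nodes would need a sparse eigensolver.
* Groups are disjoint by construction; overlapping or hierarchical
  sponge modules are out of scope.
* The consensus criterion is a fixed ≥ 99 % pass fraction, not a
  calibrated false-discovery control.
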