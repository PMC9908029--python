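# Methods

This note documents the models, rules and numerical choices behind
`myostate`, and what the synthetic-data generators do and do not emulate.

## Quality control and demultiplexing

Per-cell metrics are the number of detected features (count > 0), total
UMIs, and the mitochondrial percentage 100 · (UMIs on mitochondrial
features / total UMIs).  Mitochondrial features are a caller-supplied ID
set or, by default, features named with the `MT-` prefix.  Cells with zero
total counts get a mitochondrial percentage of 0 and a `zero_total` flag
rather than an error.

Filtering applies three removal rules with strict inequalities: fewer than
`min_genes` (default 200) or more than `max_genes` (8000) detected genes;
fewer than `min_umi` (1000) or more than `max_umi` (50,000) UMIs; more
than `max_mito_pct` (15%) mitochondrial UMIs.  Boundary cells (exactly 200
genes, exactly 15%) are kept, since the removal rules are strict.

HTO counts are normalized per cell with the centered log-ratio,
`clr_h = log(x_h + 1) − mean_h log(x_h + 1)` (pseudocount 1; every CLR
vector sums to zero by construction).  Cells are assigned to the hashtag
with maximal CLR.  This is deliberately the stated decision rule rather
than a mixture-model demultiplexer: it is fully specified, auditable, and
an optional `min_margin` flags cells whose top two CLR values are tied or
nearly tied as `AMBIGUOUS`.  How ambiguous cells are treated downstream is
left to the caller.

## Normalization and module scores

Expression is library-size normalized to `scale` (default 10,000) counts
per cell and log1p-transformed.  Zero-total cells map to all-zero columns
with a warning.

Module scores use expression-matched control genes: all genes are ranked
by mean log-normalized expression and cut into `n_bins` (25) equal-size
bins; each signature gene samples `n_ctrl` (100) control genes without
replacement from its bin (the whole bin when it holds ≤ `n_ctrl` genes;
the signature gene itself is not excluded, so a single-gene signature with
a saturated bin reduces exactly to expression minus bin mean).  The score
is the per-cell mean over signature genes minus the mean over the pooled
control genes.  Control sampling is seeded and byte-reproducible.

Cycling classification takes caller-supplied S-phase and G2-M scores
(module scores of editable gene lists, not hard-coded ones) and labels a
cell HIGH_CYCLING iff either score is strictly positive.  An exact zero —
a measure-zero event — is LOW_CYCLING, chosen once so the rule partitions
all cells deterministically.

Marker derivation keeps genes expressed in at least `min_pct` (5%) of the
cluster's cells whose log fold change (difference of mean log-normalized
expression, no extra pseudocount) exceeds `lfc_threshold` (0.25 on the log
scale of the data) with a two-sided rank-sum p-value below `alpha` after
Bonferroni correction.  The Bonferroni denominator is the number of
p-values actually computed in the call.  Two modes: `one_vs_rest`
(cluster annotation) and `pairwise`, which retains genes passing the
fraction/fold-change thresholds against every other cluster and reports
the weakest fold change and largest p-value across comparisons (used for
survival signatures).  Only overexpressed genes are reported
(direction +1).  The rank-sum test is the default throughout; a bimodal
likelihood-ratio alternative is out of scope.

## Imaging gating and screen scores

Background thresholds are per-plate quantiles (default 0.99) of the
unstained control well's intensity distribution, one per marker; a cell is
positive when strictly above the threshold, so boundary cells are
negative.  Gating is total and unambiguous: MyHC+ cells are
`differentiated` regardless of the other markers; the rest fall into the
2×2 on (myogenin, Ki-67): −/− quiescent MuSC-like, −/+ cycling MuSC-like,
+/+ cycling progenitor, +/− committed.  Well compositions report nuclei
counts and the five state percentages (summing to 100); wells under
`min_cells` (20) are flagged low-confidence.  A sample whose
differentiated percentage strictly exceeds 10% is a responder.

Replicate wells of the same compound × dose are averaged at the
composition level before scoring, which keeps score(control, control) = 0
exact and the scores antisymmetric.  Hit calling defaults to the 1 μM
dose.  The differentiating-hit rule uses strict inequalities with an
optional minimum-effect margin (default 0 percentage points).  The margin
exists for noise control: with quantile thresholding, about 1% of
genuinely negative cells exceed the background threshold per marker, so
two wells with identical true compositions differ by a few tenths of a
percentage point after gating, and at margin 0 any such fluctuation in
the favorable direction counts as a "hit".  In the synthetic screen
scenarios a 2-point margin is used — an order of magnitude above that
misgating noise at 2000 cells/well and an order of magnitude below the
planted effects (≥ 15 points).  The dedifferentiating rule carries its
own margin (≥ 1.5-fold MuSC-like enrichment, boundary inclusive, applied
to the quiescent + cycling MuSC sum on which the score is defined); a
zero-control MuSC fraction gives +inf fold (hit) when the treated
fraction is positive and NaN (not a hit, flagged) when both are zero.
The combination score averages a compound's differentiating scores at
10 μM, 1 μM, 100 nM and 10 nM and subtracts the backbone compound's own
score; missing doses are an error unless partial averaging is requested.
Cross-culture intersection keeps compounds flagged hit in both screens,
ranked by the mean of the two scores with lexicographic tie-breaks.

## Signature–survival permutation test

The statistic is T = mean over signature genes of d_g · (mean dead −
mean live) on log expression, d_g = ±1.  Internally each patient is
reduced to y_i = mean_g d_g x_ig, so T is a difference of group means of
a scalar and each permutation costs a subset sum.  The null permutes the
status vector (group sizes preserved) with seeded uniform permutations.
P-values carry the add-one correction p = (1 + #extreme) / (1 + B), so
the smallest attainable p is 1/(B+1) and the test is valid (never p = 0)
at any B.  Two-sided by default — signatures can be enriched in either
the deceased or the living — with one-sided variants exposed.  Cohort
expression is taken as already log-scale; no re-normalization is applied.
Ties (|T_b| exactly equal to |T_obs|) count as extreme.

## Synthetic-data generators

The generators define the study conditions for every test:

* **Counts**: negative binomial with shared dispersion (default 1.0) —
  the standard overdispersed model for UMI data.  Per-gene baseline means
  are lognormal around `baseline_mean` (2.0, spread σ = 0.5); per-cell
  library-size factors are lognormal (σ = 0.75), giving realistic spread
  across the QC thresholds.  Each state's `n_marker_genes_per_state` (25)
  markers are elevated by `marker_log2fc` (2.0 log2 units) in that state.
  A fixed per-cell fraction of UMIs, uniform on `mito_fraction_range`
  (0.01–0.25), is allocated multinomially to designated `MT-` genes, so
  the mitochondrial percentage is exactly controllable.
* **HTO**: each cell's true hashtag has mean `hto_signal_to_noise` (20)
  times the background mean (10); HTO counts use their own dispersion
  (10), reflecting that antibody-tag libraries are far less overdispersed
  than RNA.
* **Plate**: per-well state counts come from largest-remainder rounding
  of the planted composition by default ("exact" mode), so planted
  compositions are realized exactly and downstream error is attributable
  to gating alone; multinomial sampling is available as an option.
  Marker intensities are two-component lognormals (σ = 0.35) whose
  positive component sits `intensity_log_separation` (3.0) log-units
  above the background mean, a knob that makes both easy and hard gating
  regimes testable.  One designated unstained well draws all markers from
  the background component.
* **Cohort**: Gaussian log2 expression (gene baselines uniform on [4, 8],
  noise σ = 1.0); a planted signed signature shifts its up-genes by
  `+effect_log2fc` and down-genes by `−effect_log2fc` in deceased
  patients.

All generators are pure functions of the configuration, including the
seed: identical configurations give byte-identical outputs.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: doublets and ambient RNA, batch and plate-edge
effects, gene–gene correlation structure beyond the planted markers,
segmentation errors upstream of the per-cell imaging tables, censoring or
covariates in the cohort.  The pipeline's correctness claims are about
the stated rules and statistics, not about robustness to those artifacts.

## Problem sizes and tolerances

The test-suite and acceptance-script scenarios use desk-scale sizes chosen
as the package's own defaults: 50 replicate matrices of 1000 cells × 600
genes for QC-oracle agreement; 500 cells for demultiplexing accuracy;
1000 cells for module-score calibration (null-signature mean within
±0.05) and 50 seeded replicates for state separation; 2000 cells/well for
composition recovery (±3 percentage points) and the 96-compound screen
(5 planted differentiating + 5 dedifferentiating compounds, recovered with
no false positives at the 2-point margin); 500 null cohorts at B = 2000
for permutation calibration (type-I error inside the 99% binomial band
around 5%, Kolmogorov–Smirnov uniformity at α = 0.01), and B = 10,000 for
the planted-effect floor p = 1/(B+1).  Numerical identities (CLR vectors
summing to zero, compositions summing to 100, score antisymmetry) are
asserted at 1e-9 to 1e-12.
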