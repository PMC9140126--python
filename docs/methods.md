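# Methods

`stagetrend` analyzes a cohort of tumor transcriptomes as a molecular
continuum ordered by pathologic stage. The baseline condition is
non-malignant adjacent urothelium (NAU), followed by the tumor stages
Ta < T1 < T2 < T3 < T4. This note records the statistical model behind
each stage of the pipeline, the defaults and why they were chosen, what
the synthetic cohorts do and do not emulate, and the numerical choices
that matter.

## Batch harmonization

Multi-study expression compendia carry per-study location and scale
distortions. `batch.combat` implements the parametric empirical-Bayes
location/scale model: per gene, expression is standardized against a
covariate-adjusted grand mean and a pooled variance; per batch, an
additive effect γ and a multiplicative effect δ² are estimated on the
standardized scale and shrunk toward normal and inverse-gamma priors
whose hyperparameters are fixed across genes by the method of moments;
the conditional-posterior pair is iterated to a relative tolerance of
1e-4 (at most 100 iterations) and the data are back-transformed.

Defaults and choices:

- **The condition label is protected by default.** Whether to adjust for
  the biological condition in the standardization step is a genuine
  design choice; without protection, an unbalanced batch/stage layout
  lets the correction absorb stage signal. The default includes the
  stage as a covariate; `covariates=None` disables it.
- Only the parametric priors are implemented; the nonparametric variant
  and reference-batch mode are out of scope.
- A single batch short-circuits to the identity: with one batch the
  standardize/invert round trip is exact and there is nothing to
  estimate.
- The implementation is cross-checked in the test suite against the
  independent sva-derived port in scanpy (agreement to ~1e-5 on a
  planted fixture).

**Idempotence is approximate, not exact.** Running the correction twice
changes values by a small finite-sample residual (median ~1.5e-2 on a
2-batch, 30-samples-per-batch fixture) because the second pass
re-estimates and re-shrinks per-batch variances whose spread across
genes is dominated by sampling noise. The canonical R implementation
behaves identically on the same fixture. The property test asserts the
second-pass change is both small in absolute terms (< 0.05 median) and
far smaller than the correction itself.

The QC report re-expresses the usual batch diagnostics as numbers:
per-sample relative-log-expression medians and IQRs (deviation from the
gene-wise median), the one-way R² of the top two principal components
on batch and on condition, and the cross-batch dispersion of a
user-flagged stable-gene panel.

## Stage-wise differential screening

Each tumor stage is compared against NAU with a two-sided Mann–Whitney
U test. The *fold change* is defined as the difference of log2 group
means, mean(stage) − mean(NAU) — a difference on the log scale, never a
ratio. Three nested selections follow:

- **CDEG** (concordantly differentially expressed gene): p < α in all
  five comparisons and one consistent, nonzero fold-change sign.
- **Monotone gene**: a CDEG whose fold-change sequence fc(Ta) … fc(T4)
  is *strictly* increasing with every fc > 0 (up) or strictly
  decreasing with every fc < 0 (down).
- α defaults to 0.05 **unadjusted**. The screen stacks five
  significance filters, a concordance filter and a strict monotonicity
  filter; adjusting each component test would compound Type-II error
  across the stack, so the per-test level is left nominal.

Numerical choices:

- The exact Mann–Whitney null is used when the smaller group has ≤ 8
  observations and at most 25% of pooled values are tied; otherwise the
  normal approximation with tie and continuity corrections. For groups
  above that size the per-stage tests are evaluated in a single
  vectorized call.
- "Continuously larger/smaller" is read as strict monotonicity of the
  signed fold-change sequence; adjacent ties are excluded by default
  (`strict=False` admits them). Strictness is the conservative reading:
  non-strict runs would admit genes that plateau.
- Constant genes produce p = 1 and fc = 0 (the tie-corrected variance
  is zero and the test degenerates to no evidence).

**Calibration under the shared baseline.** The five stage comparisons
share the NAU group, which induces a correlation of roughly
(1/n₀)/((1/n₀)+(1/nₛ)) ≈ 0.5 between their test statistics at equal
group sizes. Under the global null the probability that one gene passes
the full CDEG filter is therefore far above the independence product
α⁵·2⁻⁴ (Monte Carlo: ~9e-4 vs ~2e-8 at 30 samples per group). The
binomial calibration of the filter is consequently checked on five
independently drawn comparisons — the design for which the independence
expectation is the correct reference — while the shared-baseline cohort
is checked at the per-comparison level (type-I rate within 0.05 ± 0.01).

**Power at the default planted conditions.** With a per-stage step of
0.5 log2 units, unit noise and 30 samples per stage, the weakest
component test (Ta vs NAU, effect 0.5 σ) has ~0.45–0.48 power at
α = 0.05, and even a truly monotone gene's *sample* fold-change
sequence is strictly ordered only ~68% of the time. End-to-end
sensitivity of the monotone screen is therefore ~0.40 under these
conditions, with an observed false-discovery proportion of 0. This is
the intended operating point of the generator's defaults: single-stage
effects near the detection boundary, full-ramp effects clearly
detectable. A sensitivity near 0.9 would require per-stage effects of
roughly 0.85 σ or several-fold larger groups.

The NMI/MI concordance statistic pools Ta–T1 and T2–T4 samples,
recomputes per-gene fold changes vs NAU for each pool, and reports
their Spearman correlation (Spearman is the package-wide correlation
default).

## Single-sample gene-set and regulon activity

The per-sample enrichment score is the rank-weighted running-sum
statistic: genes are ranked by expression (average ranks on ties;
highest expression = largest rank), and walking the ranking from top to
bottom the score accumulates the gap between the in-set cumulative
distribution weighted by rank^α (α = 0.25) and the uniform out-of-set
cumulative distribution, normalized by the range of the walk. Scores
depend on a sample's values only through ranks and are exactly
invariant under strictly increasing per-sample transforms. Among the
family of single-sample enrichment variants, this rank-weighted
running-sum form was chosen because it is deterministic, closed-form,
and testable by direct summation; the kernel-density variant is not
implemented. Sets smaller than `min_size` (default 5) after restriction
to the matrix are dropped with a warning.

Two practical caveats the tests respect:

- **Saturation.** When a set's genes are pushed to the very top of the
  ranking (large planted effects), the walk saturates and the score
  plateaus; stage trends then flatten and strict monotonicity is lost.
  The score is informative in its dynamic range, not at the ceiling.
- **Compositionality.** Ranks are relative: strongly regulated planted
  genes displace unrelated genes in the ranking, so "null" sets can
  drift systematically when a large fraction of the transcriptome is
  regulated.

Monotone-pathway detection applies the identical test/concordance/
monotonicity stack to score rows — a monotone pathway is definitionally
a monotone gene with scores in place of expression, and the test suite
asserts the shared code path.

Regulon activity is the mean over a transcription factor's targets of
sign × per-gene z-score (z across samples): linear in the z-matrix,
antisymmetric under sign flips, and sufficient to expose coordinated
directional regulation. The stromal score is the single-sample
enrichment score of a user-supplied stromal gene set — an
enrichment-style surrogate carrying the same rank-invariance.

## Co-expression networks

Per condition, edge weights come from tree-ensemble regression: each
gene in turn is regressed on all other genes with a seeded random
forest (√p candidate features per split, 500 trees by default), and the
impurity importances are normalized to sum to one per target. Directed
importances are symmetrized by the pairwise maximum (preserving the
strongest directional evidence), and only pairs with Spearman ρ > 0
become edges. For n selected genes this enumerates n² per-condition
pair weights before filtering (9,659,664 for a 3108-gene selection).

Edge counts are set either as a fixed top-k (5600 is the retained
published operating point, counting unordered pairs after
symmetrization) or by binary search on k until the node count of the
resulting graph is closest to a target — by default half the selected
gene set (1554 for 3108 genes), the sizing that avoids network
saturation. Ties in the binary search resolve toward the smaller k, and
edge selection is monotone in k.

Communities come from seeded Louvain modularity optimization
(resolution 1.0); hubs from exact Brandes betweenness on the unweighted
selected graph. "Default cutoffs" for hub status are under-specified in
the field, so two readings are reported side by side: a global flag at
mean + 2 SD of betweenness, and the top 5 nodes per community.
Community over-representation uses the one-sided hypergeometric tail
with Benjamini–Hochberg correction across sets. Cross-condition
community matching takes the top 5 communities by gene count per
condition, matches greedily on Jaccard similarity above 0.2, and
reports the genes shared across all matched conditions.

## Immune deconvolution

Reference-based fraction estimation is nonnegative least squares of the
linear-scale mixture on a gene × cell-type signature matrix,
renormalized to sum to one per sample. It is a transparent surrogate
filling the role that support-vector deconvolution against a
proprietary signature matrix plays in practice; it reproduces the
role, not the exact numbers, and the signature matrix is supplied by
the user or the synthetic fixture. Log-scale input must be
exponentiated first (the CLI's `--log-scale` flag does this, logged).
A permutation goodness-of-fit p-value (add-one smoothed, so p ∈ (0,1])
shuffles each sample's gene values, refits, and compares fitted-vs-
observed Pearson correlations; samples with p above the threshold
(default 0.05) are excluded from stage comparisons. Identical reference
columns are rejected as non-identifiable. Stage comparisons reuse the
Mann–Whitney machinery per cell type (NAU vs tumor, each stage vs
rest) plus the monotone-trend stack on fraction columns.

## Prognostic signature and survival

The signature score of sample *i* over four risk-up genes A–D and four
risk-down genes E–H is

    S_i = Σ_up x_gi / Var(x_g) − Σ_down x_gi / Var(x_g)

with Var the n−1 sample variance across the scoring dataset (or frozen
from a training cohort; the caller chooses and the choice is logged).
The division is by the **variance**, exactly as defined — not the
standard deviation — which makes the score scale-dependent (scaling a
gene by c multiplies its term by 1/c); an SD-normalized variant sits
behind `normalize="sd"`. Terms are summed in sorted gene order so the
up/down role swap negates scores exactly in floating point.

Candidate screening fits one univariate Cox proportional-hazards model
per gene (partial likelihood, Efron ties, via lifelines) on follow-up
administratively truncated at 60 months — the 5-year endpoint — and
retains genes with Wald p < 0.01. The signature is built by
intersecting discovery and validation hits with concordant risk
direction; conflicting genes are excluded with a warning, and strict
mode requires at least two genes per role. Survival validation
dichotomizes scores at the cohort median (ties to the low group, so the
low group takes ⌈n/2⌉ samples), fits Kaplan–Meier curves per group with
the 60-month truncation, tests with the log-rank statistic, and fits
univariate (continuous score) and multivariate (score + stage) Cox
models; stage enters categorically by default, ordinally on request,
since the field does not standardize this encoding. The (time, event)
pair is treated generically; no endpoint semantics are imposed.

## Synthetic cohorts

The generator emulates a staged multi-batch meta-cohort: 6 conditions
× 30 samples, 2000 genes, 100 monotone-up + 50 monotone-down planted
genes with a per-stage mean increment of 0.5 log2 units, residual
Gaussian noise of 1.0 log2 units, and 3 batches crossed with stage
carrying additive per-batch, per-gene shifts of SD 0.5 log2 units (an
optional multiplicative component and a deliberately confounded layout
exist for pathological fixtures). Gene baselines are drawn around 7
log2 units. Three batches (rather than the dozen of a large public
compendium) keep every batch × stage cell populated at this cohort
size, which is what makes the correction identifiable. Survival is
exponential with hazard h₀·exp(β·score) tied to a planted per-sample
score drawn independently of stage — so the multivariate
"independent prognostic value" claim is testable — with h₀ set to a
36-month median, uniform censoring at a configurable rate (default
0.3) and administrative censoring at 120 months. Cell-type mixtures are
linear-scale products of a block-marker signature matrix and Dirichlet
fraction vectors plus Gaussian noise.

What the generator does **not** emulate: probe-level microarray
artifacts (saturation, probe effects), count noise, correlated gene
modules beyond the planted monotone structure, copy-number or mutation
signal, and real censoring mechanisms. Passing tests demonstrate the
estimators' correctness and calibration under a clean additive
log-normal world, not performance on real compendia.

## Known limitations

- The monotone screen's sensitivity is bounded by the power of its
  weakest component test; at the default planted conditions it is
  ~0.4 (see the power paragraph above). Its specificity is excellent.
- Batch correction leaves a finite-sample residual batch-mean gap of
  the order of the per-gene standard error; with 40 samples per batch
  that median gap is ~0.1 log2 units on a ±2-unit planted shift.
- The single-sample enrichment score saturates under extreme planted
  effects and is compositional across sets.
- Deconvolution assumes the reference spans the mixture; unmodeled cell
  types bias fractions toward the nearest modeled profile.
- The co-expression ensemble is quadratic in the number of genes; the
  published operating scale (3108 genes × 6 conditions) is supported
  structurally but is a long computation, and tests exercise the method
  at tens of genes.
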