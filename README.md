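# stagetrend

Stage-continuum analysis of multi-batch tumor transcriptomes.

Bladder cancer spans an ordered spectrum of pathologic stages — from
histologically normal urothelium adjacent to the tumor (NAU) through
non-muscle-invasive (Ta, T1) to muscle-invasive (T2–T4) disease.
`stagetrend` treats the stage as a checkpoint variable along a
molecular continuum and asks which genes and pathway activities change
*monotonically* along it, on the premise that monotone markers are the
natural candidates for prognosis. The package is aimed at
computational biologists working with multi-study expression
compendia: it covers the full chain from batch harmonization to a
survival-validated prognostic signature, and ships a synthetic-cohort
generator with planted ground truth so that every stage is testable
without external data.

## What it computes

- **Harmonization** (`stagetrend.batch`) — parametric empirical-Bayes
  location/scale batch correction (per-batch additive γ and
  multiplicative δ² effects shrunk toward normal / inverse-gamma
  priors), with the stage protected as a covariate by default, plus
  numeric QC: RLE summaries, PC1/PC2 variance explained by batch vs
  condition, stable-gene dispersion.
- **Stage-wise screening** (`stagetrend.stagewise`) — per stage s,
  a two-sided Mann–Whitney test of stage vs NAU and the fold change
  fc_s = mean(stage) − mean(NAU) on the log2 scale. A gene is a
  **CDEG** when p < 0.05 in all five comparisons with one consistent
  sign, and **monotone** when additionally
  fc_Ta < fc_T1 < fc_T2 < fc_T3 < fc_T4 (all positive; mirrored for
  down-genes).
- **Pathway activity** (`stagetrend.genesets`) — rank-weighted
  running-sum single-sample enrichment scores (weight rank^0.25,
  range-normalized), the same monotonicity screen on score rows,
  signed mean-z regulon activity, and an enrichment-style stromal
  score.
- **Co-expression networks** (`stagetrend.network`) — per-condition
  random-forest importance weights, positive-Spearman edge filtering
  with top-k or node-count-targeted cutoffs, seeded Louvain
  communities, exact betweenness hubs, hypergeometric community
  enrichment with BH correction, and cross-condition community
  matching.
- **Deconvolution** (`stagetrend.deconvolve`) — nonnegative
  least-squares immune-fraction estimation against a reference profile
  with a permutation goodness-of-fit p-value and stage-wise fraction
  comparisons.
- **Prognosis** (`stagetrend.survival`) — the variance-normalized
  eight-gene signature

      S_i = A_i/VarA + B_i/VarB + C_i/VarC + D_i/VarD
          − E_i/VarE − F_i/VarF − G_i/VarG − H_i/VarH

  over four risk-up and four risk-down genes, univariate Cox screening
  at the 5-year endpoint, discovery/validation intersection with
  concordant risk direction, and median-split Kaplan–Meier / log-rank /
  multivariate Cox validation.

## Worked example

```python
from stagetrend.simulate import SimulationConfig, simulate_cohort
from stagetrend.batch import combat, batch_qc
from stagetrend.stagewise import (
    stage_differential_table, select_cdegs, select_monotone_genes,
)
from stagetrend.survival import survival_analysis

cfg = SimulationConfig(seed=1)           # 2000 genes, 6 stages x 30, 3 batches
matrix, samples, truth = simulate_cohort(cfg)

corrected, model = combat(matrix, samples.batch, covariates=samples.stage)
qc = batch_qc(corrected, samples.batch, samples.stage)
print(qc.pc_r2.loc["PC1", "batch_r2"])   # 0.0000 — batch signal removed

det = stage_differential_table(corrected, samples)
cdegs = select_cdegs(det, alpha=0.05)
mono = select_monotone_genes(det, cdegs)
print(len(cdegs), len(mono))             # 67 CDEGs, 60 monotone (44 up / 16 down)

res = survival_analysis(truth.true_score, samples, covariates="stage")
print(res.five_year_survival)            # {'low': 0.64, 'high': 0.17}
print(res.logrank_p)                     # 1.9e-10
```

On this seed the screen recovers 60 of the 150 planted monotone genes
with zero false discoveries: the planted per-stage step (0.5 log2
units against unit noise at 30 samples/stage) deliberately sits near
the detection boundary of the weakest single-stage test, so the screen
is highly specific but only partially sensitive — see
`docs/methods.md` for the power analysis. The survival split shows the
planted prognostic score at work: high-score patients have a 17%
5-year survival probability against 64% in the low group, the score
stays significant in the multivariate model (p ≈ 9e-11), and every
stage term is null — the score's prognostic value is independent of
stage, exactly as planted.

A thin CLI wraps the same chain over TSV/GMT files:

```bash
stagetrend --seed 1 simulate --outdir out
stagetrend harmonize --expression out/expression.tsv --samples out/samples.tsv --outdir out
stagetrend de --expression out/expression_corrected.tsv --samples out/samples.tsv --outdir out
stagetrend pathways --expression out/expression_corrected.tsv \
    --samples out/samples.tsv --gmt out/gene_sets.gmt --outdir out
```

Subcommands `network`, `deconvolve`, `prognosis` and `run-all` cover
the rest of the pipeline; options may also come from a YAML config.

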