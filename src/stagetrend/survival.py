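"""Prognostic screening, the variance-normalized signature, survival.

The signature score of sample *i* over four risk-up genes A..D and four
risk-down genes E..H is

    S_i = A_i/Var(A) + B_i/Var(B) + C_i/Var(C) + D_i/Var(D)
        - E_i/Var(E) - F_i/Var(F) - G_i/Var(G) - H_i/Var(H),

each expression value divided by that gene's variance across the
scoring dataset so that highly variable genes do not dominate the sum.
The division is by the variance, not the standard deviation, which
makes the score scale-dependent; an SD-normalized variant is available
behind a flag.  Scores are dichotomized at the cohort median (ties to
the low group) for Kaplan-Meier comparison of 5-year outcomes, with
univariate and multivariate Cox models quantifying independent
prognostic value.

Survival fits are delegated to lifelines (Cox partial likelihood with
Efron tie handling, product-limit estimator, log-rank test).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .dataio import DataError, ExpressionMatrix, SampleTable

logger = logging.getLogger(__name__)

#: 5-year endpoint: follow-up administratively truncated at 60 months.
FIVE_YEARS_MONTHS = 60.0


@dataclass
class SignatureModel:
    """Four risk-up genes, four risk-down genes, per-gene variances."""

    up_genes: list[str]
    down_genes: list[str]
    variances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = self.up_genes + self.down_genes
        if len(set(genes)) != len(genes):
            raise DataError("signature genes must be distinct")
        for g, v in self.variances.items():
            if v <= 0:
                raise DataError(f"non-positive variance for gene {g!r}")

    @property
    def genes(self) -> list[str]:
        return self.up_genes + self.down_genes

    def to_json(self, path) -> None:
        payload = {
            "up_genes": self.up_genes,
            "down_genes": self.down_genes,
            "variances": self.variances,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def truncate_followup(
    time: pd.Series, event: pd.Series, horizon: float = FIVE_YEARS_MONTHS
) -> tuple[pd.Series, pd.Series]:
    """Administrative truncation at ``horizon`` months."""
    t = pd.to_numeric(time).astype(float)
    e = pd.to_numeric(event).astype(int)
    over = t > horizon
    t = t.where(~over, horizon)
    e = e.where(~over, 0)
    return t, e


def signature_score(
    matrix: ExpressionMatrix,
    model: SignatureModel,
    normalize: str = "variance",
) -> pd.Series:
    """Per-sample signature scores.

    Variances are taken from ``model.variances`` when frozen there
    (e.g. from a training cohort) and otherwise computed on ``matrix``
    with the n-1 sample variance.  ``normalize="sd"`` divides by the
    standard deviation instead.  A missing gene or a zero-variance gene
    is an error naming the gene.
    """
    if normalize not in ("variance", "sd"):
        raise ValueError(f"unknown normalize {normalize!r}")
    missing = set(model.genes) - set(matrix.genes)
    if missing:
        raise DataError(f"signature gene(s) missing from matrix: {sorted(missing)}")
    data = matrix.data
    score = pd.Series(0.0, index=data.columns, name="signature_score")
    # fixed summation order makes the up/down role swap an exact negation
    for gene in sorted(model.genes):
        var = model.variances.get(gene)
        if var is None:
            var = float(data.loc[gene].var(ddof=1))
        if var == 0 or not np.isfinite(var):
            raise DataError(f"zero variance for signature gene {gene!r}")
        denom = var if normalize == "variance" else float(np.sqrt(var))
        sign = 1.0 if gene in model.up_genes else -1.0
        score = score + sign * data.loc[gene] / denom
    return score


def screen_prognostic_genes(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    candidates: list[str],
    alpha: float = 0.01,
    horizon: float = FIVE_YEARS_MONTHS,
) -> pd.DataFrame:
    """Univariate Cox screen of candidate genes against 5-year outcome.

    Each candidate gene is fit alone in a Cox proportional-hazards model
    on follow-up truncated at ``horizon`` months.  Returns the genes
    with Wald p < alpha, with their log-hazard beta, hazard ratio and p,
    plus the risk direction implied by the beta sign.  Constant genes
    are skipped with a warning; a cohort without events is an error.
    """
    if not samples.has_survival():
        raise DataError("sample table lacks survival columns")
    samples.validate_against(matrix)
    missing = set(candidates) - set(matrix.genes)
    if missing:
        raise DataError(f"candidate gene(s) not in matrix: {sorted(missing)[:5]}")
    surv = samples.data[["time", "event"]].dropna()
    t, e = truncate_followup(surv["time"], surv["event"], horizon)
    if e.sum() == 0:
        raise DataError("no events within the follow-up horizon")
    rows = []
    for gene in candidates:
        x = matrix.data.loc[gene, surv.index]
        if x.nunique() <= 1:
            logger.warning("gene %s constant; skipped in Cox screen", gene)
            continue
        df = pd.DataFrame({"time": t, "event": e, "x": x.astype(float)})
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # convergence failures on degenerate genes
            logger.warning("Cox fit failed for %s: %s", gene, exc)
            continue
        beta = float(cph.params_["x"])
        p = float(cph.summary.loc["x", "p"])
        rows.append(
            {
                "gene": gene,
                "beta": beta,
                "hr": float(np.exp(beta)),
                "p": p,
                "risk_direction": "up" if beta > 0 else "down",
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    return (
        table[table["p"] < alpha]
        .sort_values("p", kind="stable")
        .reset_index(drop=True)
    )


def build_signature(
    discovery_hits: pd.DataFrame,
    validation_hits: pd.DataFrame,
    strict: bool = True,
) -> SignatureModel:
    """Intersect discovery and validation prognostic hits into a model.

    Both tables need ``gene`` and ``risk_direction`` columns.  A gene
    enters the model only when both cohorts agree on its risk direction;
    conflicting genes are excluded with a warning.  With ``strict``,
    fewer than two genes per role is an error.
    """
    disc = discovery_hits.set_index("gene")["risk_direction"]
    val = validation_hits.set_index("gene")["risk_direction"]
    common = disc.index.intersection(val.index)
    up, down = [], []
    for gene in common:
        if disc[gene] != val[gene]:
            logger.warning(
                "gene %s risk direction conflicts between cohorts; excluded", gene
            )
            continue
        (up if disc[gene] == "up" else down).append(gene)
    if strict and (len(up) < 2 or len(down) < 2):
        raise DataError(
            f"signature needs >=2 genes per role, got {len(up)} up / {len(down)} down"
        )
    return SignatureModel(up_genes=sorted(up), down_genes=sorted(down))


@dataclass
class SurvivalResult:
    """KM curves, log-rank p, and Cox fits for a score-stratified cohort."""

    km_tables: dict[str, pd.DataFrame]
    five_year_survival: dict[str, float]
    logrank_p: float | None
    univariate: pd.DataFrame
    multivariate: pd.DataFrame | None
    groups: pd.Series

    def to_json(self, path) -> None:
        payload = {
            "five_year_survival": self.five_year_survival,
            "logrank_p": self.logrank_p,
            "univariate": self.univariate.to_dict(orient="index"),
            "multivariate": None
            if self.multivariate is None
            else self.multivariate.to_dict(orient="index"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _km_table(kmf: KaplanMeierFitter) -> pd.DataFrame:
    table = kmf.event_table.copy()
    surv = kmf.survival_function_.iloc[:, 0]
    return pd.DataFrame(
        {
            "time": table.index,
            "at_risk": table["at_risk"].to_numpy(),
            "events": table["observed"].to_numpy(),
            "survival": surv.reindex(table.index).to_numpy(),
        }
    ).reset_index(drop=True)


def survival_analysis(
    scores: pd.Series,
    samples: SampleTable,
    covariates: pd.DataFrame | None = None,
    stage_encoding: str = "categorical",
    horizon: float = FIVE_YEARS_MONTHS,
) -> SurvivalResult:
    """Median-split KM comparison plus Cox models for a score.

    Samples at or below the median score form the low group.  KM curves
    and the log-rank test run on follow-up truncated at ``horizon``; a
    group without events still gets its KM curve, but the log-rank test
    is skipped with a warning.  The univariate Cox model uses the
    continuous score; when ``covariates`` are given (or the string
    ``"stage"``, encoded per ``stage_encoding``), a multivariate model
    quantifies the score's independent prognostic value.
    """
    if not samples.has_survival():
        raise DataError("sample table lacks survival columns")
    scores = scores.reindex(samples.samples).dropna()
    surv = samples.data.loc[scores.index, ["time", "event"]].dropna()
    scores = scores.loc[surv.index]
    t, e = truncate_followup(surv["time"], surv["event"], horizon)

    median = float(scores.median())
    groups = pd.Series(
        np.where(scores > median, "high", "low"), index=scores.index, name="group"
    )

    km_tables: dict[str, pd.DataFrame] = {}
    five_year: dict[str, float] = {}
    group_has_events = {}
    for g in ("low", "high"):
        members = groups.index[groups == g]
        kmf = KaplanMeierFitter(label=g)
        kmf.fit(t.loc[members], e.loc[members])
        km_tables[g] = _km_table(kmf)
        five_year[g] = float(kmf.predict(horizon))
        group_has_events[g] = bool(e.loc[members].sum() > 0)

    logrank_p: float | None = None
    if all(group_has_events.values()):
        low, high = groups == "low", groups == "high"
        res = logrank_test(
            t[low.to_numpy()], t[high.to_numpy()],
            e[low.to_numpy()], e[high.to_numpy()],
        )
        logrank_p = float(res.p_value)
    else:
        logger.warning("a group has zero events; log-rank test skipped")

    uni_df = pd.DataFrame({"time": t, "event": e, "score": scores})
    cox_cols = ["coef", "exp(coef)", "coef lower 95%", "coef upper 95%", "p"]
    if e.sum() == 0:
        logger.warning("no events within the horizon; Cox models skipped")
        univariate = pd.DataFrame(columns=cox_cols)
        return SurvivalResult(
            km_tables=km_tables,
            five_year_survival=five_year,
            logrank_p=logrank_p,
            univariate=univariate,
            multivariate=None,
            groups=groups,
        )
    cph = CoxPHFitter()
    cph.fit(uni_df, duration_col="time", event_col="event")
    univariate = cph.summary[cox_cols].copy()

    multivariate = None
    cov_df = None
    if isinstance(covariates, str) and covariates == "stage":
        cov_df = _encode_stage(samples.stage.loc[scores.index], stage_encoding)
    elif covariates is not None:
        cov_df = covariates.reindex(scores.index)
    if cov_df is not None:
        multi_df = pd.concat([uni_df, cov_df], axis=1).dropna()
        cph2 = CoxPHFitter(penalizer=1e-6)
        cph2.fit(multi_df, duration_col="time", event_col="event")
        multivariate = cph2.summary[cox_cols].copy()

    return SurvivalResult(
        km_tables=km_tables,
        five_year_survival=five_year,
        logrank_p=logrank_p,
        univariate=univariate,
        multivariate=multivariate,
        groups=groups,
    )


def _encode_stage(stage: pd.Series, encoding: str) -> pd.DataFrame:
    if encoding == "ordinal":
        return pd.DataFrame({"stage_ordinal": stage.cat.codes.astype(float)})
    if encoding == "categorical":
        dummies = pd.get_dummies(stage, prefix="stage", drop_first=True, dtype=float)
        present = dummies.columns[dummies.sum(axis=0) > 0]
        return dummies[present]
    raise ValueError(f"unknown stage encoding {encoding!r}")
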