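"""Empirical-Bayes location/scale batch harmonization and QC diagnostics.

:func:`combat` implements the canonical parametric empirical-Bayes
batch-correction algorithm for log-scale expression: per-gene
standardization against a covariate-adjusted grand mean and pooled
variance, per-batch additive (gamma) and multiplicative (delta^2)
effect estimates, shrinkage toward normal / inverse-gamma priors whose
hyperparameters are fixed by the method of moments across genes, and a
back-transform.  The biological condition (stage) is protected as a
covariate by default so that correction does not absorb the signal of
interest; pass ``covariates=None`` to disable.

:func:`batch_qc` re-expresses the usual batch-diagnostic plots as
numbers: per-sample relative log expression (RLE) medians and IQRs, the
share of the top two principal components explained by batch versus by
condition, and the cross-batch dispersion of a user-flagged panel of
stable (housekeeping-like) genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)

EB_CONV_TOL = 1e-4
EB_MAX_ITER = 100


@dataclass
class BatchModel:
    """Fitted location/scale batch model.

    ``gamma_hat``/``delta2_hat`` are raw per-batch, per-gene estimates on
    the standardized scale; ``gamma_star``/``delta2_star`` the
    EB-shrunken versions; ``gamma_bar``/``tau2`` and
    ``a_prior``/``b_prior`` the normal and inverse-gamma hyperparameters;
    ``grand_mean``/``var_pooled`` the per-gene standardization constants.
    """

    batches: list[str]
    gamma_hat: pd.DataFrame
    delta2_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    gamma_bar: pd.Series
    tau2: pd.Series
    a_prior: pd.Series
    b_prior: pd.Series
    grand_mean: pd.Series
    var_pooled: pd.Series
    covariate_levels: list[str]


def _one_hot(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(labels))
    mat = np.stack([(labels == lv).to_numpy(float) for lv in levels], axis=1)
    return mat, levels


def combat(
    matrix: ExpressionMatrix,
    batches: pd.Series,
    covariates: pd.Series | None = None,
) -> tuple[ExpressionMatrix, BatchModel]:
    """Remove additive and multiplicative batch effects by parametric EB.

    ``batches`` maps each sample to its batch; ``covariates`` optionally
    gives a per-sample condition label to protect.  Every batch needs at
    least two samples, and no batch may coincide exactly with a single
    covariate level (perfect confounding makes the model unidentifiable).
    Returns the corrected matrix (same genes/samples, same order) and
    the fitted :class:`BatchModel`.
    """
    data = matrix.data
    batches = pd.Series(batches).reindex(data.columns)
    if batches.isna().any():
        raise DataError("batch label missing for some samples")
    counts = batches.value_counts()
    singles = counts[counts < 2]
    if len(singles):
        raise DataError(f"batch with a single sample: {list(singles.index)}")

    batch_design, batch_levels = _one_hot(batches.astype(str))
    n_batch = len(batch_levels)
    n_batches = batch_design.sum(axis=0)
    n_array = float(len(data.columns))

    cov_levels: list[str] = []
    if covariates is not None and n_batch > 1:
        covariates = pd.Series(covariates).reindex(data.columns)
        cov_full, cov_levels_all = _one_hot(covariates.astype(str))
        for b, blev in enumerate(batch_levels):
            for c, clev in enumerate(cov_levels_all):
                in_batch = batch_design[:, b] == 1
                if np.array_equal(in_batch, cov_full[:, c] == 1):
                    raise DataError(
                        f"batch {blev!r} perfectly confounded with "
                        f"covariate level {clev!r}"
                    )
        cov_design = cov_full[:, 1:]  # drop first level: reference
        cov_levels = cov_levels_all[1:]
        design = np.concatenate([batch_design, cov_design], axis=1)
    else:
        design = batch_design

    if n_batch == 1:
        # nothing to correct against; the algorithm would standardize and
        # invert exactly, so short-circuit to the identity
        model = BatchModel(
            batches=batch_levels,
            gamma_hat=pd.DataFrame(0.0, index=batch_levels, columns=data.index),
            delta2_hat=pd.DataFrame(1.0, index=batch_levels, columns=data.index),
            gamma_star=pd.DataFrame(0.0, index=batch_levels, columns=data.index),
            delta2_star=pd.DataFrame(1.0, index=batch_levels, columns=data.index),
            gamma_bar=pd.Series(0.0, index=batch_levels),
            tau2=pd.Series(0.0, index=batch_levels),
            a_prior=pd.Series(np.nan, index=batch_levels),
            b_prior=pd.Series(np.nan, index=batch_levels),
            grand_mean=data.mean(axis=1),
            var_pooled=data.var(axis=1, ddof=0),
            covariate_levels=cov_levels,
        )
        return ExpressionMatrix(data.copy()), model

    X = data.to_numpy()  # genes x samples

    # least-squares fit of the full design; batch coefficients first
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    grand_mean = (n_batches / n_array) @ beta[:n_batch, :]
    resid = X - (design @ beta).T
    var_pooled = (resid**2).sum(axis=1) / n_array
    if np.any(var_pooled == 0):
        zero = data.index[var_pooled == 0].tolist()
        raise DataError(f"gene(s) with zero pooled variance: {zero[:5]}")

    stand_mean = np.tile(grand_mean[:, None], (1, int(n_array)))
    if design.shape[1] > n_batch:
        cov_part = design.copy()
        cov_part[:, :n_batch] = 0
        stand_mean = stand_mean + (cov_part @ beta).T
    sd = np.sqrt(var_pooled)[:, None]
    Z = (X - stand_mean) / sd

    batch_members = [np.flatnonzero(batch_design[:, b] == 1) for b in range(n_batch)]
    gamma_hat = np.stack([Z[:, m].mean(axis=1) for m in batch_members])
    delta2_hat = np.stack([Z[:, m].var(axis=1, ddof=1) for m in batch_members])

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1)
    # inverse-gamma hyperparameters by the method of moments
    d_mean = delta2_hat.mean(axis=1)
    d_var = delta2_hat.var(axis=1, ddof=1)
    a_prior = (2 * d_var + d_mean**2) / d_var
    b_prior = (d_mean * d_var + d_mean**3) / d_var

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    for b, members in enumerate(batch_members):
        gamma_star[b], delta2_star[b] = _eb_iterate(
            Z[:, members],
            gamma_hat[b],
            delta2_hat[b],
            gamma_bar[b],
            tau2[b],
            a_prior[b],
            b_prior[b],
        )

    adjusted = Z.copy()
    for b, members in enumerate(batch_members):
        adjusted[:, members] = (
            Z[:, members] - gamma_star[b][:, None]
        ) / np.sqrt(delta2_star[b])[:, None]
    corrected = adjusted * sd + stand_mean

    out = ExpressionMatrix(
        pd.DataFrame(corrected, index=data.index, columns=data.columns)
    )
    model = BatchModel(
        batches=batch_levels,
        gamma_hat=pd.DataFrame(gamma_hat, index=batch_levels, columns=data.index),
        delta2_hat=pd.DataFrame(delta2_hat, index=batch_levels, columns=data.index),
        gamma_star=pd.DataFrame(gamma_star, index=batch_levels, columns=data.index),
        delta2_star=pd.DataFrame(delta2_star, index=batch_levels, columns=data.index),
        gamma_bar=pd.Series(gamma_bar, index=batch_levels),
        tau2=pd.Series(tau2, index=batch_levels),
        a_prior=pd.Series(a_prior, index=batch_levels),
        b_prior=pd.Series(b_prior, index=batch_levels),
        grand_mean=pd.Series(grand_mean, index=data.index),
        var_pooled=pd.Series(var_pooled, index=data.index),
        covariate_levels=cov_levels,
    )
    return out, model


def _eb_iterate(z, g_hat, d2_hat, g_bar, t2, a, b):
    """Conditional-posterior iteration for the EB estimates of one batch."""
    n = z.shape[1]
    g_old, d_old = g_hat.copy(), d2_hat.copy()
    for _ in range(EB_MAX_ITER):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        ss = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * ss + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / d_old),
        )
        g_old, d_old = g_new, d_new
        if change < EB_CONV_TOL:
            break
    return g_old, d_old


# ---------------------------------------------------------------------------
# QC diagnostics


@dataclass
class QCReport:
    """Numeric batch-QC summary.

    ``rle`` has per-sample RLE median and IQR; ``pc_r2`` the fraction of
    PC1/PC2 variance explained by batch and by condition;
    ``stable_gene_dispersion`` the mean across flagged stable genes of
    the variance of their batch means (NaN when no panel was given).
    """

    rle: pd.DataFrame
    pc_r2: pd.DataFrame
    stable_gene_dispersion: float

    def to_json(self, path) -> None:
        payload = {
            "rle": self.rle.to_dict(orient="index"),
            "pc_r2": self.pc_r2.to_dict(orient="index"),
            "stable_gene_dispersion": self.stable_gene_dispersion,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _r2_oneway(values: np.ndarray, labels: pd.Series) -> float:
    """Coefficient of determination of a one-way group-mean fit."""
    y = values - values.mean()
    sst = float((y**2).sum())
    if sst == 0:
        return 0.0
    ssr = 0.0
    for lv in pd.unique(labels):
        grp = y[(labels == lv).to_numpy()]
        ssr += float(((grp - grp.mean()) ** 2).sum())
    return 1.0 - ssr / sst


def batch_qc(
    matrix: ExpressionMatrix,
    batches: pd.Series,
    condition: pd.Series | None = None,
    stable_genes: list[str] | None = None,
) -> QCReport:
    """Quantitative batch diagnostics on an expression matrix.

    Relative log expression is each sample's deviation from the
    gene-wise median; well-behaved data have per-sample RLE medians near
    zero.  PC1/PC2 of the centered matrix are each regressed (one-way)
    on batch and on condition; a large batch R^2 flags residual batch
    structure.  When ``stable_genes`` are given, the mean variance of
    their batch means quantifies the housekeeping contrast.
    """
    data = matrix.data
    batches = pd.Series(batches).reindex(data.columns)
    if batches.nunique() < 2:
        raise DataError("batch QC requires at least 2 batches")

    rle_dev = data.sub(data.median(axis=1), axis=0)
    rle = pd.DataFrame(
        {
            "rle_median": rle_dev.median(axis=0),
            "rle_iqr": rle_dev.quantile(0.75, axis=0)
            - rle_dev.quantile(0.25, axis=0),
        }
    )

    centered = data.to_numpy() - data.to_numpy().mean(axis=1, keepdims=True)
    # samples x genes SVD; PCs are the sample coordinates
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    pcs = u[:, :2] * s[:2]
    rows = {}
    for k in range(2):
        row = {"batch_r2": _r2_oneway(pcs[:, k], batches)}
        if condition is not None:
            cond = pd.Series(condition).reindex(data.columns)
            row["condition_r2"] = _r2_oneway(pcs[:, k], cond)
        row["variance_share"] = float(s[k] ** 2 / (s**2).sum())
        rows[f"PC{k + 1}"] = row
    pc_r2 = pd.DataFrame(rows).T

    dispersion = float("nan")
    if stable_genes:
        present = [g for g in stable_genes if g in data.index]
        if present:
            sub = data.loc[present]
            batch_means = sub.T.groupby(batches, observed=True).mean()
            dispersion = float(batch_means.var(axis=0, ddof=1).mean())
    return QCReport(rle=rle, pc_r2=pc_r2, stable_gene_dispersion=dispersion)
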