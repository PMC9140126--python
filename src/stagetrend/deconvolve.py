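"""Reference-based immune-fraction estimation and stage comparisons.

Per sample, cell-type fractions are obtained by nonnegative least
squares of the linear-scale mixture on a gene x cell-type reference
profile, renormalized to sum to one.  A permutation goodness-of-fit
p-value guards against meaningless fits: the sample's gene values are
shuffled ``n_perm`` times, the NNLS fit is repeated, and p is the
(add-one smoothed) fraction of shuffles whose fitted-vs-observed
Pearson correlation reaches the observed one.  Samples that fail the
fit test are excluded from downstream stage comparisons, which reuse
the Mann-Whitney and monotone-trend machinery on fraction columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .dataio import DataError, ExpressionMatrix, SampleTable, TUMOR_STAGES
from .stagewise import mann_whitney, select_cdegs, select_monotone_genes, stage_differential_table

logger = logging.getLogger(__name__)


@dataclass
class FractionTable:
    """Estimated fractions plus per-sample fit diagnostics."""

    fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    rmse: pd.Series
    p_value: pd.Series

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if (f < -1e-12).any():
            raise DataError("negative fraction")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise DataError("fractions must sum to 1 per sample")


def _fit_sample(ref: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    coef, _ = nnls(ref, y)
    fitted = ref @ coef
    rmse = float(np.sqrt(np.mean((fitted - y) ** 2)))
    if fitted.std() == 0 or y.std() == 0:
        corr = 0.0
    else:
        corr = float(stats.pearsonr(fitted, y).statistic)
    return coef, rmse, corr


def estimate_fractions(
    mixtures: ExpressionMatrix,
    reference: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
) -> FractionTable:
    """NNLS deconvolution of linear-scale mixtures on a reference panel.

    ``reference`` is genes x cell types on the linear scale; its genes
    must all be present in the mixtures.  Identical reference columns
    make the problem non-identifiable and are an error.  ``n_perm``
    below 100 gives a coarse p-value and triggers a warning.
    """
    if reference.shape[1] < 2:
        raise DataError("need at least 2 cell types")
    cols = reference.columns
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if np.allclose(reference[cols[i]], reference[cols[j]]):
                raise DataError(
                    f"identical reference columns: {cols[i]!r}, {cols[j]!r}"
                )
    missing = set(reference.index) - set(mixtures.genes)
    if missing:
        raise DataError(f"reference genes absent from mixtures: {sorted(missing)[:5]}")
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: permutation p-values are coarse", n_perm)

    rng = np.random.default_rng(seed)
    ref = reference.to_numpy(dtype=float)
    panel = mixtures.data.loc[list(reference.index)].to_numpy(dtype=float)

    frac_rows, rmses, pvals = [], [], []
    for j, sample in enumerate(mixtures.samples):
        y = panel[:, j]
        coef, rmse, corr = _fit_sample(ref, y)
        total = coef.sum()
        fractions = coef / total if total > 0 else np.full(len(coef), 1.0 / len(coef))
        exceed = 0
        for _ in range(n_perm):
            y_perm = rng.permutation(y)
            _, _, corr_perm = _fit_sample(ref, y_perm)
            if corr_perm >= corr:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
        frac_rows.append(fractions)
        rmses.append(rmse)
        pvals.append(p)
    fractions = pd.DataFrame(
        frac_rows, index=mixtures.samples, columns=list(reference.columns)
    )
    return FractionTable(
        fractions=fractions,
        rmse=pd.Series(rmses, index=mixtures.samples, name="rmse"),
        p_value=pd.Series(pvals, index=mixtures.samples, name="p"),
    )


def compare_fractions(
    fractions: FractionTable,
    samples: SampleTable,
    p_threshold: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Stage-wise comparisons of estimated cell-type fractions.

    Samples whose deconvolution permutation p >= ``p_threshold`` are
    dropped first.  For every cell type the table reports the NAU-vs-
    tumor Mann-Whitney p, each stage-vs-rest p, and a monotone-trend
    flag from the stage-vs-NAU monotonicity stack applied to the
    fraction column.  Groupings with fewer than two samples per side
    are skipped with a warning.
    """
    keep = fractions.p_value.index[fractions.p_value < p_threshold]
    kept = fractions.fractions.loc[[s for s in keep if s in samples.samples]]
    if kept.empty:
        raise DataError("no sample passed the deconvolution fit filter")
    ann = samples.data.loc[kept.index]
    stage = ann["stage"]

    monotone_flags: dict[str, bool] = {}
    try:
        as_matrix = ExpressionMatrix(kept.T.copy())
        sub_table = SampleTable(ann.copy())
        det = stage_differential_table(as_matrix, sub_table)
        cdegs = select_cdegs(det, alpha=alpha)
        mono = select_monotone_genes(det, cdegs)
        monotone_flags = {
            ct: mono.directions.get(ct, None) for ct in kept.columns
        }
    except DataError as exc:
        logger.warning("monotone-trend screen skipped: %s", exc)
        monotone_flags = {ct: None for ct in kept.columns}

    is_tumor = stage != "NAU"
    rows = []
    for ct in kept.columns:
        row: dict[str, object] = {"cell_type": ct}
        x = kept.loc[~is_tumor, ct].to_numpy()
        y = kept.loc[is_tumor, ct].to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            _, row["p_nau_vs_tumor"] = mann_whitney(x, y)
            row["nau_minus_tumor"] = float(x.mean() - y.mean())
        else:
            logger.warning("NAU-vs-tumor grouping too small for %s", ct)
            row["p_nau_vs_tumor"] = np.nan
            row["nau_minus_tumor"] = np.nan
        for st in TUMOR_STAGES:
            in_stage = (stage == st).to_numpy()
            if in_stage.sum() >= 2 and (~in_stage).sum() >= 2:
                _, row[f"p_{st}_vs_rest"] = mann_whitney(
                    kept.loc[in_stage, ct].to_numpy(),
                    kept.loc[~in_stage, ct].to_numpy(),
                )
            else:
                row[f"p_{st}_vs_rest"] = np.nan
        row["monotone_direction"] = monotone_flags.get(ct)
        rows.append(row)
    return pd.DataFrame(rows)
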