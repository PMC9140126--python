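"""Single-sample gene-set activity, regulon activity, stromal scores.

The single-sample enrichment score is the rank-weighted running-sum
statistic: per sample, genes are ranked by expression; walking down the
ranking, an in-set cumulative distribution weighted by rank^alpha is
compared with the uniform out-of-set cumulative distribution, and the
score is the sum of the gap over the whole walk, normalized by the
range of the walk.  Scores therefore depend on a sample's values only
through their ranks and are exactly invariant under any strictly
increasing per-sample transform.

Monotone-pathway detection reuses the stage-vs-NAU machinery verbatim
on score rows, so a "monotone pathway" is definitionally a monotone
gene with scores in place of expression.

Regulon activity is a signed mean of target z-scores: simple, linear,
and sufficient to expose coordinated directional regulation of a
transcription factor's targets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DataError, ExpressionMatrix, GeneSetCollection, SampleTable
from .stagewise import MonotoneSet, select_cdegs, select_monotone_genes, stage_differential_table

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25
DEFAULT_MIN_SIZE = 5


def _sample_score(ranks: np.ndarray, order: np.ndarray, in_set: np.ndarray,
                  alpha: float) -> float:
    """Running-sum score for one sample.

    ``ranks`` are ascending ranks (highest expression = largest rank),
    ``order`` walks genes from highest to lowest expression, ``in_set``
    flags membership.
    """
    n = len(ranks)
    members = in_set[order]
    w = ranks[order] ** alpha
    w_in = np.where(members, w, 0.0).cumsum()
    n_out = n - members.sum()
    cdf_in = w_in / w_in[-1] if w_in[-1] > 0 else np.zeros(n)
    if n_out > 0:
        cdf_out = np.where(~members, 1.0, 0.0).cumsum() / n_out
    else:
        cdf_out = np.zeros(n)
    walk = cdf_in - cdf_out
    rng = walk.max() - walk.min()
    total = walk.sum()
    if rng == 0:
        return 0.0
    return float(total / rng)


def ssgsea(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    min_size: int = DEFAULT_MIN_SIZE,
) -> pd.DataFrame:
    """Single-sample enrichment scores, sets x samples.

    Sets are restricted to the matrix genes; sets falling below
    ``min_size`` after restriction are dropped with a warning.  Ties in
    expression receive average ranks.
    """
    if len(sets) == 0:
        raise DataError("empty gene-set collection")
    usable = sets.restrict_to(matrix.genes, min_size=min_size)
    if len(usable) == 0:
        raise DataError("no gene set meets min_size after restriction")
    genes = pd.Index(matrix.genes)
    membership = {
        name: np.asarray(genes.isin(members))
        for name, members in usable.sets.items()
    }
    values = matrix.data.to_numpy()
    scores = np.empty((len(usable.sets), values.shape[1]))
    for j in range(values.shape[1]):
        col = values[:, j]
        ranks = stats.rankdata(col, method="average")  # ascending: top gene = n
        order = np.argsort(-col, kind="stable")
        for i, name in enumerate(usable.sets):
            scores[i, j] = _sample_score(ranks, order, membership[name], alpha)
    return pd.DataFrame(scores, index=list(usable.sets), columns=matrix.samples)


def monotone_pathways(
    scores: pd.DataFrame,
    samples: SampleTable,
    alpha: float = 0.05,
) -> MonotoneSet:
    """Pathways whose activity is monotone across the stage continuum.

    Applies the identical stage-vs-NAU test / concordance / strict
    monotonicity stack used for genes to the score rows.
    """
    as_matrix = ExpressionMatrix(scores.copy())
    table = stage_differential_table(as_matrix, samples)
    cdegs = select_cdegs(table, alpha=alpha)
    return select_monotone_genes(table, cdegs)


def regulon_activity(
    matrix: ExpressionMatrix,
    regulons: GeneSetCollection,
    min_size: int = 1,
) -> pd.DataFrame:
    """Signed mean target z-score per regulon and sample.

    Each gene is z-scored across samples; a regulon's activity in a
    sample is the mean over its targets of sign x z.  Regulons with no
    overlapping targets are dropped with a warning.  The returned frame
    carries the number of used targets in ``.attrs["n_targets"]``.
    """
    signed = {n: regulons.signs.get(n) for n in regulons.sets}
    if any(s is None for s in signed.values()):
        unsigned = [n for n, s in signed.items() if s is None]
        raise DataError(f"regulons without signs: {unsigned[:5]}")
    usable = regulons.restrict_to(matrix.genes, min_size=max(1, min_size))
    if len(usable) == 0:
        raise DataError("no regulon has targets in the matrix")
    data = matrix.data
    z = data.sub(data.mean(axis=1), axis=0).div(data.std(axis=1, ddof=1), axis=0)
    rows, n_targets = {}, {}
    for name, targets in usable.sets.items():
        sgn = pd.Series(usable.signs[name])
        rows[name] = z.loc[targets].mul(sgn.loc[targets], axis=0).mean(axis=0)
        n_targets[name] = len(targets)
    out = pd.DataFrame(rows).T
    out.attrs["n_targets"] = n_targets
    return out


def stromal_score(
    matrix: ExpressionMatrix,
    stromal_set: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """Per-sample stromal infiltration surrogate.

    The single-sample enrichment score of a user-supplied stromal gene
    set; an enrichment-style stand-in for dedicated stromal-infiltration
    estimators, with the same rank-invariance properties as
    :func:`ssgsea`.
    """
    if len(stromal_set) != 1:
        raise DataError("stromal_score expects exactly one gene set")
    scores = ssgsea(matrix, stromal_set, alpha=alpha, min_size=1)
    return scores.iloc[0].rename("stromal_score")
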