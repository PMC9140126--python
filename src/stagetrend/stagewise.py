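"""Stage-vs-baseline differential testing and the monotonicity screen.

Every tumor stage (Ta..T4) is compared against the non-malignant
adjacent urothelium (NAU) baseline with a two-sided Mann-Whitney U test;
the fold change is the difference of log2 group means, mean(stage) -
mean(NAU) -- a difference, never a ratio.  A gene is *concordantly
differentially expressed* (CDEG) when it is significant in all five
comparisons with one consistent direction of change, and *monotone*
when, in addition, its fold-change sequence across Ta->T4 is strictly
increasing (all positive) or strictly decreasing (all negative).

Significance is deliberately unadjusted (default alpha = 0.05): the
screen stacks five significance filters plus a concordance and a strict
monotonicity filter, and adjusting each component test would compound
Type-II error across the stack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DataError, ExpressionMatrix, SampleTable, TUMOR_STAGES

logger = logging.getLogger(__name__)

#: Largest per-group size for which the exact Mann-Whitney null is used.
EXACT_MAX_N = 8
#: Largest fraction of tied values for which the exact null is trusted.
EXACT_MAX_TIE_SHARE = 0.25


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of first group, p).

    The exact permutation null is used when the smaller group has at
    most 8 observations and no more than 25% of the pooled values are
    tied; otherwise the normal approximation with tie and continuity
    corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("Mann-Whitney groups must be non-empty")
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_share = counts[counts > 1].sum() / pooled.size
    if min(x.size, y.size) <= EXACT_MAX_N and tie_share <= EXACT_MAX_TIE_SHARE:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def stage_differential_table(
    matrix: ExpressionMatrix, samples: SampleTable
) -> pd.DataFrame:
    """Per-gene, per-stage U, p and fold change vs the NAU baseline.

    Returns a long-format DETable with columns ``gene, stage, U, p, fc``
    (fc in log2 units).  Stages with fewer than two samples are skipped
    with a warning; an absent NAU group is an error.
    """
    samples.validate_against(matrix)
    nau = samples.stage_samples("NAU")
    if not nau:
        raise DataError("no NAU baseline samples")
    if len(nau) < 2:
        raise DataError("need at least 2 NAU samples")
    x_nau = matrix.data[nau].to_numpy()
    nau_mean = x_nau.mean(axis=1)

    frames = []
    for stage in TUMOR_STAGES:
        members = samples.stage_samples(stage)
        if len(members) < 2:
            logger.warning("stage %s skipped: %d sample(s)", stage, len(members))
            continue
        x_stage = matrix.data[members].to_numpy()
        fc = x_stage.mean(axis=1) - nau_mean
        if min(len(members), len(nau)) > EXACT_MAX_N:
            res = stats.mannwhitneyu(
                x_stage, x_nau, alternative="two-sided", method="asymptotic", axis=1
            )
            u = np.asarray(res.statistic, dtype=float)
            p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
        else:
            u = np.empty(matrix.shape[0])
            p = np.empty(matrix.shape[0])
            for i in range(matrix.shape[0]):
                u[i], p[i] = mann_whitney(x_stage[i], x_nau[i])
        frames.append(
            pd.DataFrame(
                {"gene": matrix.genes, "stage": stage, "U": u, "p": p, "fc": fc}
            )
        )
    if not frames:
        raise DataError("no stage had enough samples to test")
    return pd.concat(frames, ignore_index=True)


def _pivot(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    stages = [s for s in TUMOR_STAGES if s in set(table["stage"])]
    p = table.pivot(index="gene", columns="stage", values="p")[stages]
    fc = table.pivot(index="gene", columns="stage", values="fc")[stages]
    return p, fc


def select_cdegs(table: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Concordantly differentially expressed genes and their direction.

    A gene qualifies iff p < alpha in every tested stage comparison and
    the fold-change sign is identical (and nonzero) in all of them.
    Returns a Series gene -> direction ('up'/'down').
    """
    p, fc = _pivot(table)
    sig = (p < alpha).all(axis=1)
    all_up = (fc > 0).all(axis=1)
    all_down = (fc < 0).all(axis=1)
    keep = sig & (all_up | all_down)
    direction = pd.Series(
        np.where(all_up[keep], "up", "down"), index=p.index[keep], name="direction"
    )
    return direction.sort_index()


@dataclass
class MonotoneSet:
    """Genes passing the monotonicity screen, with audit trail.

    ``directions`` maps gene -> 'up'/'down'; ``fold_changes`` retains
    the Ta..T4 fc sequence of every member for audit.
    """

    directions: pd.Series
    fold_changes: pd.DataFrame

    def __len__(self) -> int:
        return len(self.directions)

    @property
    def up_genes(self) -> list[str]:
        return list(self.directions.index[self.directions == "up"])

    @property
    def down_genes(self) -> list[str]:
        return list(self.directions.index[self.directions == "down"])

    def to_frame(self) -> pd.DataFrame:
        out = self.fold_changes.copy()
        out.columns = [f"fc_{s}" for s in out.columns]
        out.insert(0, "direction", self.directions)
        return out


def select_monotone_genes(
    table: pd.DataFrame,
    cdegs: pd.Series,
    strict: bool = True,
) -> MonotoneSet:
    """Monotone genes: CDEGs whose fc sequence is strictly monotone.

    An up-gene has fc(Ta) < fc(T1) < ... < fc(T4) with every fc > 0; a
    down-gene mirrors this.  Adjacent ties are excluded under the
    default strict reading (``strict=False`` admits non-strict runs).
    """
    p, fc = _pivot(table)
    missing = set(cdegs.index) - set(fc.index)
    if missing:
        raise DataError(f"CDEGs not in DETable: {sorted(missing)[:5]}")
    fc = fc.loc[cdegs.index]
    diffs = fc.to_numpy()[:, 1:] - fc.to_numpy()[:, :-1]
    if strict:
        increasing = (diffs > 0).all(axis=1)
        decreasing = (diffs < 0).all(axis=1)
    else:
        increasing = (diffs >= 0).all(axis=1)
        decreasing = (diffs <= 0).all(axis=1)
    up = increasing & (fc.to_numpy() > 0).all(axis=1) & (cdegs == "up").to_numpy()
    down = decreasing & (fc.to_numpy() < 0).all(axis=1) & (cdegs == "down").to_numpy()
    keep = up | down
    directions = pd.Series(
        np.where(up[keep], "up", "down"), index=fc.index[keep], name="direction"
    )
    return MonotoneSet(directions=directions, fold_changes=fc.loc[directions.index])


def logfc_concordance(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    nmi_stages: tuple[str, ...] = ("Ta", "T1"),
    mi_stages: tuple[str, ...] = ("T2", "T3", "T4"),
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlation between NAU-vs-NMI and NAU-vs-MI fold-change vectors.

    Samples are pooled within the non-muscle-invasive (Ta, T1) and
    muscle-invasive (T2-T4) groups, per-gene fold changes vs NAU are
    recomputed on the pooled groups, and their Spearman (default) rank
    correlation is returned with its p-value.
    """
    samples.validate_against(matrix)
    nau = samples.stage_samples("NAU")
    if not nau:
        raise DataError("no NAU baseline samples")
    nmi = [s for st in nmi_stages for s in samples.stage_samples(st)]
    mi = [s for st in mi_stages for s in samples.stage_samples(st)]
    if not nmi or not mi:
        raise DataError("empty NMI or MI pool")
    base = matrix.data[nau].mean(axis=1)
    fc_nmi = matrix.data[nmi].mean(axis=1) - base
    fc_mi = matrix.data[mi].mean(axis=1) - base
    if method == "spearman":
        r, p = stats.spearmanr(fc_nmi, fc_mi)
    elif method == "pearson":
        r, p = stats.pearsonr(fc_nmi, fc_mi)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def write_detable(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_monotone_set(monotone: MonotoneSet, path) -> None:
    monotone.to_frame().to_csv(path, sep="\t", index_label="gene")
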