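"""Synthetic multi-batch staged cohorts with planted ground truth.

The generator emulates the structure of a staged tumor meta-cohort: six
ordered conditions (NAU and five tumor stages), several batches crossed
with stage, a subset of genes planted with strictly monotone stage
trends, additive (optionally multiplicative) batch effects on the log2
scale, gene-set fixtures, cell-type mixtures for deconvolution, and
survival times tied to a planted per-sample prognostic score.

Defaults follow the study conditions the pipeline is meant to exercise:
30 samples per condition, 2000 genes, 100 monotone-up and 50
monotone-down genes with a per-stage step of 0.5 log2 units, residual
noise of 1.0 log2 units, and three batches crossed with stage.  The
planted per-stage step and noise level put single-stage effects near the
detection boundary while leaving the full Ta-T4 ramp clearly detectable,
which is the regime a monotonicity screen is designed for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import (
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
    STAGES,
    TUMOR_STAGES,
)

logger = logging.getLogger(__name__)

#: Baseline log2 intensity around which gene means are drawn.
BASELINE_MEAN = 7.0
BASELINE_SD = 1.0

#: Baseline hazard for simulated survival: median 36 months at score 0.
BASELINE_HAZARD = np.log(2.0) / 36.0

#: Administrative censoring horizon (months) for simulated follow-up.
ADMIN_CENSOR_MONTHS = 120.0


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_per_stage: dict[str, int] = field(
        default_factory=lambda: {s: 30 for s in STAGES}
    )
    n_genes: int = 2000
    n_monotone_up: int = 100
    n_monotone_down: int = 50
    step: float = 0.5            # per-stage mean increment, log2 units
    n_batches: int = 3
    batch_shift_sd: float = 0.5  # sd of per-batch, per-gene additive shifts
    batch_scale_sd: float = 0.0  # sd of per-batch log variance inflation
    confounded: bool = False     # pathological fixture: batch == stage blocks
    noise_sd: float = 1.0        # residual sd, log2 units
    n_gene_sets: int = 10
    set_size: int = 25
    survival_beta: float = float(np.log(2.0))  # log-hazard per score unit
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_stage.values()):
            raise DataError("negative per-stage sample count")
        if self.n_monotone_up + self.n_monotone_down > self.n_genes:
            raise DataError("more planted monotone genes than genes")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if not 0 <= self.censor_rate < 1:
            raise DataError("censor_rate must be in [0, 1)")
        if self.n_batches < 1:
            raise DataError("need at least one batch")


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    monotone_up_genes: list[str]
    monotone_down_genes: list[str]
    batch_assignments: pd.Series
    true_score: pd.Series
    true_fractions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if set(self.monotone_up_genes) & set(self.monotone_down_genes):
            raise DataError("planted up and down gene lists overlap")


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleTable, GroundTruth]:
    """Simulate a staged multi-batch cohort with planted monotone genes.

    A planted up-gene has stage means ``mu, mu+step, ..., mu+5*step``
    across NAU..T4 (down-genes mirrored); all other genes share one mean
    across stages.  Gaussian noise (``noise_sd``) is added per cell, then
    a per-batch, per-gene additive shift drawn from N(0, batch_shift_sd)
    (and an optional multiplicative scale distortion) is applied on top
    of the biology.  Batches are crossed with stage unless ``confounded``
    is set.  The same seed reproduces the output exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    up = genes[: config.n_monotone_up]
    down = genes[config.n_monotone_up : config.n_monotone_up + config.n_monotone_down]

    samples: list[str] = []
    stages: list[str] = []
    for stage in STAGES:
        for k in range(config.n_per_stage.get(stage, 0)):
            samples.append(f"{stage}_{k:03d}")
            stages.append(stage)
    n = len(samples)
    stage_idx = np.array([STAGES.index(s) for s in stages])

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_genes)
    means = np.tile(baseline[:, None], (1, n))
    means[: len(up), :] += config.step * stage_idx[None, :]
    means[len(up) : len(up) + len(down), :] -= config.step * stage_idx[None, :]

    values = means + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))

    # batch structure: crossed with stage (round-robin within stage) unless
    # deliberately confounded (contiguous stage blocks per batch)
    if config.confounded:
        batch_idx = (
            np.floor(np.arange(n) / max(1, n / config.n_batches))
            .astype(int)
            .clip(max=config.n_batches - 1)
        )
    else:
        batch_idx = np.zeros(n, dtype=int)
        for s in range(len(STAGES)):
            members = np.flatnonzero(stage_idx == s)
            batch_idx[members] = np.arange(len(members)) % config.n_batches
    batch_labels = np.array([f"B{b}" for b in batch_idx])

    shifts = rng.normal(0.0, config.batch_shift_sd, size=(config.n_batches, config.n_genes))
    values += shifts[batch_idx, :].T
    if config.batch_scale_sd > 0:
        scales = np.exp(
            rng.normal(0.0, config.batch_scale_sd, size=(config.n_batches, config.n_genes))
        )
        centered = values - means - shifts[batch_idx, :].T
        values = means + shifts[batch_idx, :].T + centered * scales[batch_idx, :].T

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))

    true_score = pd.Series(rng.standard_normal(n), index=samples, name="true_score")
    time, event = simulate_survival(true_score, config, rng=rng)

    ages = np.round(rng.normal(68, 9, size=n)).clip(35, 95)
    sexes = rng.choice(["M", "F"], size=n, p=[0.78, 0.22])
    table = SampleTable(
        pd.DataFrame(
            {
                "stage": stages,
                "batch": batch_labels,
                "age": ages,
                "sex": sexes,
                "time": time.to_numpy(),
                "event": event.to_numpy(),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = GroundTruth(
        monotone_up_genes=up,
        monotone_down_genes=down,
        batch_assignments=pd.Series(batch_labels, index=samples, name="batch"),
        true_score=true_score,
    )
    logger.info(
        "simulated cohort: %d genes x %d samples, %d batches, seed=%d",
        config.n_genes, n, config.n_batches, config.seed,
    )
    return matrix, table, truth


def simulate_survival(
    score: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Exponential survival tied to a per-sample score.

    Event times are exponential with hazard ``h0 * exp(survival_beta *
    score)``.  Each subject is independently censored with probability
    ``censor_rate`` at a time uniform on (0, event time); everyone still
    at risk at 120 months is administratively censored there.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    s = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(s)):
        raise DataError("scores must be finite")
    hazard = BASELINE_HAZARD * np.exp(config.survival_beta * s)
    t_event = rng.exponential(1.0 / hazard)
    event = np.ones(len(s), dtype=int)
    time = t_event.copy()
    if config.censor_rate > 0:
        censored = rng.random(len(s)) < config.censor_rate
        time[censored] = rng.uniform(0.0, t_event[censored])
        event[censored] = 0
    admin = time > ADMIN_CENSOR_MONTHS
    time[admin] = ADMIN_CENSOR_MONTHS
    event[admin] = 0
    index = score.index if isinstance(score, pd.Series) else pd.RangeIndex(len(s))
    return (
        pd.Series(time, index=index, name="time"),
        pd.Series(event, index=index, name="event"),
    )


def simulate_mixtures(
    reference: pd.DataFrame,
    fractions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Linear-scale cell-type mixtures ``reference @ fractions.T`` + noise.

    ``reference`` is genes x cell types (linear scale, nonnegative);
    ``fractions`` is samples x cell types with nonnegative rows summing
    to 1.  The result stays on the linear scale, which is where
    reference-based deconvolution operates.
    """
    if (fractions.to_numpy() < 0).any():
        raise DataError("negative mixture fraction")
    sums = fractions.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise DataError("mixture fractions must sum to 1 per sample")
    if list(reference.columns) != list(fractions.columns):
        fractions = fractions[list(reference.columns)]
    mixed = reference.to_numpy() @ fractions.to_numpy().T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mixed = mixed + rng.normal(0.0, noise_sd, size=mixed.shape)
    df = pd.DataFrame(mixed, index=reference.index, columns=fractions.index)
    return ExpressionMatrix(df)


def make_reference_profiles(
    n_genes: int = 200,
    cell_types: tuple[str, ...] = ("CD8T", "CD4T", "NK", "Mono", "M2"),
    n_markers: int = 20,
    marker_level: float = 100.0,
    base_level: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic linear-scale signature matrix: each cell type gets a
    disjoint block of high markers over a shared low background."""
    rng = np.random.default_rng(seed)
    n_markers = min(n_markers, n_genes // len(cell_types))
    genes = [f"R{i:04d}" for i in range(n_genes)]
    ref = pd.DataFrame(
        rng.uniform(0.5 * base_level, 1.5 * base_level, size=(n_genes, len(cell_types))),
        index=genes,
        columns=list(cell_types),
    )
    for j, ct in enumerate(cell_types):
        block = slice(j * n_markers, (j + 1) * n_markers)
        ref.iloc[block, j] = marker_level * rng.uniform(0.8, 1.2, size=n_markers)
    return ref


def make_gene_sets(truth: GroundTruth, config: SimulationConfig) -> GeneSetCollection:
    """Gene-set fixtures keyed to the planted truth.

    Emits one set of the planted monotone-up genes, one of the planted
    monotone-down genes, ``n_gene_sets`` decoy sets drawn without
    replacement from non-planted genes, and one signed regulon whose
    "TF" targets are planted genes with the matching mode of regulation
    (+1 for up-targets, -1 for down-targets).
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    planted = set(truth.monotone_up_genes) | set(truth.monotone_down_genes)
    pool = [g for g in genes if g not in planted]
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    signs: dict[str, dict[str, int]] = {}
    if truth.monotone_up_genes:
        sets["PLANTED_UP"] = list(truth.monotone_up_genes)
        desc["PLANTED_UP"] = "planted monotone-up genes"
    if truth.monotone_down_genes:
        sets["PLANTED_DOWN"] = list(truth.monotone_down_genes)
        desc["PLANTED_DOWN"] = "planted monotone-down genes"
    for k in range(config.n_gene_sets):
        name = f"DECOY_{k:02d}"
        sets[name] = list(rng.choice(pool, size=config.set_size, replace=False))
        desc[name] = "random decoy set of non-planted genes"
    if planted:
        targets = list(truth.monotone_up_genes) + list(truth.monotone_down_genes)
        sets["TF_PLANTED"] = targets
        desc["TF_PLANTED"] = "signed regulon over planted genes"
        signs["TF_PLANTED"] = {
            **{g: 1 for g in truth.monotone_up_genes},
            **{g: -1 for g in truth.monotone_down_genes},
        }
    return GeneSetCollection(sets, desc, signs)
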