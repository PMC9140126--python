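"""Signature scoring, prognostic screening, KM/Cox validation."""

import numpy as np
import pandas as pd
import pytest

from stagetrend.dataio import DataError, ExpressionMatrix, SampleTable
from stagetrend.simulate import SimulationConfig, simulate_cohort, simulate_survival
from stagetrend.survival import (
    SignatureModel,
    build_signature,
    screen_prognostic_genes,
    signature_score,
    survival_analysis,
)


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(2)
    data = pd.DataFrame(
        rng.normal(7, 2, (8, 6)), index=list("ABCDEFGH"),
        columns=[f"s{i}" for i in range(6)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def toy_model():
    return SignatureModel(
        up_genes=list("ABCD"), down_genes=list("EFGH"),
        variances={g: float(i + 1) for i, g in enumerate("ABCDEFGH")},
    )


class TestSignatureScore:
    def test_matches_hand_computed_eight_term_sum(self, toy_matrix, toy_model):
        scores = signature_score(toy_matrix, toy_model)
        for s in toy_matrix.samples:
            manual = sum(
                toy_matrix.data.loc[g, s] / toy_model.variances[g] for g in "ABCD"
            ) - sum(
                toy_matrix.data.loc[g, s] / toy_model.variances[g] for g in "EFGH"
            )
            assert scores[s] == pytest.approx(manual, rel=1e-12)

    def test_swapping_roles_negates_scores_exactly(self, toy_matrix, toy_model):
        swapped = SignatureModel(
            up_genes=toy_model.down_genes, down_genes=toy_model.up_genes,
            variances=toy_model.variances,
        )
        np.testing.assert_allclose(
            signature_score(toy_matrix, swapped),
            -signature_score(toy_matrix, toy_model),
        )

    def test_zero_variance_gene_raises_naming_the_gene(self, toy_matrix):
        flat = toy_matrix.data.copy()
        flat.loc["C"] = 5.0
        model = SignatureModel(up_genes=list("ABCD"), down_genes=list("EFGH"))
        with pytest.raises(DataError, match="C"):
            signature_score(ExpressionMatrix(flat), model)

    def test_linearity_constant_shift_moves_scores_by_c_over_var(
        self, toy_matrix, toy_model
    ):
        base = signature_score(toy_matrix, toy_model)
        shifted = toy_matrix.data.copy()
        shifted.loc["A"] += 3.0
        moved = signature_score(ExpressionMatrix(shifted), toy_model)
        np.testing.assert_allclose(
            moved - base, 3.0 / toy_model.variances["A"], atol=1e-12
        )

    def test_missing_gene_is_an_error(self, toy_matrix, toy_model):
        dropped = ExpressionMatrix(toy_matrix.data.drop(index="H"))
        with pytest.raises(DataError, match="H"):
            signature_score(dropped, toy_model)

    def test_sd_variant_scales_terms_by_sd(self, toy_matrix, toy_model):
        sd_scores = signature_score(toy_matrix, toy_model, normalize="sd")
        manual = sum(
            toy_matrix.data.loc[g] / np.sqrt(toy_model.variances[g]) for g in "ABCD"
        ) - sum(
            toy_matrix.data.loc[g] / np.sqrt(toy_model.variances[g]) for g in "EFGH"
        )
        np.testing.assert_allclose(sd_scores, manual)


class TestScreenPrognosticGenes:
    def _cohort_with_prognostic_gene(self, seed, beta=np.log(2.0), n=500):
        rng = np.random.default_rng(seed)
        samples = [f"p{i}" for i in range(n)]
        risky = rng.integers(0, 2, n).astype(float)
        X = pd.DataFrame(
            rng.normal(7, 1, (20, n)),
            index=[f"g{i}" for i in range(20)], columns=samples,
        )
        X.loc["g0"] = risky + rng.normal(0, 0.01, n)
        cfg = SimulationConfig(survival_beta=beta, censor_rate=0.2, seed=seed + 1)
        t, e = simulate_survival(pd.Series(risky, index=samples), cfg)
        table = SampleTable(pd.DataFrame(
            {"stage": ["T2"] * n, "time": t, "event": e}, index=samples
        ))
        return ExpressionMatrix(X), table

    def test_planted_hazard_gene_detected_with_beta_near_truth(self):
        betas = []
        for seed in range(10):
            m, table = self._cohort_with_prognostic_gene(400 + seed)
            res = screen_prognostic_genes(m, table, m.genes, alpha=0.01)
            assert "g0" in set(res["gene"])
            betas.append(float(res.set_index("gene").loc["g0", "beta"]))
        assert abs(np.mean(betas) - np.log(2)) < 0.15

    def test_null_gene_retention_near_alpha(self):
        rng = np.random.default_rng(99)
        n, ng = 300, 400
        samples = [f"p{i}" for i in range(n)]
        X = pd.DataFrame(
            rng.normal(7, 1, (ng, n)),
            index=[f"g{i}" for i in range(ng)], columns=samples,
        )
        cfg = SimulationConfig(survival_beta=0.0, censor_rate=0.2, seed=7)
        t, e = simulate_survival(pd.Series(np.zeros(n), index=samples), cfg)
        table = SampleTable(pd.DataFrame(
            {"stage": ["T2"] * n, "time": t, "event": e}, index=samples
        ))
        res = screen_prognostic_genes(ExpressionMatrix(X), table, list(X.index),
                                      alpha=0.05)
        rate = len(res) / ng
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / ng)

    def test_flipping_gene_sign_flips_beta(self):
        m, table = self._cohort_with_prognostic_gene(55)
        res = screen_prognostic_genes(m, table, ["g0"], alpha=0.5)
        flipped = m.data.copy()
        flipped.loc["g0"] = -flipped.loc["g0"]
        res2 = screen_prognostic_genes(
            ExpressionMatrix(flipped), table, ["g0"], alpha=0.5
        )
        b1 = float(res.set_index("gene").loc["g0", "beta"])
        b2 = float(res2.set_index("gene").loc["g0", "beta"])
        assert b2 == pytest.approx(-b1, rel=1e-6)


class TestBuildSignature:
    def _hits(self, genes, direction):
        return pd.DataFrame({
            "gene": genes,
            "risk_direction": direction if isinstance(direction, list)
            else [direction] * len(genes),
        })

    def test_concordant_intersection_split_by_direction(self):
        disc = self._hits([f"g{i}" for i in range(1, 11)],
                          ["up"] * 5 + ["down"] * 5)
        val = self._hits([f"g{i}" for i in range(3, 13)],
                         ["up"] * 3 + ["down"] * 7)
        model = build_signature(disc, val)
        assert set(model.up_genes) == {"g3", "g4", "g5"}
        assert set(model.down_genes) == {"g6", "g7", "g8", "g9", "g10"}

    def test_direction_conflict_excluded(self, caplog):
        disc = self._hits(["a", "b", "c", "d", "e"],
                          ["up", "up", "down", "down", "up"])
        val = self._hits(["a", "b", "c", "d", "e"],
                         ["up", "down", "down", "down", "up"])
        with caplog.at_level("WARNING"):
            model = build_signature(disc, val)
        assert "b" not in model.genes
        assert "b" in caplog.text

    def test_strict_mode_requires_two_genes_per_role(self):
        disc = self._hits(["a", "b", "c"], ["up", "up", "up"])
        val = self._hits(["a", "b", "c"], ["up", "up", "up"])
        with pytest.raises(DataError):
            build_signature(disc, val, strict=True)
        model = build_signature(disc, val, strict=False)
        assert model.up_genes == ["a", "b", "c"]


class TestSurvivalAnalysis:
    def _table(self, t, e, stage=None, index=None):
        idx = index or [f"p{i}" for i in range(len(t))]
        return SampleTable(pd.DataFrame(
            {"stage": stage or ["T2"] * len(t), "time": t, "event": e}, index=idx
        ))

    def test_km_matches_hand_computed_product_limit(self):
        table = self._table([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        scores = pd.Series(
            [0.0, 0.0, 0.0, 1.0, 1.0, 1.0], index=table.samples
        )
        res = survival_analysis(scores, table)
        pooled = pd.concat(res.km_tables.values())
        # low group: times 1,2,3 events 1,1,0 -> S(1)=2/3, S(2)=1/3
        low = res.km_tables["low"].set_index("time")["survival"]
        assert low.loc[1.0] == pytest.approx(2 / 3)
        assert low.loc[2.0] == pytest.approx(1 / 3)
        # high group: times 4,5,6 events 1,0,1 -> S(4)=2/3, S(6)=0
        high = res.km_tables["high"].set_index("time")["survival"]
        assert high.loc[4.0] == pytest.approx(2 / 3)
        assert high.loc[6.0] == pytest.approx(0.0)
        assert (pooled["survival"].dropna() <= 1).all()

    def test_median_split_sizes_and_tie_policy(self):
        scores = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0],
                           index=[f"p{i}" for i in range(5)])
        table = self._table([5] * 5, [1] * 5)
        res = survival_analysis(scores, table)
        assert (res.groups == "low").sum() == 3  # ties at the median go low
        assert (res.groups == "high").sum() == 2

    def test_no_events_gives_flat_curves_and_no_logrank(self):
        table = self._table([70, 80, 90, 100], [0, 0, 0, 0])
        scores = pd.Series([0, 0, 1, 1.0], index=table.samples)
        res = survival_analysis(scores, table)
        assert res.five_year_survival["low"] == pytest.approx(1.0)
        assert res.five_year_survival["high"] == pytest.approx(1.0)
        assert res.logrank_p is None

    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(4)
        n = 200
        cfg = SimulationConfig(survival_beta=0.0, censor_rate=0.2, seed=5)
        t, e = simulate_survival(pd.Series(np.zeros(n)), cfg)
        idx = [f"p{i}" for i in range(n)]
        table = self._table(list(t), list(e), index=idx)
        scores = pd.Series(rng.standard_normal(n), index=idx)
        res = survival_analysis(scores, table)
        hr = float(res.univariate["exp(coef)"].iloc[0])
        assert 0.7 < hr < 1.4
        assert res.logrank_p > 0.01

    def test_score_independent_of_stage_retains_significance(self):
        """Survival tied to the planted score, stage unrelated: the
        multivariate model keeps the score and nulls the stage."""
        score_hits = stage_hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_genes=20, n_monotone_up=0, n_monotone_down=0,
                n_batches=1, batch_shift_sd=0.0, seed=800 + seed,
            )
            _, table, truth = simulate_cohort(cfg)
            res = survival_analysis(
                truth.true_score, table, covariates="stage",
                stage_encoding="ordinal",
            )
            score_hits += float(res.multivariate.loc["score", "p"]) < 0.05
            stage_hits += float(res.multivariate.loc["stage_ordinal", "p"]) < 0.05
        assert score_hits >= 0.9 * n_seeds
        # stage is a null covariate: significant at most at the nominal
        # rate plus 3 binomial SDs (0.05*20 + 3*sqrt(20*0.05*0.95) ~ 3.9)
        assert stage_hits <= 4

    def test_time_unit_rescaling_leaves_beta_unchanged(self):
        rng = np.random.default_rng(10)
        n = 300
        score = pd.Series(rng.standard_normal(n), index=[f"p{i}" for i in range(n)])
        cfg = SimulationConfig(survival_beta=0.7, censor_rate=0.2, seed=11)
        t, e = simulate_survival(score, cfg)
        table = self._table(list(t), list(e), index=list(score.index))
        res1 = survival_analysis(score, table, horizon=60.0)
        table2 = self._table(list(t * 30.44), list(e), index=list(score.index))
        res2 = survival_analysis(score, table2, horizon=60.0 * 30.44)
        b1 = float(res1.univariate["coef"].iloc[0])
        b2 = float(res2.univariate["coef"].iloc[0])
        assert b1 == pytest.approx(b2, rel=1e-6)
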