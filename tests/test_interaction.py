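"""Exclusions, thyroid classification, interaction models, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lociscreen import assoc, interaction as ia
from lociscreen import synthdata as sd


class TestApplyExclusions:
    def test_overlapping_fixture_leaves_9730(self):
        flags = sd.exclusion_fixture(10_146)
        cohort = pd.concat(
            [pd.DataFrame({"sample_id": [f"S{i}" for i in range(10_146)]}), flags],
            axis=1,
        )
        out, report = ia.apply_exclusions(cohort)
        assert report["excluded_union"] == 416
        assert report["n_after"] == 9_730
        assert len(out) == 9_730
        # count identity: n_out = n_in - |union of flags|
        assert report["n_after"] == report["n_before"] - report["excluded_union"]

    def test_no_flags_set_is_identity(self):
        cohort = pd.DataFrame({"x": [1, 2, 3], "goiter": [False] * 3})
        out, report = ia.apply_exclusions(cohort, flags=["goiter"])
        pd.testing.assert_frame_equal(out, cohort)
        assert report["excluded_union"] == 0

    def test_all_flagged_warns_and_empties(self):
        cohort = pd.DataFrame({"x": [1, 2], "goiter": [True, True]})
        with pytest.warns(UserWarning, match="all individuals"):
            out, _ = ia.apply_exclusions(cohort, flags=["goiter"])
        assert out.empty


class TestClassifyThyroid:
    def test_rule_table(self):
        status = ia.classify_thyroid(
            tsh=[1.38, 2.0, 0.39, 5.0, 0.4, 3.8],
            levothyroxine=[False, True, False, False, False, False],
            thiamazole=[False, False, False, False, False, False],
        )
        assert list(status.category) == [
            "normal",        # mid-range TSH, no meds
            "hypothyroid",   # levothyroxine dominates normal TSH
            "hyperthyroid",  # TSH below 0.4
            "hypothyroid",   # TSH above 3.8
            "normal",        # boundary: strict inequalities
            "normal",
        ]
        assert status.basis[1] == "medication"

    def test_antithyroid_drug_dominates(self):
        status = ia.classify_thyroid(tsh=[5.0], thiamazole=[True])
        assert status.category[0] == "hyperthyroid"

    def test_unclassifiable_raises(self):
        with pytest.raises(ValueError, match="unclassifiable"):
            ia.classify_thyroid(tsh=[np.nan], levothyroxine=[False])

    def test_category_rates_match_calibration(self):
        """Synthetic cohort calibrated to the study's thyroid category
        rates: hyper ~1.7%, normal ~88.5%, hypo ~9.8%."""
        truth = sd.GroundTruth(n_individuals=60_000, seed=21)
        _, cohort = sd.simulate_cohort(truth)
        status = ia.classify_thyroid(
            cohort["tsh"], cohort["levothyroxine"], cohort["thiamazole"],
            cohort["propylthiouracil"],
        )
        frac = pd.Series(status.category).value_counts(normalize=True)
        for cat, target in [("hyperthyroid", 0.017), ("normal", 0.885), ("hypothyroid", 0.098)]:
            tol = 4 * np.sqrt(target * (1 - target) / 60_000) + 0.01
            assert frac[cat] == pytest.approx(target, abs=tol)


def _interaction_cohort(gamma, n=10_000, seed=0):
    truth = sd.GroundTruth(
        n_individuals=n,
        loci=[sd.LocusSpec("L", maf=0.3, beta_gfr=-0.02)],
        interaction_gamma=gamma,
        interaction_locus="L",
        seed=seed,
    )
    return sd.simulate_cohort(truth), truth


class TestContinuousInteraction:
    def test_generated_coefficient_recovered(self):
        (dosages, cohort), truth = _interaction_cohort(gamma=0.01)
        res = ia.fit_interaction_continuous(
            cohort["true_ln_egfr"], dosages.values[:, 0], cohort["tsh"],
            cohort[["age", "sex"]],
        )
        assert res.b_interaction == pytest.approx(0.01, abs=3 * res.se_interaction)

    def test_centering_invariance(self):
        (dosages, cohort), _ = _interaction_cohort(gamma=0.01, n=2_000, seed=3)
        raw = ia.fit_interaction_continuous(
            cohort["true_ln_egfr"], dosages.values[:, 0], cohort["tsh"],
        )
        centered = ia.fit_interaction_continuous(
            cohort["true_ln_egfr"], dosages.values[:, 0],
            cohort["tsh"] - cohort["tsh"].mean(),
        )
        assert centered.b_interaction == pytest.approx(raw.b_interaction, rel=1e-9)
        assert centered.p_interaction == pytest.approx(raw.p_interaction, rel=1e-6)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(4)
        n = 1_000
        y = rng.normal(size=n)
        tsh = rng.lognormal(0.355, 0.596, n)
        pvals = []
        for _ in range(200):
            d = rng.binomial(2, 0.3, n).astype(float)
            pvals.append(ia.fit_interaction_continuous(y, d, tsh).p_interaction)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCategoricalInteraction:
    def test_hypo_specific_effect_doubling(self):
        rng = np.random.default_rng(5)
        n = 12_000
        d = rng.binomial(2, 0.3, n).astype(float)
        hypo = rng.random(n) < 0.3
        cat = np.where(hypo, "hypothyroid", "normal")
        beta = -0.02
        y = beta * d + beta * d * hypo + rng.normal(0, 0.15, n)  # doubled in hypo
        status = ia.ThyroidStatus(category=cat, basis=np.full(n, "tsh_threshold"))
        results = ia.fit_interaction_categorical(y, d, status)
        assert len(results) == 1  # no hyperthyroid stratum -> contrast skipped
        res = results[0]
        assert res.model == "hypo_vs_normal"
        assert res.b_interaction == pytest.approx(beta, abs=3 * res.se_interaction)
        assert res.b_snp == pytest.approx(beta, abs=0.01)

    def test_all_normal_cohort_skips_both_contrasts(self):
        n = 200
        status = ia.ThyroidStatus(
            category=np.full(n, "normal"), basis=np.full(n, "tsh_threshold")
        )
        with pytest.warns(UserWarning, match="empty stratum"):
            results = ia.fit_interaction_categorical(
                np.random.randn(n), np.random.binomial(2, 0.3, n).astype(float), status
            )
        assert results == []


class TestSignificanceAndPrediction:
    @pytest.mark.parametrize("p,expected", [
        (0.00177, True),       # reported significant interaction
        (0.05 / 11, False),    # boundary is strict
        (0.03, False),         # nominal only
    ])
    def test_threshold(self, p, expected):
        assert ia.interaction_significant(p) is expected

    def test_parallel_lines_without_interaction(self):
        fit = ia.InteractionResult(
            rsid="v", model="continuous_tsh", b_snp=-0.01, b_env=0.001,
            b_interaction=0.0, se_interaction=0.001, p_interaction=0.9,
            n=100, env_mean=1.5, env_sd=0.9,
            cov_snp_inter=np.array([[1e-6, 0.0], [0.0, 1e-8]]),
        )
        pred = ia.predict_at_tsh_levels(fit)
        assert pred["snp_slope"].nunique() == 1

    def test_slope_difference_identity(self):
        fit = ia.InteractionResult(
            rsid="v", model="continuous_tsh", b_snp=-0.01, b_env=0.001,
            b_interaction=0.004, se_interaction=0.001, p_interaction=0.01,
            n=100, env_mean=1.5, env_sd=0.9,
            cov_snp_inter=np.array([[1e-6, 0.0], [0.0, 1e-8]]),
        )
        pred = ia.predict_at_tsh_levels(fit)
        diff = pred["snp_slope"].iloc[2] - pred["snp_slope"].iloc[0]
        assert diff == pytest.approx(2 * 0.9 * 0.004, rel=1e-9)

    def test_fitted_model_matches_closed_form_prediction(self):
        (dosages, cohort), _ = _interaction_cohort(gamma=0.02, n=3_000, seed=6)
        res = ia.fit_interaction_continuous(
            cohort["true_ln_egfr"], dosages.values[:, 0], cohort["tsh"]
        )
        pred = ia.predict_at_tsh_levels(res, levels=[2.0])
        assert pred["snp_slope"].iloc[0] == pytest.approx(
            res.b_snp + 2.0 * res.b_interaction, rel=1e-12
        )


class TestSensitivityChecks:
    def test_missingness_flag_independent_of_genotype(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.3, 2_000).astype(float)
        flag = rng.random(2_000) < 0.05
        p = ia.missingness_genotype_check(d, flag)
        assert p > 0.001

    def test_genotype_driven_missingness_detected(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.3, 1_000).astype(float)
        p = ia.missingness_genotype_check(d, d > 0)
        assert p < 1e-10

    def test_one_empty_group_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            ia.missingness_genotype_check(np.ones(10), np.zeros(10, dtype=bool))

    def test_municipality_adjustment_stable_when_independent(self, cohort_with_mediator):
        """Adding municipality as a covariate moves the SNP effect by far
        less than half a standard error when it is independent of genotype."""
        truth, dosages, cohort = cohort_with_mediator
        d = dosages.column("L1_lead")
        y = cohort["ln_egfr"].to_numpy()
        pcs = [f"PC{i}" for i in range(1, 11)]
        b0, se0, _ = assoc.fit_snp_model(y, d, cohort[["age", "sex"] + pcs])
        b1, _, _ = assoc.fit_snp_model(
            y, d, cohort[["age", "sex", "municipality"] + pcs]
        )
        assert abs(b1 - b0) < 0.5 * se0
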