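"""One-sided locus re-testing, LD, harmonization, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lociscreen import assoc
from lociscreen import synthdata as sd
from lociscreen.types import DosageMatrix, VariantRecord


class TestResidualize:
    def test_orthogonal_covariates_center_only(self):
        rng = np.random.default_rng(0)
        n = 2_000
        age = rng.uniform(20, 80, n)
        sex = rng.choice(["male", "female"], n)
        y = rng.normal(5.0, 1.0, n)  # independent of age/sex
        resid = assoc.residualize_outcome(y, age, sex)
        assert resid.mean() == pytest.approx(0.0, abs=1e-10)
        assert np.corrcoef(resid, y - y.mean())[0, 1] > 0.99

    def test_pure_age_effect_removed(self):
        age = np.linspace(20, 80, 100)
        sex = ["male", "female"] * 50
        resid = assoc.residualize_outcome(2.0 * age, age, sex)
        np.testing.assert_allclose(resid, 0.0, atol=1e-8)

    def test_known_coefficients_recovered(self):
        rng = np.random.default_rng(1)
        n = 5_000
        age = rng.uniform(20, 80, n)
        female = rng.random(n) < 0.5
        y = 4.5 - 0.004 * age + 0.02 * female + rng.normal(0, 0.1, n)
        resid = assoc.residualize_outcome(y, age, np.where(female, "female", "male"))
        # least-squares oracle: residuals orthogonal to the design
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-10
        assert abs(np.corrcoef(resid, female)[0, 1]) < 1e-10


class TestFitSnpModel:
    def test_known_slope_recovered(self):
        rng = np.random.default_rng(2)
        n = 10_000
        d = rng.binomial(2, 0.3, n).astype(float)
        y = 0.01 * d + rng.normal(0, 0.2, n)
        b, se, p = assoc.fit_snp_model(y, d)
        assert b == pytest.approx(0.01, abs=3 * se)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(3)
        n, reps = 400, 400
        rejections = 0
        y = rng.normal(size=n)
        for _ in range(reps):
            d = rng.binomial(2, 0.3, n).astype(float)
            _, _, p = assoc.fit_snp_model(y, d)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_constant_dosage_raises(self):
        with pytest.raises(ValueError, match="constant"):
            assoc.fit_snp_model(np.random.randn(100), np.ones(100))

    def test_collinear_covariate_named(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.3, 200).astype(float)
        cov = pd.DataFrame({"PC1": rng.normal(size=200)})
        cov["PC1_copy"] = cov["PC1"] * 2.0
        with pytest.raises(ValueError, match="PC1"):
            assoc.fit_snp_model(rng.normal(size=200), d, cov)

    def test_matches_simple_regression_when_covariates_orthogonal(self):
        rng = np.random.default_rng(5)
        n = 3_000
        d = rng.binomial(2, 0.4, n).astype(float)
        y = 0.02 * d + rng.normal(0, 0.1, n)
        b_plain, _, _ = assoc.fit_snp_model(y, d)
        # covariate orthogonalized against dosage: slope must be identical
        z = rng.normal(size=n)
        z -= np.polyval(np.polyfit(d, z, 1), d)
        b_adj, _, _ = assoc.fit_snp_model(y, d, pd.DataFrame({"z": z}))
        assert b_adj == pytest.approx(b_plain, abs=1e-12)


class TestOneSidedP:
    def test_zero_effect_gives_half(self):
        assert assoc.one_sided_p(0.0, 1.0, "-") == pytest.approx(0.5)

    def test_published_locus_value(self):
        # strongest re-associated locus: b=-0.01042, SE=0.00212, expected '-'
        p = assoc.one_sided_p(-0.01042, 0.00212, "-")
        assert p == pytest.approx(4.51e-7, rel=0.05)

    def test_wrong_direction_exceeds_half(self):
        assert assoc.one_sided_p(1.0, 1.0, "-") == pytest.approx(
            1 - stats.norm.cdf(-1.0)
        )

    @pytest.mark.parametrize("p_one,expected", [
        (2.85e-4, 5.70e-4),   # printed one-sided -> printed two-sided
        (3.00e-5, 5.99e-5),
        (0.5, 1.0),
    ])
    def test_two_sided_doubling(self, p_one, expected):
        assert assoc.two_sided_from_one(p_one) == pytest.approx(expected, rel=0.01)

    def test_two_sided_flags_wrong_direction(self):
        with pytest.warns(UserWarning, match="unexpected direction"):
            assert assoc.two_sided_from_one(0.9) == pytest.approx(0.2)

    def test_composition_gives_standard_two_sided(self):
        b, se = -0.008, 0.002
        p2 = assoc.two_sided_from_one(assoc.one_sided_p(b, se, "-"))
        assert p2 == pytest.approx(2 * stats.norm.sf(abs(b / se)), rel=1e-9)


class TestLdR2:
    def test_identical_and_flipped_columns(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.3, 1000).astype(float)
        assert assoc.ld_r2(d, d) == pytest.approx(1.0)
        assert assoc.ld_r2(d, 2.0 - d) == pytest.approx(1.0)  # allele flip, r = -1

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.3, 10_000).astype(float)
        assert assoc.ld_r2(a, b) < 0.01

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="constant"):
            assoc.ld_r2(np.ones(10), np.arange(10.0))


def _locus_matrix(n=4_000, seed=0):
    return sd.simulate_genotypes(maf=0.3, n_proxies=4, target_r2=0.9, n=n,
                                 seed=seed, prefix="L")


class TestSelectProxies:
    def _lead(self, **kw):
        defaults = dict(rsid="L_lead", chrom="1", pos=1_000_000,
                        effect_allele="A", other_allele="G", eaf=0.3,
                        b=-0.005, se=0.001, p_two=1e-6)
        defaults.update(kw)
        return VariantRecord(**defaults)

    def test_generated_locus_fully_retained(self):
        g = _locus_matrix()
        res = assoc.select_proxies(self._lead(), g.variants, g)
        assert len(res.proxies) == 5  # lead + 4 proxies at target r2 = 0.9
        assert all(r2 > 0.8 for r2 in res.proxy_r2)

    def test_boundary_r2_excluded(self):
        # r2_min equal to the realized r2 must exclude (strict >)
        g = _locus_matrix()
        r2 = assoc.ld_r2(g.values[:, 0], g.values[:, 1])
        res = assoc.select_proxies(self._lead(), g.variants, g, r2_min=r2)
        assert "L_p1" not in [v.rsid for v in res.proxies]

    def test_swapped_alleles_flip_dosage(self):
        g = _locus_matrix(n=500)
        swapped = [
            VariantRecord(rsid=v.rsid, chrom=v.chrom, pos=v.pos,
                          effect_allele="G", other_allele="A", eaf=0.7)
            for v in g.variants
        ]
        flipped = DosageMatrix(values=2.0 - g.values, variants=swapped,
                               sample_ids=list(g.sample_ids))
        res_orig = assoc.select_proxies(self._lead(), g.variants, g)
        res_flip = assoc.select_proxies(self._lead(), swapped, flipped)
        # harmonization undoes the relabeling completely
        np.testing.assert_allclose(res_flip.dosages.values, res_orig.dosages.values)
        assert [v.effect_allele for v in res_flip.proxies] == ["A"] * 5

    def test_rare_variants_removed(self):
        g = _locus_matrix(n=3_000)
        rare = np.zeros((3_000, 1))
        rare[:5, 0] = 1.0  # MAF < 0.005
        withrare = g.hstack(DosageMatrix(
            values=rare,
            variants=[VariantRecord(rsid="L_rare", chrom="1", pos=1_004_000,
                                    effect_allele="A", other_allele="G", eaf=0.001)],
            sample_ids=list(g.sample_ids),
        ))
        res = assoc.select_proxies(self._lead(), withrare.variants, withrare)
        assert "L_rare" not in [v.rsid for v in res.proxies]

    def test_ambiguous_high_maf_dropped(self):
        g = _locus_matrix(n=500)
        amb = [VariantRecord(rsid=v.rsid, chrom=v.chrom, pos=v.pos,
                             effect_allele="A", other_allele="T", eaf=0.45)
               for v in g.variants]
        lead = self._lead(effect_allele="A", other_allele="T", eaf=0.45)
        with pytest.raises(ValueError, match="harmonized"):
            assoc.select_proxies(
                lead, amb,
                DosageMatrix(values=g.values, variants=amb,
                             sample_ids=list(g.sample_ids)),
            )

    def test_missing_lead_raises(self):
        g = _locus_matrix(n=200)
        with pytest.raises(KeyError):
            assoc.select_proxies(self._lead(rsid="absent"), g.variants, g)


class TestLocusSignificance:
    def _locus_with_p(self, p_one):
        lead = VariantRecord(rsid="x", effect_allele="A", other_allele="G",
                             b=-0.01, se=0.002, p_one=p_one, p_two=min(1.0, 2 * p_one))
        return assoc.LocusResult(locus_name="x", lead=lead, proxies=[lead])

    def test_boundary_cases(self):
        assert assoc.locus_significant(self._locus_with_p(3.34e-4))
        assert not assoc.locus_significant(self._locus_with_p(3.5e-4))

    def test_family_wise_error_under_null(self):
        """147 independent null loci: expected false positives ~ 0.05 per family."""
        rng = np.random.default_rng(8)
        families, n_loci = 150, 147
        hits = 0
        for _ in range(families):
            p_one = rng.uniform(size=n_loci)  # null one-sided p-values
            hits += (p_one < 0.05 / n_loci).any()
        rate = hits / families
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / families)


class TestEffectiveTestCoverage:
    def test_identity_matrix(self):
        assert assoc.effective_test_coverage(np.eye(100), 98) == pytest.approx(0.98)

    def test_rank_one_matrix(self):
        assert assoc.effective_test_coverage(np.ones((10, 10)), 1) == pytest.approx(1.0)

    def test_block_diagonal_perfect_blocks(self):
        blocks = [np.ones((5, 5))] * 10
        corr = np.zeros((50, 50))
        for i, b in enumerate(blocks):
            corr[5 * i:5 * (i + 1), 5 * i:5 * (i + 1)] = b
        assert assoc.effective_test_coverage(corr, 10) == pytest.approx(1.0)

    def test_asymmetric_raises(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            assoc.effective_test_coverage(m, 2)


class TestGenomicLambda:
    def test_all_half_is_one(self):
        assert assoc.genomic_lambda([0.5] * 11) == pytest.approx(1.0)

    def test_uniform_p_values(self):
        rng = np.random.default_rng(9)
        lam = assoc.genomic_lambda(rng.uniform(size=1_000_000))
        assert lam == pytest.approx(1.0, abs=0.005)

    def test_inflated_z_scores(self):
        rng = np.random.default_rng(10)
        z = rng.normal(0, np.sqrt(1.1), 500_000)
        p = 2 * stats.norm.sf(np.abs(z))
        assert assoc.genomic_lambda(p) == pytest.approx(1.1, abs=0.02)
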