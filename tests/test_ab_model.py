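"""Genotype AB distributions: density, fitting, p-values, devAB."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from abbscore.ab_model import (
    GENOTYPES,
    BeinfModel,
    GenotypeABModel,
    HetModel,
    ModelError,
    assign_genotype,
    beinf_density,
    beinf_lower_tail,
    beinf_upper_tail,
    binom_two_sided_pvalues,
    default_model,
    dev_ab,
    fit_beinf,
    fit_het_binomial,
    genotype_pvalues,
)


class TestBeinfDensity:
    def test_point_masses(self):
        m = BeinfModel(alpha=0.8, gamma=0.1, mu=0.3, phi=10)
        assert beinf_density(0.0, m) == pytest.approx(0.72)
        assert beinf_density(1.0, m) == pytest.approx(0.08)

    def test_degenerate_mixture_is_plain_beta(self):
        m = BeinfModel(alpha=0.0, gamma=0.0, mu=0.3, phi=10)
        y = np.linspace(0.01, 0.99, 7)
        np.testing.assert_allclose(
            beinf_density(y, m), stats.beta.pdf(y, 3.0, 7.0), rtol=1e-12
        )
        total, _ = integrate.quad(lambda t: beinf_density(t, m), 0, 1)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_total_probability_random_parameters(self, rng):
        for _ in range(25):
            m = BeinfModel(
                alpha=rng.uniform(0, 0.99),
                gamma=rng.uniform(0, 1),
                mu=rng.uniform(0.05, 0.95),
                phi=rng.uniform(0.5, 200),
            )
            cont, _ = integrate.quad(lambda t: beinf_density(t, m), 0, 1)
            total = beinf_density(0.0, m) + beinf_density(1.0, m) + cont
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_domain_error(self):
        m = BeinfModel(0.5, 0.5, 0.5, 10)
        with pytest.raises(ValueError):
            beinf_density(1.5, m)

    def test_tails_are_complementary_in_the_interior(self):
        m = BeinfModel(alpha=0.3, gamma=0.4, mu=0.2, phi=25)
        for y in (0.05, 0.3, 0.9):
            # P(Y >= y) + P(Y <= y) = 1 for continuous y (no atom at y)
            assert beinf_upper_tail(y, m) + beinf_lower_tail(y, m) == pytest.approx(1.0)
        assert beinf_upper_tail(0.0, m) == 1.0
        assert beinf_lower_tail(1.0, m) == 1.0


class TestFitBeinf:
    def test_simulate_then_refit_recovery(self, rng):
        true = BeinfModel(alpha=0.9, gamma=0.0, mu=0.02, phi=30)
        y = true.rvs(10_000, rng)
        fit = fit_beinf(y, "zero_inflated")
        assert fit.alpha == pytest.approx(true.alpha, abs=0.01)
        assert fit.mu == pytest.approx(true.mu, abs=0.005)
        assert fit.phi == pytest.approx(true.phi, rel=0.20)

    def test_boundary_only_sample(self):
        with pytest.warns(RuntimeWarning):
            fit = fit_beinf(np.zeros(100), "zero_inflated")
        assert fit.alpha == 1.0
        assert fit.gamma == 0.0
        assert fit.degenerate

    def test_interior_only_matches_shape_parameterization(self, rng):
        y = rng.beta(2.0, 18.0, size=4000)
        fit = fit_beinf(y, "zero_inflated")
        assert fit.alpha == 0.0
        # independent generic fit of the two-shape beta
        a, b, _, _ = stats.beta.fit(y, floc=0, fscale=1)
        assert fit.mu == pytest.approx(a / (a + b), rel=0.02)
        assert fit.phi == pytest.approx(a + b, rel=0.05)

    def test_empty_input_errors(self):
        with pytest.raises(ModelError):
            fit_beinf([], "zero_inflated")


class TestFitHetBinomial:
    @pytest.mark.parametrize(
        "alt, depth, expected",
        [([5] * 60, [10] * 60, 0.5), ([3, 7] * 30, [10, 10] * 30, 0.5)],
    )
    def test_pooled_mle(self, alt, depth, expected):
        assert fit_het_binomial(alt, depth).p_het == pytest.approx(expected)

    def test_recovery(self, rng):
        alt = rng.binomial(30, 0.48, size=10_000)
        fit = fit_het_binomial(alt, np.full(10_000, 30))
        assert fit.p_het == pytest.approx(0.48, abs=0.005)

    def test_empty_errors(self):
        with pytest.raises(ModelError):
            fit_het_binomial([], [])


def _enumerate_two_sided(k, n, p):
    pmf = stats.binom.pmf(np.arange(n + 1), n, p)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum())


class TestBinomialPvalues:
    def test_matches_enumeration_oracle(self):
        for n in (5, 17, 30, 55):
            ks = np.arange(n + 1)
            ours = binom_two_sided_pvalues(ks, np.full(n + 1, n), 0.5)
            oracle = [_enumerate_two_sided(k, n, 0.5) for k in ks]
            np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_matches_scipy_binomtest(self):
        for k, n, p in [(7, 30, 0.5), (3, 40, 0.3), (0, 12, 0.5), (25, 50, 0.48)]:
            ours = binom_two_sided_pvalues([k], [n], p)[0]
            ref = stats.binomtest(k, n, p, alternative="two-sided").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_mode_has_pvalue_one(self):
        assert binom_two_sided_pvalues([15], [30], 0.5)[0] == pytest.approx(1.0)


class TestGenotypePvalues:
    def test_symmetric_mode(self, clean_model):
        _, p_het, _ = genotype_pvalues(15, 30, clean_model)
        assert p_het == pytest.approx(1.0)

    def test_hom_ref_point_mass(self, clean_model):
        p_hr, _, _ = genotype_pvalues(0, 30, clean_model)
        assert p_hr == 1.0

    def test_het_two_sided_enumeration(self, clean_model):
        _, p_het, _ = genotype_pvalues(7, 30, clean_model)
        assert p_het == pytest.approx(_enumerate_two_sided(7, 30, 0.5), abs=1e-12)

    def test_superuniform_under_own_genotype(self, rng):
        """P-values of data drawn from the matching genotype model are
        uniform or super-uniform (one-sided KS does not reject)."""
        model = default_model()
        depth = np.maximum(rng.negative_binomial(5, 5 / 65, size=5000), 1)
        alt = rng.binomial(depth, 0.5)
        p_het = binom_two_sided_pvalues(alt, depth, 0.5)
        # alternative='greater': empirical CDF above the uniform CDF,
        # i.e. sub-uniform p-values; must not be detected
        ks = stats.ks_1samp(p_het, stats.uniform.cdf, alternative="greater")
        assert ks.pvalue > 0.01

        ab = model.hom_ref_.rvs(5000, rng)
        p_hr = beinf_upper_tail(ab, model.hom_ref_)
        ks = stats.ks_1samp(p_hr, stats.uniform.cdf, alternative="greater")
        assert ks.pvalue > 0.01


class TestAssignGenotype:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ((1.0, 0.001, 1e-9), "hom_ref"),
            ((1e-6, 0.9, 1e-6), "het"),
            ((0.5, 0.5, 0.1), "hom_ref"),  # documented tie-break
            ((0.1, 0.5, 0.5), "het"),
        ],
    )
    def test_argmax_with_tie_break(self, pvals, expected):
        assert assign_genotype(pvals) == expected

    def test_recovery_on_clean_depth_30_data(self, rng):
        model = default_model()
        n = 3000
        truth = rng.integers(0, 3, size=n)
        depth = np.full(n, 30)
        p = np.empty(n)
        p[truth == 1] = 0.5
        p[truth == 0] = model.hom_ref_.rvs(int((truth == 0).sum()), rng)
        p[truth == 2] = model.hom_alt_.rvs(int((truth == 2).sum()), rng)
        alt = rng.binomial(depth, p)
        pred = model.predict(np.column_stack([alt, depth]))
        assert (pred == truth).mean() >= 0.99


class TestDevAB:
    @pytest.mark.parametrize(
        "ab, genotype, expected",
        [
            (0.5, "het", 0.0),
            (0.0, "hom_ref", 0.0),
            (0.25, "het", 0.25),
            (0.25, "hom_ref", 0.25),
            (0.25, "hom_alt", 0.75),
            (1.0, "hom_alt", 0.0),
        ],
    )
    def test_formula(self, ab, genotype, expected):
        assert dev_ab(ab, genotype) == pytest.approx(expected)

    @settings(deadline=None, max_examples=200)
    @given(
        ab1=st.floats(0, 1),
        ab2=st.floats(0, 1),
        genotype=st.sampled_from(GENOTYPES),
    )
    def test_lipschitz(self, ab1, ab2, genotype):
        assert abs(dev_ab(ab1, genotype) - dev_ab(ab2, genotype)) <= abs(ab1 - ab2) + 1e-12


class TestGenotypeABModelEstimator:
    def test_fit_from_labeled_pairs(self, rng):
        true = default_model()
        n = 6000
        truth = rng.integers(0, 3, size=n)
        depth = np.maximum(rng.negative_binomial(5, 5 / 65, size=n), 20)
        p = np.empty(n)
        p[truth == 1] = 0.5
        p[truth == 0] = true.hom_ref_.rvs(int((truth == 0).sum()), rng)
        p[truth == 2] = true.hom_alt_.rvs(int((truth == 2).sum()), rng)
        alt = rng.binomial(depth, p)
        fitted = GenotypeABModel().fit(
            np.column_stack([alt, depth]), np.array(GENOTYPES)[truth]
        )
        assert fitted.het_.p_het == pytest.approx(0.5, abs=0.01)
        # binomial thinning moves interior mass onto the boundary, so the
        # fitted alpha exceeds the generator's; it must stay a probability
        assert true.hom_ref_.alpha <= fitted.hom_ref_.alpha <= 1.0

    def test_json_roundtrip(self, tmp_path, clean_model):
        path = tmp_path / "model.json"
        clean_model.to_json(path)
        loaded = GenotypeABModel.from_json(path)
        assert loaded.het_.p_het == clean_model.het_.p_het
        assert loaded.hom_ref_ == clean_model.hom_ref_
        assert loaded.hom_alt_ == clean_model.hom_alt_

    def test_rejects_unknown_labels(self):
        with pytest.raises(ModelError):
            GenotypeABModel().fit(np.array([[1, 10]]), np.array(["diploid"]))
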