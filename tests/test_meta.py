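"""Dependent-effects meta-analysis: conversion, covariance, decoupling, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from ppe import meta, synthetic, trial_model

# the seven published adjusted OR rows (nonmatched vs matched)
PUBLISHED_AOR = [
    ("metformin", 0.67, 0.29, 1.52),
    ("ivermectin", 1.08, 0.70, 1.65),
    ("pegylated interferon lambda", 1.15, 0.60, 2.10),
    ("fluvoxamine+budesonide", 0.97, 0.34, 2.37),
    ("fluvoxamine", 0.92, 0.61, 1.39),
    ("famotidine", 0.96, 0.17, 5.30),
    ("spirulina", 0.81, 0.16, 3.79),
]


def published_estimates():
    return [meta.logor_from_ci(o, l, h, label=n) for n, o, l, h in PUBLISHED_AOR]


def _random_psd(rng, k, positive_weights=True):
    """Random PSD covariance; optionally conditioned on nonnegative GLS weights.

    The decoupled representation carries only positive SEs, so the exact GLS
    identity is defined for covariance structures whose inverse has
    nonnegative row sums (a redundant study under strong positive correlation
    would need a negative pooling weight, which no SE can encode; the
    realization then floors that weight).
    """
    while True:
        a = rng.standard_normal((k, k + 2))
        S = a @ a.T / (k + 2)
        S += 0.05 * np.eye(k)
        if not positive_weights or (np.linalg.inv(S).sum(axis=1) > 0).all():
            return S


class TestLogorFromCi:
    def test_ivermectin_row_conversion(self):
        e = meta.logor_from_ci(1.08, 0.70, 1.65)
        assert e.log_or == pytest.approx(0.07696, abs=1e-4)
        assert e.se == pytest.approx(0.21874, abs=1e-4)

    def test_metformin_row_conversion(self):
        e = meta.logor_from_ci(0.67, 0.29, 1.52)
        assert e.se == pytest.approx(0.42261, abs=1e-4)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            meta.logor_from_ci(1.0, 1.0, 1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            meta.logor_from_ci(-1.0, 0.5, 2.0)


class TestFixedEffect:
    def test_duplicated_estimate(self):
        e = meta.EffectEstimate("a", 0.3, 0.2)
        res = meta.fixed_effect_meta([e, e])
        assert res.pooled_log_or == pytest.approx(0.3)
        assert res.pooled_se == pytest.approx(0.2 / np.sqrt(2))
        assert res.Q == pytest.approx(0.0) and res.I2 == 0.0

    def test_published_rows_show_no_heterogeneity(self):
        res = meta.fixed_effect_meta(published_estimates())
        assert res.Q < res.df
        assert res.I2 == 0.0

    def test_published_rows_match_independent_meta_software(self):
        # frozen oracle from R metafor (rma, method="FE") on the same rows
        res = meta.fixed_effect_meta(published_estimates())
        assert res.pooled_log_or == pytest.approx(-0.025129, abs=1e-5)
        assert res.pooled_se == pytest.approx(0.123231, abs=1e-5)
        assert res.Q == pytest.approx(1.403026, abs=1e-5)

    def test_constructed_heterogeneity_hand_computation(self):
        ests = [
            meta.EffectEstimate("p", 1.0, 0.1),
            meta.EffectEstimate("m", -1.0, 0.1),
        ]
        res = meta.fixed_effect_meta(ests)
        assert res.Q == pytest.approx(200.0)
        assert res.I2 == pytest.approx(99.5)

    @given(shift=st.floats(-2, 2))
    @settings(max_examples=25, deadline=None)
    def test_i2_invariant_under_common_shift(self, shift):
        base = published_estimates()
        shifted = [
            meta.EffectEstimate(e.label, e.log_or + shift, e.se) for e in base
        ]
        assert meta.fixed_effect_meta(shifted).I2 == pytest.approx(
            meta.fixed_effect_meta(base).I2
        )
        assert meta.fixed_effect_meta(shifted).Q == pytest.approx(
            meta.fixed_effect_meta(base).Q, abs=1e-8
        )


class TestRandomEffect:
    def test_published_rows_identical_to_fixed_effect(self):
        fe = meta.fixed_effect_meta(published_estimates())
        re = meta.random_effect_meta(published_estimates())
        assert re.tau2 == 0.0
        assert re.pooled_log_or == pytest.approx(fe.pooled_log_or)
        assert re.pooled_se == pytest.approx(fe.pooled_se)

    def test_heterogeneous_estimates_inflate_pooled_se(self):
        ests = [
            meta.EffectEstimate("p", 1.0, 0.1),
            meta.EffectEstimate("m", -1.0, 0.1),
        ]
        fe, re = meta.fixed_effect_meta(ests), meta.random_effect_meta(ests)
        assert re.tau2 > 0.0
        assert re.pooled_se > fe.pooled_se

    def test_identical_pair_has_zero_tau2(self):
        e = meta.EffectEstimate("a", 0.2, 0.3)
        assert meta.random_effect_meta([e, e]).tau2 == 0.0


class TestDecouple:
    def test_diagonal_sigma_is_identity(self):
        ests = published_estimates()
        sigma = meta.CovMatrix(
            [e.label for e in ests], np.diag([e.se**2 for e in ests])
        )
        out = meta.decouple(ests, sigma)
        for a, b in zip(ests, out):
            assert b.se == pytest.approx(a.se)
            assert b.log_or == a.log_or and b.label == a.label

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    def test_exchangeable_correlation_closed_form(self, rho):
        k, v = 5, 0.04
        S = v * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))
        ests = [meta.EffectEstimate(f"s{i}", 0.1 * i, np.sqrt(v)) for i in range(k)]
        out = meta.decouple(ests, meta.CovMatrix([e.label for e in ests], S))
        pooled_var = meta.fixed_effect_meta(out).pooled_se ** 2
        assert pooled_var == pytest.approx(v * (1 + (k - 1) * rho) / k, rel=1e-8)

    def test_perfectly_correlated_limit_adds_nothing(self):
        k, v, rho = 4, 0.09, 0.9999
        S = v * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))
        ests = [meta.EffectEstimate(f"s{i}", 0.0, np.sqrt(v)) for i in range(k)]
        out = meta.decouple(ests, meta.CovMatrix([e.label for e in ests], S))
        assert meta.fixed_effect_meta(out).pooled_se ** 2 == pytest.approx(
            v, rel=1e-3
        )

    def test_gls_contract_on_random_psd_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            k = int(rng.integers(2, 8))
            S = _random_psd(rng, k)
            theta = rng.standard_normal(k)
            ests = [
                meta.EffectEstimate(f"s{i}", theta[i], np.sqrt(S[i, i]))
                for i in range(k)
            ]
            out = meta.decouple(ests, meta.CovMatrix([e.label for e in ests], S))
            fe = meta.fixed_effect_meta(out) if k > 1 else None
            point, var = meta.gls_pool(theta, S)
            assert fe.pooled_log_or == pytest.approx(point, abs=1e-8)
            assert fe.pooled_se**2 == pytest.approx(var, rel=1e-8)

    def test_variance_identity_holds_even_with_floored_weights(self):
        # when a redundant study's GLS weight is negative the pooled *point*
        # is approximated, but the pooled *variance* identity is exact
        rng = np.random.default_rng(7)
        found = 0
        while found < 5:
            S = _random_psd(rng, 4, positive_weights=False)
            if (np.linalg.inv(S).sum(axis=1) > 0).all():
                continue
            found += 1
            theta = rng.standard_normal(4)
            ests = [
                meta.EffectEstimate(f"s{i}", theta[i], np.sqrt(S[i, i]))
                for i in range(4)
            ]
            out = meta.decouple(ests, meta.CovMatrix([e.label for e in ests], S))
            _, var = meta.gls_pool(theta, S)
            assert meta.fixed_effect_meta(out).pooled_se ** 2 == pytest.approx(
                var, rel=1e-8
            )

    def test_singular_sigma_raises_with_ridge_hint(self):
        ests = [meta.EffectEstimate("a", 0.0, 1.0), meta.EffectEstimate("b", 0.0, 1.0)]
        S = np.ones((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            meta.decouple(ests, meta.CovMatrix(["a", "b"], S + 1e-18))


class TestBootstrapCovariance:
    def _two_block_trial(self, shared: bool):
        cfg = synthetic.default_config()
        cfg.generate_pro = False
        records = synthetic.generate_trial(cfg, seed=6)
        comps = [
            trial_model.build_comparison(spec, records) for spec in cfg.treatments
        ]
        return comps, records

    def test_disjoint_comparisons_near_zero_correlation(self, comparisons,
                                                        default_records):
        names = [c.treatment.name for c in comparisons]
        # metformin (early 2021) and spirulina (2022) share no patients
        pair = [comparisons[names.index("metformin")],
                comparisons[names.index("spirulina")]]
        assert not (pair[0].all_ids & pair[1].all_ids)
        sig = meta.bootstrap_covariance(pair, default_records, B=1000, seed=0)
        assert abs(sig.correlation[0, 1]) < 0.1

    def test_identical_comparisons_near_unit_correlation(self, comparisons,
                                                         default_records):
        pair = [comparisons[1], comparisons[1]]
        sig = meta.bootstrap_covariance(pair, default_records, B=1000, seed=0)
        assert sig.correlation[0, 1] > 0.9

    def test_diagonal_matches_woolf_variance(self, comparisons, default_records,
                                             record_index):
        sig = meta.bootstrap_covariance(
            comparisons, default_records, B=1000, seed=3
        )
        for i, cs in enumerate(comparisons):
            t = trial_model.extract_two_by_two(cs, record_index)
            woolf = (
                1 / (t.events_a + 0.5) + 1 / (t.n_a - t.events_a + 0.5)
                + 1 / (t.events_b + 0.5) + 1 / (t.n_b - t.events_b + 0.5)
            )
            assert sig.matrix[i, i] == pytest.approx(woolf, rel=0.25)

    def test_reproducible_given_seed(self, comparisons, default_records):
        a = meta.bootstrap_covariance(comparisons[:3], default_records, B=50, seed=9)
        b = meta.bootstrap_covariance(comparisons[:3], default_records, B=50, seed=9)
        assert np.array_equal(a.matrix, b.matrix)


class TestBayesMeta:
    def test_flat_prior_matches_frequentist_fixed_effect(self):
        ests = published_estimates()
        fe = meta.fixed_effect_meta(ests)
        pooled = meta.bayes_meta(ests, prior_sd=100.0, seed=0)
        mcse = fe.pooled_se / np.sqrt(pooled.mu_draws.size)
        assert np.log(pooled.or_point) == pytest.approx(
            fe.pooled_log_or, abs=4 * mcse
        )
        assert np.log(pooled.cri_95[0]) == pytest.approx(fe.ci_95[0], abs=0.01)
        assert np.log(pooled.cri_95[1]) == pytest.approx(fe.ci_95[1], abs=0.01)

    def test_precise_null_estimates_give_equivalence_probability_one(self):
        ests = [meta.EffectEstimate(f"s{i}", 0.0, 0.01) for i in range(4)]
        pooled = meta.bayes_meta(ests, seed=1)
        assert pooled.prob_equiv > 0.999

    def test_pooled_posterior_scale_closed_form(self):
        # a pooled posterior of Normal(0.01, 0.14^2) implies equivalence
        # probability ~0.84 (the published pooled analysis reports 85.4%)
        expected = norm.cdf((np.log(1.2) - 0.01) / 0.14) - norm.cdf(
            (np.log(0.8) - 0.01) / 0.14
        )
        assert expected == pytest.approx(0.8429, abs=0.001)
        e = meta.EffectEstimate("pooled", 0.01, 0.14)
        pooled = meta.bayes_meta([e], prior_sd=1000.0, seed=2)
        assert pooled.prob_equiv == pytest.approx(expected, abs=0.01)

    def test_seed_reproducibility(self):
        ests = published_estimates()
        a = meta.bayes_meta(ests, seed=5)
        b = meta.bayes_meta(ests, seed=5)
        assert np.array_equal(a.mu_draws, b.mu_draws)


def test_cov_matrix_validates_shape_and_symmetry():
    with pytest.raises(ValueError, match="symmetric"):
        meta.CovMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        meta.CovMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, -1.0]]))
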