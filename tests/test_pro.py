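"""PROMIS/EQ-5D scoring, imputation, Tobit regression and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest

from ppe import pro


@pytest.fixture(scope="module")
def value_set():
    return pro.synthetic_value_set()


def _pro_frame(n=600, group_effect=0.0, miss=0.15, seed=0, eq5d=False,
               eq5d_intercept=0.6):
    """Synthetic analysis frame with a known group effect on the day-28 score."""
    rng = np.random.default_rng(seed)
    group = np.repeat([0.0, 1.0], n // 2)
    age50 = (rng.random(n) < 0.48).astype(float)
    male = (rng.random(n) < 0.4).astype(float)
    bmi30 = (rng.random(n) < 0.35).astype(float)
    if eq5d:
        base = np.clip(rng.normal(0.85, 0.12, n), 0, 1.0)
        latent = (eq5d_intercept + 0.35 * base + group_effect * group
                  + rng.normal(0, 0.1, n))
        d28 = np.minimum(latent, 1.0)
        out_col = "eq5d_d28"
    else:
        base = np.clip(rng.normal(30, 6, n).round(), 10, 50)
        d28 = (5 + 0.8 * base + group_effect * group - 1.0 * age50
               + rng.normal(0, 4, n)).round()
        out_col = "promis_d28"
    frame = pd.DataFrame({
        "group": group, "age50": age50, "male": male, "bmi30": bmi30,
        "baseline": base, out_col: d28,
    })
    mask = rng.random(n) < miss
    frame.loc[mask, out_col] = np.nan
    return frame


class TestScores:
    @pytest.mark.parametrize(
        "items,total",
        [([5] * 10, 50), ([1] * 10, 10), ([3] * 10, 30)],
    )
    def test_promis_total(self, items, total):
        assert pro.promis_total(items) == total

    def test_promis_missing_or_invalid_rejected(self):
        with pytest.raises(ValueError):
            pro.promis_total(None)
        with pytest.raises(ValueError):
            pro.promis_total([3] * 9)
        with pytest.raises(ValueError):
            pro.promis_total([3] * 9 + [6])

    def test_full_health_anchor(self, value_set):
        assert pro.eq5d_index((1, 1, 1, 1, 1), value_set) == 1.0

    def test_worst_state_is_floor(self, value_set):
        worst = pro.eq5d_index((5, 5, 5, 5, 5), value_set)
        assert worst == value_set.floor
        assert worst == pytest.approx(1.0 - 4 * sum(pro.DEFAULT_DECREMENTS))

    def test_additive_single_step_decrement(self, value_set):
        assert pro.eq5d_index((2, 1, 1, 1, 1), value_set) == pytest.approx(0.95)

    def test_out_of_range_state_rejected(self, value_set):
        with pytest.raises(ValueError):
            pro.eq5d_index((0, 1, 1, 1, 1), value_set)

    def test_value_set_total_on_domain_and_round_trip(self, value_set, tmp_path):
        assert len(value_set.utilities) == 3125
        path = tmp_path / "vs.csv"
        value_set.save(path)
        back = pro.ValueSet.load(path)
        assert back.utilities == value_set.utilities

    def test_incomplete_value_set_rejected(self, value_set):
        broken = dict(value_set.utilities)
        broken.pop((3, 3, 3, 3, 3))
        with pytest.raises(ValueError, match="incomplete"):
            pro.ValueSet(broken)


class TestMicePmm:
    def test_complete_data_returns_identical_copies(self):
        frame = _pro_frame(miss=0.0)
        imp = pro.mice_pmm(frame, m=3)
        assert imp.m == 3
        for d in imp.datasets:
            pd.testing.assert_frame_equal(d, frame)

    def test_imputed_values_come_from_observed_donors(self):
        frame = _pro_frame(n=400, miss=0.15, seed=1)
        observed = set(frame["promis_d28"].dropna())
        imp = pro.mice_pmm(frame, m=3, cycles=3, seed=2)
        missing_rows = frame.index[frame["promis_d28"].isna()]
        for d in imp.datasets:
            assert not d["promis_d28"].isna().any()
            assert set(d.loc[missing_rows, "promis_d28"]) <= observed

    def test_reproducible_given_seed(self):
        frame = _pro_frame(n=300, seed=3)
        a = pro.mice_pmm(frame, m=2, cycles=2, seed=5)
        b = pro.mice_pmm(frame, m=2, cycles=2, seed=5)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)

    def test_imputed_mean_recovers_truth_under_mcar(self):
        # the average imputed-data mean should track the complete-data mean
        devs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            frame = _pro_frame(n=500, miss=0.15, seed=seed)
            truth = 5 + 0.8 * frame["baseline"].mean()  # expected day-28 mean
            imp = pro.mice_pmm(frame, m=5, cycles=3, seed=seed)
            means = [d["promis_d28"].mean() for d in imp.datasets]
            devs.append(np.mean(means) - truth)
        se = 4 / np.sqrt(500)  # residual scale / sqrt(n)
        assert abs(np.mean(devs)) < 3 * se

    def test_all_missing_variable_rejected(self):
        frame = _pro_frame(n=100)
        frame["promis_d28"] = np.nan
        with pytest.raises(ValueError):
            pro.mice_pmm(frame, m=2)


class TestLinearPro:
    def test_outcome_equal_to_baseline_recovered_exactly(self):
        frame = _pro_frame(miss=0.0, seed=4)
        frame["promis_d28"] = frame["baseline"]
        fit = pro.fit_linear_pro(frame)
        assert fit["group"].estimate == pytest.approx(0.0, abs=1e-10)
        assert fit["baseline"].estimate == pytest.approx(1.0, abs=1e-10)

    def test_null_group_effect_coverage(self):
        covered = 0
        for seed in range(20):
            frame = _pro_frame(n=750, group_effect=0.0, miss=0.0, seed=seed)
            fit = pro.fit_linear_pro(frame)["group"]
            covered += abs(fit.estimate) <= 1.96 * fit.se
        assert covered >= 18

    def test_interval_width_comparable_to_published_scale(self):
        # published PROMIS contrasts at n~750 have half-widths around +-1 point
        frame = _pro_frame(n=750, miss=0.0, seed=9)
        fit = pro.fit_linear_pro(frame)["group"]
        assert 0.1 < 1.96 * fit.se < 2.5

    def test_collinear_design_rejected(self):
        frame = _pro_frame(n=100, miss=0.0)
        frame["bmi30"] = frame["male"]
        with pytest.raises(ValueError, match="collinear"):
            pro.fit_linear_pro(frame)


class TestTobit:
    def test_reduces_to_linear_when_nothing_censored(self):
        frame = _pro_frame(n=500, miss=0.0, seed=10, eq5d=True)
        frame["eq5d_d28"] = np.clip(frame["eq5d_d28"], None, 0.98)  # off the bound
        ols = pro.fit_linear_pro(frame, outcome="eq5d_d28")["group"]
        post = pro.fit_tobit(frame, total_iters=8000, seed=1, warn=False)
        est = pro.tobit_group_estimate(post)
        assert est.estimate == pytest.approx(ols.estimate, abs=3 * ols.se / 5)

    def test_intercept_recovery_under_heavy_censoring(self):
        # latent Normal(0.9, 0.1^2) censored at 1 (~16% at the bound)
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            latent = rng.normal(0.9, 0.1, 2000)
            frame = pd.DataFrame({"y": np.minimum(latent, 1.0)})
            post = pro.fit_tobit(
                frame, outcome="y", covariates=[], total_iters=8000,
                seed=seed, warn=False,
            )
            errs.append(float(post.coef("intercept").mean()) - 0.9)
        assert abs(np.mean(errs)) < 0.02

    def test_null_group_coverage_at_majority_censoring(self):
        covered = 0
        for seed in range(10):
            frame = _pro_frame(n=700, group_effect=0.0, miss=0.0,
                               seed=seed + 50, eq5d=True, eq5d_intercept=0.72)
            assert (frame["eq5d_d28"] >= 1.0).mean() > 0.45
            post = pro.fit_tobit(frame, total_iters=8000, seed=seed, warn=False)
            g = post.coef("group")
            lo, hi = np.percentile(g, [2.5, 97.5])
            covered += lo <= 0.0 <= hi
        assert covered >= 9

    def test_data_above_declared_bound_rejected(self):
        frame = _pro_frame(n=200, miss=0.0, eq5d=True)
        with pytest.raises(ValueError, match="bound"):
            pro.fit_tobit(frame, upper=0.9)

    def test_fully_censored_outcome_rejected(self):
        frame = _pro_frame(n=100, miss=0.0, eq5d=True)
        frame["eq5d_d28"] = 1.0
        with pytest.raises(ValueError, match="censored"):
            pro.fit_tobit(frame)


class TestRubinPool:
    def test_identical_fits_reduce_to_single_fit(self):
        fits = [pro.CoefEstimate(0.4, 0.1)] * 5
        pooled = pro.rubin_pool(fits)
        assert pooled.estimate == pytest.approx(0.4)
        assert pooled.se == pytest.approx(0.1)
        assert pooled.between_var == 0.0

    def test_spread_estimates_direct_formula(self):
        fits = [pro.CoefEstimate(j / 15, 0.0) for j in range(1, 16)]
        pooled = pro.rubin_pool(fits)
        q = np.array([j / 15 for j in range(1, 16)])
        assert pooled.estimate == pytest.approx(q.mean())
        assert pooled.se**2 == pytest.approx((1 + 1 / 15) * q.var(ddof=1))

    def test_between_variance_widens_interval(self):
        tight = pro.rubin_pool([pro.CoefEstimate(0.0, 0.1)] * 10)
        spread = pro.rubin_pool(
            [pro.CoefEstimate(x, 0.1) for x in np.linspace(-0.3, 0.3, 10)]
        )
        assert (spread.ci_95[1] - spread.ci_95[0]) > (
            tight.ci_95[1] - tight.ci_95[0]
        )

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError):
            pro.rubin_pool([pro.CoefEstimate(0.0, 1.0)])


class TestFullProPipeline:
    def test_null_pipeline_centers_on_zero(self, comparisons, record_index,
                                           value_set):
        cs = next(c for c in comparisons if c.treatment.name == "spirulina")
        pooled = pro.analyze_pro_comparison(
            cs, record_index, "eq5d", value_set,
            m=5, cycles=3, seed=3, tobit_iters=6000,
        )
        assert pooled.ci_95[0] <= 0.0 <= pooled.ci_95[1]
        # day-28 utilities sit near the ceiling, so the contrast is small
        assert abs(pooled.estimate) < 0.05

    def test_promis_pipeline_runs_and_pools(self, comparisons, record_index):
        cs = next(c for c in comparisons if c.treatment.name == "metformin")
        pooled = pro.analyze_pro_comparison(
            cs, record_index, "promis", m=4, cycles=3, seed=1
        )
        assert np.isfinite(pooled.se) and pooled.se > 0
        assert pooled.ci_95[0] < pooled.estimate < pooled.ci_95[1]
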