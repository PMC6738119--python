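"""Cutpoint optimisation, model-grid ranking and stratified reporting."""

import warnings

import numpy as np
import pytest

from invigor import (
    GeneratorConfig,
    compute_sm_invigor,
    generate_cohort,
    multivariate_adjustment,
    optimise_cutpoint,
    power_law,
    rank_models,
)
from invigor.errors import DataError
from invigor.sm_invigor import candidate_thresholds
from invigor.survival import administrative_censor


class TestOptimiseCutpoint:
    def test_hand_verified_four_patient_example(self):
        # deaths only in the two fastest patients: 2v2 split maximises chi2
        cut = optimise_cutpoint(
            [0.01, 0.02, 0.50, 0.60], [10, 10, 1, 2], [0, 0, 1, 1], min_group_frac=0.25
        )
        assert cut.threshold == pytest.approx(0.26)
        assert cut.chi_square == pytest.approx(2.8824, abs=1e-4)
        assert (cut.n_slow, cut.n_fast) == (2, 2)
        assert list(cut.labels) == ["slow", "slow", "fast", "fast"]

    def test_two_patients_single_candidate_midpoint(self):
        cut = optimise_cutpoint([0.1, 0.3], [5, 1], [0, 1], min_group_frac=0.5)
        assert cut.threshold == pytest.approx(0.2)
        assert cut.n_candidates == 1

    def test_identical_rates_raise(self):
        with pytest.raises(DataError, match="identical"):
            optimise_cutpoint([0.1, 0.1, 0.1], [1, 2, 3], [1, 1, 0])

    def test_equals_exhaustive_oracle_on_random_instances(self):
        from lifelines.statistics import logrank_test as ll

        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(10, 61))
            rates = rng.normal(0.1, 0.05, n)
            t = rng.exponential(50, n)
            e = (rng.random(n) < 0.6).astype(float)
            if e.sum() == 0:
                e[0] = 1.0
            cut = optimise_cutpoint(rates, t, e, 0.1)
            best_thr, best_chi = None, -1.0
            for thr in candidate_thresholds(rates, 0.1):
                g = rates > thr
                chi = ll(t[g], t[~g], e[g], e[~g]).test_statistic
                if chi > best_chi + 1e-12:
                    best_chi, best_thr = chi, thr
            assert cut.threshold == pytest.approx(best_thr, abs=1e-12)
            assert cut.chi_square == pytest.approx(best_chi, rel=1e-8)

    def test_maximised_statistic_inflated_relative_to_fixed_split(self):
        # under the null the selected chi2 stochastically dominates a fixed split
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(30):
            n = 40
            rates = rng.normal(0.1, 0.04, n)
            t = rng.exponential(30, n)
            e = (rng.random(n) < 0.6).astype(float)
            if e.sum() == 0:
                e[0] = 1.0
            maxed = optimise_cutpoint(rates, t, e, 0.1).chi_square
            from invigor.survival import logrank_test

            fixed = logrank_test(t, e, rates > np.median(rates)).chi_square
            diffs.append(maxed - fixed)
        assert np.median(diffs) >= 0
        assert np.mean(diffs) > 0

    def test_recovered_threshold_converges_to_generative_step(self):
        # median |recovered - 0.045| shrinks as the cohort grows
        med_err = []
        for n in (100, 400, 1600):
            errs = []
            for seed in range(7):
                cohort, _ = generate_cohort(GeneratorConfig(n=n, seed=200 + seed))
                from invigor import cohort_rates

                rates = cohort_rates(cohort, "sphere", power_law(0.5))
                t, e = administrative_censor(
                    cohort.df["bcss_months"], cohort.df["event"], 120.0
                )
                cut = optimise_cutpoint(rates["rate"], t, e, 0.1)
                errs.append(abs(cut.threshold - 0.045))
            med_err.append(np.median(errs))
        assert med_err[2] < med_err[0]
        assert med_err[1] <= med_err[0] * 1.5


@pytest.fixture(scope="module")
def grid():
    cohort, _ = generate_cohort(GeneratorConfig(n=200, seed=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rank_models(cohort)


class TestExtensions:
    def test_permutation_adjusted_p_is_valid_and_seeded(self):
        from invigor import permutation_adjusted_p

        rng = np.random.default_rng(4)
        rates = rng.normal(0.1, 0.05, 30)
        t = rng.exponential(40, 30)
        e = (rng.random(30) < 0.6).astype(float)
        p1 = permutation_adjusted_p(rates, t, e, n_permutations=50, seed=2)
        p2 = permutation_adjusted_p(rates, t, e, n_permutations=50, seed=2)
        assert p1 == p2
        assert 0 < p1 <= 1
        # the raw maximally selected p is anti-conservative relative to it
        raw = optimise_cutpoint(rates, t, e).p_value
        assert p1 >= raw

    def test_cross_validated_criterion_deterministic_and_orders_signal(self):
        from invigor import cross_validated_criterion

        cohort, truth = generate_cohort(GeneratorConfig(n=300, seed=21))
        from invigor import cohort_rates

        rates = cohort_rates(cohort, "sphere", power_law(0.5))["rate"].to_numpy()
        t = cohort.df["bcss_months"].to_numpy()
        e = cohort.df["event"].to_numpy()
        fast = (truth["true_group"] == "fast").to_numpy().astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1 = cross_validated_criterion(fast, t, e, seed=3)
            c2 = cross_validated_criterion(fast, t, e, seed=3)
            null = cross_validated_criterion(
                np.random.default_rng(0).permutation(fast), t, e, seed=3
            )
        assert c1 == c2
        assert np.isfinite(c1)
        assert c1 < null  # the true grouping predicts held-out survival better


class TestRankModels:
    def test_grid_covers_24_combinations(self, grid):
        assert len(grid.table) == 24
        assert set(grid.table["form"]) == {"continuous", "dichotomised"}
        assert grid.table.groupby(["shape", "law"]).size().eq(2).all()

    def test_winner_has_minimum_finite_aic(self, grid):
        usable = grid.table[~grid.table["failed"]]
        assert grid.best["aic"] == usable["aic"].min()

    def test_deterministic_given_cohort(self):
        cohort, _ = generate_cohort(GeneratorConfig(n=150, seed=4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g1 = rank_models(cohort)
            g2 = rank_models(cohort)
        assert g1.table.equals(g2.table)

    def test_no_events_raises(self):
        cohort, _ = generate_cohort(GeneratorConfig(n=60, seed=2))
        cohort.df["event"] = 0.0
        with pytest.raises(DataError, match="events"):
            rank_models(cohort)

    def test_volume_fits_reported_per_shape(self, grid):
        assert grid.volume_fits is not None
        assert set(grid.volume_fits["variable"]) == {"screening_volume", "diagnostic_volume"}
        assert len(grid.volume_fits) == 6


class TestComputeSmInvigor:
    def test_rate_exactly_at_threshold_is_slow(self, synthetic_cohort_small):
        cohort, _ = synthetic_cohort_small
        from invigor import cohort_rates

        rates = cohort_rates(cohort, "sphere", power_law(0.5))
        thr = float(rates["rate"].iloc[0])
        out = compute_sm_invigor(cohort, "sphere", power_law(0.5), thr)
        assert out["rates"]["label"].iloc[0] == "slow"

    def test_single_group_warns_and_skips_tests(self, synthetic_cohort_small):
        cohort, _ = synthetic_cohort_small
        with pytest.warns(UserWarning, match="single"):
            out = compute_sm_invigor(cohort, "sphere", power_law(0.5), -1.0)
        assert out["report"]["n_slow"] == 0
        assert out["report"]["survival"] is None

    def test_fast_group_shows_worse_survival_on_calibrated_cohort(self):
        cohort, _ = generate_cohort(GeneratorConfig(n=400, seed=13))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = compute_sm_invigor(cohort, "sphere", power_law(0.5), 0.045)
        surv = out["report"]["survival"]
        assert surv["km_fast"]["survival_at_120m"] < surv["km_slow"]["survival_at_120m"]
        assert surv["cox_univariate"]["hazard_ratio_fast"] > 1.0


class TestMultivariateAdjustment:
    def test_label_only_hazard_driver_dominates_adjusters(self):
        hits = 0
        for seed in range(5):
            cohort, truth = generate_cohort(GeneratorConfig(n=500, seed=40 + seed))
            labels = truth["true_group"].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = multivariate_adjustment(cohort, labels, ("age_years", "er_status"))
            hits += fit.p_values["fast"] < 0.05
        assert hits >= 4

    def test_no_adjusters_reduces_to_univariate(self, synthetic_cohort_small):
        cohort, truth = synthetic_cohort_small
        labels = truth["true_group"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            multi = multivariate_adjustment(cohort, labels, ())
            from invigor import fit_cox
            import pandas as pd

            uni = fit_cox(
                pd.DataFrame(
                    {
                        "time": cohort.df["bcss_months"],
                        "event": cohort.df["event"],
                        "fast": (labels == "fast").astype(float),
                    }
                ),
                ["fast"],
            )
        assert multi.coefficients["fast"] == pytest.approx(uni.coefficients["fast"])

    def test_constant_label_raises(self, synthetic_cohort_small):
        cohort, _ = synthetic_cohort_small
        with pytest.raises(DataError):
            multivariate_adjustment(cohort, np.array(["slow"] * len(cohort)), ())
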