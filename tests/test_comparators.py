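"""Refit, harmonization and batch-adjusted model comparators."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from reformri import (
    ConfigError,
    FitConfig,
    FitError,
    HarmonizerConfig,
    ReferenceInterval,
    apply_harmonizer,
    evaluate_bounds,
    false_positive_rate,
    fit_batch_adjusted_lss,
    fit_harmonizer,
    fit_location_scale_shape,
    interval_from_model,
    refit_interval,
    reform_calibrate,
    scenario_presets,
    simulate_study,
    trial_rng,
)

from conftest import make_records

BASE, _ = scenario_presets("exp1_large_shift")


def two_batch_data(delta=0.3, gamma=1.0, n=500, seed=7):
    params = dataclasses.replace(
        BASE, batch_effects={"A": (0.0, 1.0), "B": (delta, gamma)}, seed=seed
    )
    return simulate_study(params, {"A": n, "B": n})


class TestRefit:
    def test_delegates_to_naive_fit(self, rng):
        _, test_params = scenario_presets("exp1_large_shift")
        data = simulate_study(test_params, {"TEST": 300}, rng=rng)
        direct = interval_from_model(fit_location_scale_shape(data), 0.05)
        refit = refit_interval(data, 0.05)
        grid = np.linspace(25, 90, 31)
        sexes = np.full(31, "F", dtype=object)
        for a, b in zip(evaluate_bounds(direct, grid, sexes),
                        evaluate_bounds(refit, grid, sexes)):
            assert np.allclose(a, b, atol=1e-9)

    def test_below_minimum_is_structured_error(self):
        with pytest.raises(FitError):
            refit_interval(make_records(np.full(10, 2.5)), 0.05)

    def test_large_exchangeable_refit_controls_fpr(self):
        _, test_params = scenario_presets("exp1_large_shift")
        cal = simulate_study(test_params, {"TEST": 2000}, rng=trial_rng(11, 0))
        fresh = simulate_study(test_params, {"TEST": 3000}, rng=trial_rng(11, 1))
        interval = refit_interval(cal, 0.05)
        fpr, _, _ = false_positive_rate(interval, fresh)
        assert fpr == pytest.approx(0.05, abs=0.02)


class TestHarmonizer:
    def test_single_batch_rejected(self):
        with pytest.raises(ConfigError, match="two batches"):
            fit_harmonizer(make_records(np.full(100, 2.5)), "scalar_scale")

    def test_small_batch_named_in_error(self):
        small = dataclasses.replace(BASE, batch_effects={"A": (0.0, 1.0), "B": (0.0, 1.0)}, seed=3)
        data = simulate_study(small, {"A": 200, "B": 10})
        with pytest.raises(ConfigError, match="'B'"):
            fit_harmonizer(data, "scalar_scale")

    def test_recovers_additive_shift(self):
        h = fit_harmonizer(two_batch_data(delta=0.3), "scalar_scale")
        est = h.batch_shifts["B"] - h.batch_shifts["A"]
        assert est == pytest.approx(0.3, abs=0.05)

    def test_recovers_variance_ratio(self):
        h = fit_harmonizer(two_batch_data(delta=0.0, gamma=1.5), "scalar_scale")
        ratio = (h.batch_scales["B"] / h.batch_scales["A"]) ** 2
        assert ratio == pytest.approx(2.25, rel=0.15)

    def test_covariate_scale_recovers_log_ratio(self):
        h = fit_harmonizer(two_batch_data(delta=0.0, gamma=1.5), "covariate_scale")
        ratio = np.exp(2 * (h.batch_scales["B"] - h.batch_scales["A"]))
        assert ratio == pytest.approx(2.25, rel=0.15)

    def test_reference_batch_records_unchanged(self):
        data = two_batch_data()
        h = fit_harmonizer(data, "scalar_scale",
                           HarmonizerConfig(reference_batch="A"))
        batch_a = [r for r in data if r.batch == "A"]
        out = apply_harmonizer(h, batch_a)
        assert max(abs(o.value - r.value) for o, r in zip(out, batch_a)) < 1e-10

    def test_preserves_covariates_and_count(self):
        data = two_batch_data(n=120)
        out = apply_harmonizer(fit_harmonizer(data, "covariate_scale"), data)
        assert len(out) == len(data)
        assert all(o.age == r.age and o.sex == r.sex and o.batch == r.batch
                   for o, r in zip(out, data))

    def test_pure_shift_alignment_of_batch_means(self):
        data = two_batch_data(delta=0.4, n=800, seed=21)
        out = apply_harmonizer(fit_harmonizer(data, "scalar_scale"), data)
        vals = {b: np.array([r.value for r in out
                             if r.batch == b and 45 <= r.age <= 60])
                for b in ("A", "B")}
        se = np.sqrt(sum(v.var(ddof=1) / len(v) for v in vals.values()))
        assert abs(vals["A"].mean() - vals["B"].mean()) < 2 * se

    def test_idempotent_on_harmonized_data(self):
        # re-harmonizing already-harmonized data is a near-identity: the
        # second-pass correction is under 1% of the first-pass correction
        data = two_batch_data(delta=0.3, gamma=1.4)
        once = apply_harmonizer(fit_harmonizer(data, "scalar_scale"), data)
        first = max(abs(a.value - b.value) for a, b in zip(once, data))
        h2 = fit_harmonizer(once, "scalar_scale")
        twice = apply_harmonizer(h2, once)
        second = max(abs(a.value - b.value) for a, b in zip(once, twice))
        assert first > 0.05  # the first pass genuinely moved values
        assert second < 0.01 * first

    def test_unseen_batch_rejected(self):
        h = fit_harmonizer(two_batch_data(), "scalar_scale")
        alien = [dataclasses.replace(make_records([2.5])[0], batch="Z")]
        with pytest.raises(ConfigError, match="'Z'"):
            apply_harmonizer(h, alien)

    def test_skewed_tail_shift_breaks_location_scale_but_not_conformal(self):
        """A batch difference confined to one tail: harmonizing mean and
        variance leaves per-tail miscoverage broken, while conformal
        calibration fixes each tail separately."""
        ref = dataclasses.replace(BASE, batch_effects={"A": (0.0, 1.0)},
                                  noise="gaussian", seed=31)
        skew = dataclasses.replace(BASE, batch_effects={"B": (0.0, 1.0)},
                                   noise="bct", noise_nu=-3.0, noise_tau=5.0,
                                   noise_cv=0.45, seed=32)
        ref_data = simulate_study(ref, {"A": 1500})
        test_data = simulate_study(skew, {"B": 1900}, rng=trial_rng(33, 0))
        cal, val = test_data[:400], test_data[400:]
        naive = interval_from_model(fit_location_scale_shape(ref_data), 0.1)

        h = fit_harmonizer(ref_data + cal, "scalar_scale",
                           HarmonizerConfig(reference_batch="A"))
        _, h_lo, h_hi = false_positive_rate(naive, apply_harmonizer(h, val))
        calibrated, _ = reform_calibrate(naive, cal)
        _, r_lo, r_hi = false_positive_rate(calibrated, val)

        tail_tol = 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(val))
        assert max(abs(r_lo - 0.05), abs(r_hi - 0.05)) < 0.03
        assert max(abs(h_lo - 0.05), abs(h_hi - 0.05)) > 0.03


class TestBatchAdjustedLSS:
    def test_null_batch_effects_shrink_to_zero(self):
        data = two_batch_data(delta=0.0, seed=12)
        adj = fit_batch_adjusted_lss(data)
        assert all(abs(v) < 0.05 for v in adj.mu_offsets.values())

    def test_location_shift_recovered_in_target_interval(self):
        data = two_batch_data(delta=0.3, seed=11)
        adj = fit_batch_adjusted_lss(data)
        grid = np.linspace(30, 85, 12)
        sexes = np.full(12, "F", dtype=object)
        lo_a, hi_a = evaluate_bounds(adj.interval_for_batch("A", 0.05), grid, sexes)
        lo_b, hi_b = evaluate_bounds(adj.interval_for_batch("B", 0.05), grid, sexes)
        center_diff = np.mean((lo_b + hi_b) / 2 - (lo_a + hi_a) / 2)
        assert center_diff == pytest.approx(0.3, abs=0.05)

    def test_single_batch_reduces_to_plain_fit(self, rng):
        _, test_params = scenario_presets("exp1_large_shift")
        data = simulate_study(test_params, {"TEST": 400}, rng=rng)
        adj = fit_batch_adjusted_lss(data)
        plain = fit_location_scale_shape(data)
        grid = np.linspace(30, 85, 12)
        sexes = np.full(12, "F", dtype=object)
        iv_adj = adj.interval_for_batch("TEST", 0.05)
        iv_plain = interval_from_model(plain, 0.05)
        for a, b in zip(evaluate_bounds(iv_adj, grid, sexes),
                        evaluate_bounds(iv_plain, grid, sexes)):
            assert np.allclose(a, b, atol=0.02)

    def test_infinite_shrinkage_recovers_no_offset_model(self):
        data = two_batch_data(delta=0.3, seed=13, n=300)
        adj = fit_batch_adjusted_lss(data, prior_sd=1e-4, prior_sd_logsigma=1e-4)
        assert all(abs(v) < 1e-3 for v in adj.mu_offsets.values())
        assert all(abs(v) < 1e-3 for v in adj.logsigma_offsets.values())
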