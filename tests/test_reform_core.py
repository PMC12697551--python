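"""Conformal calibration core: residuals, conformal quantiles, coverage."""

import math

import numpy as np
import pytest

from reformri import (
    ConfigError,
    ReferenceInterval,
    ReformError,
    ResidualSet,
    compute_residuals,
    conformal_quantile,
    evaluate_membership,
    reform_calibrate,
    residual_diagnostics,
    write_gridded_interval,
    read_gridded_interval,
    interpolate_interval,
)

from conftest import make_records


def brute_force_conformal(values, level):
    """Independent oracle: sort and index, k = ceil(level*(n+1))."""
    ordered = sorted(values)
    n = len(values)
    k = math.ceil(level * (n + 1))
    if k > n:
        return ordered[-1], True
    return ordered[k - 1], False


class TestResiduals:
    def test_direct_substitution(self):
        iv = ReferenceInterval.constant(0.05, 1.0, 3.0)
        rs = compute_residuals(iv, make_records([0.5, 3.4]))
        assert rs.lower_residuals[0] == pytest.approx(0.5)
        assert rs.upper_residuals[0] == pytest.approx(-2.5)
        assert rs.lower_residuals[1] == pytest.approx(-2.4)
        assert rs.upper_residuals[1] == pytest.approx(0.4)

    def test_inside_records_have_nonpositive_residuals(self, rng):
        iv = ReferenceInterval.constant(0.05, 1.0, 3.0)
        rs = compute_residuals(iv, make_records(rng.uniform(1.0, 3.0, 50)))
        assert np.all(rs.lower_residuals <= 0) and np.all(rs.upper_residuals <= 0)

    def test_empty_calibration_set_rejected(self):
        iv = ReferenceInterval.constant(0.05, 1.0, 3.0)
        with pytest.raises(ReformError):
            compute_residuals(iv, [])

    def test_calibrated_interval_warns(self):
        iv = ReferenceInterval.constant(0.05, 1.0, 3.0, calibrated=True)
        with pytest.warns(UserWarning, match="calibrated"):
            compute_residuals(iv, make_records([2.0]))


class TestConformalQuantile:
    def test_matches_sort_and_index_oracle_everywhere(self, rng):
        levels = (0.5, 0.9, 0.95, 0.975, 0.99, 0.995)
        for n in range(1, 51):
            values = rng.normal(size=n)
            for level in levels:
                got, ov = conformal_quantile(values, level)
                want, want_ov = brute_force_conformal(values.tolist(), level)
                assert got == want and ov == want_ov

    def test_worked_example(self):
        got, ov = conformal_quantile(np.arange(1.0, 10.0), 0.9)
        assert got == 9.0 and not ov

    def test_overflow_returns_maximum_with_flag(self):
        got, ov = conformal_quantile(np.array([0.5, -0.2, 1.3]), 0.975)
        assert got == 1.3 and ov

    def test_degenerate_all_equal(self):
        for level in (0.5, 0.99):
            got, _ = conformal_quantile(np.full(7, 4.2), level)
            assert got == 4.2

    def test_monotone_in_level(self, rng):
        values = rng.normal(size=37)
        prev = -np.inf
        for level in (0.5, 0.7, 0.9, 0.95, 0.99):
            got, _ = conformal_quantile(values, level)
            assert got >= prev
            prev = got

    def test_empty_rejected(self):
        with pytest.raises(ReformError):
            conformal_quantile(np.array([]), 0.9)


class TestReformCalibrate:
    def test_constants_shift_bounds(self, rng):
        iv = ReferenceInterval.constant(0.05, 1.0, 3.0)
        # values whose residual conformal quantiles are known via the oracle
        vals = rng.uniform(0.0, 4.0, 99)
        cal = make_records(vals)
        calibrated, consts = reform_calibrate(iv, cal)
        c_lo, _ = brute_force_conformal((1.0 - vals).tolist(), 0.975)
        c_hi, _ = brute_force_conformal((vals - 3.0).tolist(), 0.975)
        assert consts.c_lower == pytest.approx(c_lo)
        assert consts.c_upper == pytest.approx(c_hi)
        lo, hi = calibrated.lower([50.0], ["F"]), calibrated.upper([50.0], ["F"])
        assert lo[0] == pytest.approx(1.0 - c_lo)
        assert hi[0] == pytest.approx(3.0 + c_hi)
        assert calibrated.calibrated

    def test_zero_constants_reproduce_naive_interval(self):
        iv = ReferenceInterval.constant(0.5, 1.0, 3.0)
        # nC=9, level 0.75 -> k=8; two values sit exactly on each bound so the
        # 8th and 9th order statistics of both residual sets are 0
        vals = np.concatenate([np.linspace(1.5, 2.5, 5), [1.0, 1.0, 3.0, 3.0]])
        calibrated, consts = reform_calibrate(iv, make_records(vals))
        assert consts.c_lower == 0.0 and consts.c_upper == 0.0
        assert calibrated.lower([40.0], ["F"])[0] == 1.0
        assert calibrated.upper([40.0], ["F"])[0] == 3.0

    def test_shift_invariance_of_constants(self, rng):
        vals = rng.normal(2.0, 0.7, 60)
        iv = ReferenceInterval.constant(0.1, 1.2, 2.8)
        _, c1 = reform_calibrate(iv, make_records(vals))
        shift = 5.5
        iv_s = ReferenceInterval.constant(0.1, 1.2 + shift, 2.8 + shift)
        _, c2 = reform_calibrate(iv_s, make_records(vals + shift))
        assert c1.c_lower == pytest.approx(c2.c_lower, abs=1e-12)
        assert c1.c_upper == pytest.approx(c2.c_upper, abs=1e-12)

    def test_full_alpha_convention_uses_lower_order_statistic(self, rng):
        vals = rng.normal(2.0, 0.5, 200)
        iv = ReferenceInterval.constant(0.1, 1.5, 2.5)
        _, half = reform_calibrate(iv, make_records(vals), "half_alpha")
        _, full = reform_calibrate(iv, make_records(vals), "full_alpha")
        assert full.c_lower <= half.c_lower and full.c_upper <= half.c_upper
        assert full.tail_level_convention == "full_alpha"

    def test_unknown_convention_rejected(self):
        iv = ReferenceInterval.constant(0.1, 1.0, 3.0)
        with pytest.raises(ConfigError):
            reform_calibrate(iv, make_records([2.0]), "third_way")

    def test_reference_free_recalibration_from_gridded_file(self, tmp_path, rng):
        """Calibration depends on the naive interval only through its bounds:
        a gridded-file round trip yields identical constants."""
        iv = ReferenceInterval(
            alpha=0.05,
            lower=lambda a, s: 2.0 + 0.01 * np.atleast_1d(np.asarray(a, float)),
            upper=lambda a, s: 3.5 + 0.01 * np.atleast_1d(np.asarray(a, float)),
        )
        ages = rng.uniform(25, 90, 80)
        cal = make_records(rng.normal(2.8, 0.5, 80), ages=ages)
        _, direct = reform_calibrate(iv, cal)
        path = tmp_path / "grid.csv"
        write_gridded_interval(iv, np.linspace(20, 95, 151), ("F", "M"), path)
        round_trip = interpolate_interval(read_gridded_interval(path), margin=10)
        _, via_file = reform_calibrate(round_trip, cal)
        assert via_file.c_lower == pytest.approx(direct.c_lower, abs=1e-9)
        assert via_file.c_upper == pytest.approx(direct.c_upper, abs=1e-9)


class TestCoverage:
    @pytest.mark.parametrize("n_cal", [40, 120, 400])
    def test_finite_sample_per_tail_miscoverage(self, n_cal):
        """Across exchangeable trials the mean per-tail miscoverage sits in
        [alpha/2 - 3 SE, alpha/2 + 1/(nC+1) + 3 SE], even though the naive
        interval is misspecified for the sampled population."""
        alpha = 0.1
        iv = ReferenceInterval.constant(alpha, 2.2, 2.6)  # deliberately off
        n_trials, n_val = 300, 400
        lower_rates, upper_rates = [], []
        master = np.random.default_rng(7 + n_cal)
        for _ in range(n_trials):
            vals = master.normal(2.0, 0.4, n_cal + n_val)
            cal = make_records(vals[:n_cal])
            calibrated, _ = reform_calibrate(iv, cal)
            lo = calibrated.lower([50.0], ["F"])[0]
            hi = calibrated.upper([50.0], ["F"])[0]
            v = vals[n_cal:]
            lower_rates.append(np.mean(v <= lo))
            upper_rates.append(np.mean(v >= hi))
        for rates in (lower_rates, upper_rates):
            mean = np.mean(rates)
            se = np.std(rates) / np.sqrt(n_trials)
            assert mean <= alpha / 2 + 1.0 / (n_cal + 1) + 3 * se
            assert mean >= alpha / 2 - 3 * se

    def test_width_monotone_in_constants(self):
        iv = ReferenceInterval.constant(0.05, 1.0, 3.0)
        small = iv.shifted(0.1, 0.1)
        large = iv.shifted(0.5, 0.2)
        assert large.lower([50.0], ["F"])[0] <= small.lower([50.0], ["F"])[0]
        assert large.upper([50.0], ["F"])[0] >= small.upper([50.0], ["F"])[0]


class TestMembership:
    iv = ReferenceInterval.constant(0.05, 1.0, 3.0)

    def test_inside(self):
        assert evaluate_membership(self.iv, make_records([2.0])[0]) == "inside"

    def test_boundary_counts_as_outside(self):
        assert evaluate_membership(self.iv, make_records([1.0])[0]) == "below"
        assert evaluate_membership(self.iv, make_records([3.0])[0]) == "above"

    def test_crossed_bounds_never_inside(self):
        crossed = ReferenceInterval.constant(0.05, 3.0, 1.0, calibrated=True)
        assert evaluate_membership(crossed, make_records([2.0])[0]) in ("below", "above")
        assert evaluate_membership(crossed, make_records([0.5])[0]) == "below"
        assert evaluate_membership(crossed, make_records([3.5])[0]) == "above"


class TestDiagnostics:
    def test_all_zero_residuals(self):
        rs = ResidualSet(np.zeros(10), np.zeros(10), alpha=0.05)
        d = residual_diagnostics(rs)
        assert d["lower"]["frac_positive"] == 0.0
        assert d["lower"]["sd"] == 0.0

    def test_symmetric_residuals_mean_zero(self):
        rs = ResidualSet(np.array([-1.0, 1.0]), np.array([-1.0, 1.0]), alpha=0.05)
        d = residual_diagnostics(rs)
        assert d["upper"]["mean"] == 0.0

    def test_binned_counts_conserve_n(self, rng, tmp_path):
        rs = ResidualSet(rng.normal(size=57), rng.normal(size=57), alpha=0.1)
        d = residual_diagnostics(rs, plot_path=tmp_path / "resid.png")
        assert sum(d["lower"]["hist_counts"]) == 57
        assert sum(d["upper"]["hist_counts"]) == 57
        assert (tmp_path / "resid.png").exists()
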