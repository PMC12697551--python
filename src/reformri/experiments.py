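"""Resampling evaluation harness.

Repeats the reference-interval workflow over many random splits: draw a
reference set from the reference dataset and a calibration set from the
test dataset, fit the naive interval, apply each configured calibration
method, and score the false positive rate (FPR, fraction of healthy
validation records outside the interval) — and, when a disease subgroup is
present, the positive rate (PR, fraction of disease records outside).
Trials where a model fit fails are recorded as ``fit_error`` rows and never
abort the sweep.  Wilcoxon signed-rank helpers compare FPR distributions
against the target level and between methods on paired splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .comparators import (
    HarmonizerConfig,
    apply_harmonizer,
    fit_batch_adjusted_lss,
    fit_harmonizer,
    refit_interval,
)
from .errors import ConfigError, FitError, ReformError
from .naive_models import (
    FitConfig,
    fit_additive_quantile,
    fit_location_scale_shape,
    interval_from_model,
)
from .reform_core import reform_calibrate
from .synthetic_data import (
    SimulationParams,
    make_splits,
    scenario_presets,
    simulate_study,
    trial_rng,
)
from .tabular_io import ReferenceInterval, evaluate_bounds, records_to_frame

__all__ = [
    "ExperimentConfig",
    "false_positive_rate",
    "positive_rate",
    "run_resampling_experiment",
    "summarize_trials",
    "SignedRankResult",
    "signed_rank_vs_target",
    "signed_rank_paired",
    "fpr_window_filter",
]

KNOWN_METHODS = ("unadjusted", "reform", "refit", "combat_gam", "combat_ls", "gamlss_re")


# ---------------------------------------------------------------------------
# Rates


def _classify(interval: ReferenceInterval, records):
    """Vectorised membership labels; boundary values count as outside and a
    record violating both crossed bounds is assigned the nearer tail.

    Harmonization-based intervals are scored on the reference scale: the
    records are mapped through the fitted harmonizer first."""
    if isinstance(interval, _HarmonizedInterval):
        records = apply_harmonizer(interval.harmonizer, list(records))
        interval = interval.base
    df = records_to_frame(records)
    ages = df["age"].to_numpy()
    sexes = df["sex"].to_numpy(dtype=object)
    y = df["value"].to_numpy()
    lo, hi = evaluate_bounds(interval, ages, sexes)
    below = y <= lo
    above = y >= hi
    both = below & above
    nearer_lower = np.abs(y - lo) <= np.abs(hi - y)
    out_below = (below & ~both) | (both & nearer_lower)
    out_above = (above & ~both) | (both & ~nearer_lower)
    return out_below, out_above


def false_positive_rate(interval: ReferenceInterval, validation_records):
    """(fpr_total, fpr_lower, fpr_upper) on a healthy validation set."""
    records = list(validation_records)
    if not records:
        raise ReformError("validation set is empty")
    out_below, out_above = _classify(interval, records)
    n = len(records)
    return (
        float((out_below | out_above).sum() / n),
        float(out_below.sum() / n),
        float(out_above.sum() / n),
    )


def positive_rate(interval: ReferenceInterval, case_records):
    """Fraction of disease-group records outside the interval."""
    records = list(case_records)
    if not records:
        raise ReformError("case set is empty")
    out_below, out_above = _classify(interval, records)
    return float((out_below | out_above).sum() / len(records))


# ---------------------------------------------------------------------------
# Experiment configuration and sweep


@dataclass
class ExperimentConfig:
    """Full specification of one resampling sweep.

    ``scenario`` selects a preset generator pair; alternatively provide
    ``reference_params``/``test_params`` directly.  ``reference_sizes`` may
    include the string ``"full"`` for the entire reference dataset.
    """

    scenario: str | None = "exp1_large_shift"
    reference_params: SimulationParams | None = None
    test_params: SimulationParams | None = None
    n_reference_dataset: int = 1000
    n_test_dataset: int = 1000
    n_case_dataset: int = 0
    reference_sizes: tuple = (50, 200, "full")
    calibration_sizes: tuple = (20, 40, 80, 120, 160, 200, 300, 400, 500, 600)
    alphas: tuple = (0.1, 0.05, 0.01)
    n_trials: int = 1000
    methods: tuple = ("unadjusted", "reform", "refit")
    naive_model: str = "bct_lss"
    master_seed: int = 0
    fit_config: FitConfig = field(default_factory=FitConfig)
    refit_min_n: int = 20
    tail_level_convention: str = "half_alpha"

    def resolve_params(self):
        if self.reference_params is not None and self.test_params is not None:
            return self.reference_params, self.test_params
        if self.scenario is None:
            raise ConfigError("provide a scenario name or explicit generator params")
        return scenario_presets(self.scenario)


def _fit_naive(records, naive_model: str, alphas, fit_config: FitConfig):
    """Fit the naive model once and derive an interval per alpha."""
    if naive_model == "bct_lss":
        model = fit_location_scale_shape(records, fit_config)
        return {a: interval_from_model(model, a) for a in alphas}
    if naive_model == "additive_qr":
        out = {}
        curves = {}
        for a in alphas:
            for lvl in (a / 2, 1 - a / 2):
                if lvl not in curves:
                    curves[lvl] = fit_additive_quantile(records, lvl, fit_config)
            out[a] = interval_from_model((curves[a / 2], curves[1 - a / 2]), a)
        return out
    raise ConfigError(f"unknown naive model {naive_model!r}")


def run_resampling_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full sweep; returns one row per (sizes, alpha, method, trial).

    The reference and test datasets are generated once from the config's
    generator pair; each trial then redraws the reference and calibration
    subsets without replacement, with validation = the remaining test-batch
    healthy records.  Rows are ordered deterministically and the whole table
    is reproducible from ``master_seed``.
    """
    ref_params, test_params = config.resolve_params()
    for m in config.methods:
        if m not in KNOWN_METHODS:
            raise ConfigError(f"unknown method {m!r}; known: {KNOWN_METHODS}")
    ref_batches = list(ref_params.batch_effects)
    test_batch = list(test_params.batch_effects)[0]
    per_batch = max(1, config.n_reference_dataset // len(ref_batches))
    ref_data = simulate_study(
        ref_params, {b: per_batch for b in ref_batches},
        rng=trial_rng(config.master_seed, 10_000_001),
    )
    test_spec = {"CN": config.n_test_dataset}
    if config.n_case_dataset > 0:
        test_spec["CASE"] = config.n_case_dataset
    test_data = simulate_study(
        test_params, {test_batch: test_spec},
        rng=trial_rng(config.master_seed, 10_000_002),
    )
    all_records = ref_data + test_data
    by_id = {r.subject_id: r for r in all_records}
    case_records = [r for r in test_data if r.group == "CASE"]
    n_ref_full = sum(1 for r in ref_data if r.group == "CN")

    sizes = []
    for s in config.reference_sizes:
        n = n_ref_full if s == "full" else int(s)
        if n > n_ref_full:
            raise ConfigError(
                f"reference size {s} exceeds the reference dataset ({n_ref_full})"
            )
        sizes.append((s, n))
    for nc in config.calibration_sizes:
        if nc >= config.n_test_dataset:
            raise ConfigError(
                f"calibration size {nc} leaves no validation records "
                f"(test dataset has {config.n_test_dataset})"
            )

    rows = []
    naive_cache: dict = {}
    trial_counter = 0
    for size_label, n_ref in sizes:
        for n_cal in config.calibration_sizes:
            for trial in range(config.n_trials):
                trial_counter += 1
                split = make_splits(
                    all_records, n_ref, n_cal, ref_batches, test_batch,
                    seed=np.random.SeedSequence(
                        [config.master_seed, trial_counter]
                    ).generate_state(1)[0] % (2**31),
                )
                ref_recs = [by_id[i] for i in sorted(split.reference_ids)]
                cal_recs = [by_id[i] for i in sorted(split.calibration_ids)]
                val_recs = [by_id[i] for i in sorted(split.validation_ids)]

                cache_key = frozenset(split.reference_ids)
                try:
                    if cache_key not in naive_cache:
                        naive_cache[cache_key] = _fit_naive(
                            ref_recs, config.naive_model, config.alphas,
                            config.fit_config,
                        )
                        if len(naive_cache) > 8:  # keep only the reusable full-set fit
                            naive_cache = {cache_key: naive_cache[cache_key]}
                    naive_by_alpha = naive_cache[cache_key]
                    naive_err = None
                except FitError as exc:
                    naive_by_alpha, naive_err = None, str(exc)

                for alpha in config.alphas:
                    for method in config.methods:
                        row = {
                            "trial": trial,
                            "method": method,
                            "n_reference": size_label,
                            "n_calibration": n_cal,
                            "alpha": alpha,
                            "fpr_total": np.nan,
                            "fpr_lower": np.nan,
                            "fpr_upper": np.nan,
                            "pr": np.nan,
                            "status": "ok",
                            "error": "",
                        }
                        try:
                            if naive_err is not None and method != "refit":
                                raise FitError(naive_err)
                            interval = _method_interval(
                                method, naive_by_alpha[alpha] if naive_by_alpha else None,
                                alpha, ref_recs, cal_recs, test_batch, config,
                            )
                            fpr, flo, fhi = false_positive_rate(interval, val_recs)
                            row.update(fpr_total=fpr, fpr_lower=flo, fpr_upper=fhi)
                            if case_records:
                                row["pr"] = positive_rate(interval, case_records)
                        except (FitError, ConfigError, ReformError) as exc:
                            row.update(status="fit_error", error=str(exc))
                        rows.append(row)
    return pd.DataFrame(rows)


def _method_interval(method, naive_interval, alpha, ref_recs, cal_recs,
                     test_batch, config: ExperimentConfig) -> ReferenceInterval:
    if method == "unadjusted":
        return naive_interval
    if method == "reform":
        calibrated, _ = reform_calibrate(
            naive_interval, cal_recs,
            tail_level_convention=config.tail_level_convention,
        )
        return calibrated
    if method == "refit":
        fc = FitConfig(
            n_interior_knots=config.fit_config.n_interior_knots,
            penalty=config.fit_config.penalty,
            min_n=config.refit_min_n,
            max_iter=config.fit_config.max_iter,
            tol=config.fit_config.tol,
        )
        return refit_interval(cal_recs, alpha, model=config.naive_model, config=fc)
    if method in ("combat_gam", "combat_ls"):
        variant = "scalar_scale" if method == "combat_gam" else "covariate_scale"
        ref_batches = list(dict.fromkeys(r.batch for r in ref_recs))
        hconf = HarmonizerConfig(
            min_n_per_batch=min(20, len(cal_recs)),
            reference_batch=ref_batches[0] if len(ref_batches) == 1 else None,
        )
        harm = fit_harmonizer(ref_recs + cal_recs, variant=variant, config=hconf)
        if len(ref_batches) == 1:
            # single reference batch: the naive interval already lives on the
            # reference scale; classify harmonized records against it
            base = naive_interval
        else:
            # pooled convention: refit the naive interval on harmonized data
            base = _fit_naive(
                apply_harmonizer(harm, ref_recs), config.naive_model,
                (alpha,), config.fit_config,
            )[alpha]
        return _HarmonizedInterval(base, harm)
    if method == "gamlss_re":
        adj = fit_batch_adjusted_lss(ref_recs + cal_recs, config.fit_config)
        return adj.interval_for_batch(test_batch, alpha)
    raise ConfigError(f"unknown method {method!r}")


class _HarmonizedInterval(ReferenceInterval):
    """A reference-scale interval paired with the harmonizer that maps new
    records onto that scale before classification.  The bound functions
    evaluate on the reference scale; the rate functions recognise this type
    and harmonize records first."""

    def __init__(self, base: ReferenceInterval, harmonizer):
        self.base = base
        self.harmonizer = harmonizer
        super().__init__(
            alpha=base.alpha,
            lower=base.lower,
            upper=base.upper,
            calibrated=base.calibrated,
            provenance=f"harmonized({harmonizer.variant}) | {base.provenance}",
        )


# ---------------------------------------------------------------------------
# Summaries and tests


def summarize_trials(trials: pd.DataFrame, grouping=("method", "n_reference", "n_calibration", "alpha")) -> pd.DataFrame:
    """Median and IQR of FPR (and PR) per group, excluding failed fits.

    Failed-fit rows are excluded from the statistics and counted in
    ``n_error``; a group with no successful trial reports null statistics.
    """
    if trials.empty:
        raise ConfigError("empty trial table")
    grouping = list(grouping)
    for col in grouping:
        if col not in trials.columns:
            raise ConfigError(f"grouping column {col!r} absent from the trial table")
    out = []
    for keys, grp in trials.groupby(grouping, sort=True, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        ok = grp[grp["status"] == "ok"]
        row = dict(zip(grouping, keys))
        row["n_ok"] = len(ok)
        row["n_error"] = len(grp) - len(ok)
        for col in ("fpr_total", "pr"):
            vals = ok[col].dropna() if col in ok else pd.Series(dtype=float)
            if len(vals):
                row[f"{col}_median"] = float(vals.median())
                row[f"{col}_q25"] = float(vals.quantile(0.25))
                row[f"{col}_q75"] = float(vals.quantile(0.75))
            else:
                row[f"{col}_median"] = np.nan
                row[f"{col}_q25"] = np.nan
                row[f"{col}_q75"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool
    n_used: int
    alternative: str = "two-sided"


def _signed_rank(diffs, alternative: str, sig_level: float) -> SignedRankResult:
    diffs = np.asarray(diffs, float)
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return SignedRankResult(np.nan, 1.0, False, True, 0, alternative)
    no_ties = np.unique(np.abs(nz)).size == nz.size
    method = "exact" if (nz.size <= 25 and no_ties) else "approx"
    res = stats.wilcoxon(nz, alternative=alternative, method=method,
                         correction=(method == "approx"))
    return SignedRankResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < sig_level),
        degenerate=False,
        n_used=int(nz.size),
        alternative=alternative,
    )


def signed_rank_vs_target(values, target: float, alternative: str = "two-sided",
                          sig_level: float = 0.05) -> SignedRankResult:
    """One-sample Wilcoxon signed-rank test of ``values`` against ``target``.

    Exact null distribution for n <= 25 without ties, otherwise a normal
    approximation with continuity correction; zero differences are dropped.
    All-zero differences yield a flagged degenerate result with p = 1.
    """
    return _signed_rank(np.asarray(values, float) - target, alternative, sig_level)


def signed_rank_paired(values_a, values_b, alternative: str = "two-sided",
                       sig_level: float = 0.05) -> SignedRankResult:
    """Paired Wilcoxon signed-rank test of A - B on trial-matched values."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ConfigError(f"paired samples differ in length: {a.shape} vs {b.shape}")
    return _signed_rank(a - b, alternative, sig_level)


def fpr_window_filter(trials: pd.DataFrame, alpha: float,
                      tolerance_fraction: float = 0.2) -> pd.DataFrame:
    """Keep trials whose FPR is near-target for *every* compared method.

    A trial (at one size combination) is retained only when all of its
    method rows are successful and have ``fpr_total`` within
    ``[alpha*(1-tol), alpha*(1+tol)]``.
    """
    if tolerance_fraction <= 0:
        raise ConfigError("tolerance fraction must be positive")
    lo, hi = alpha * (1 - tolerance_fraction), alpha * (1 + tolerance_fraction)
    sub = trials[np.isclose(trials["alpha"], alpha)]
    keys = ["trial", "n_reference", "n_calibration"]

    def keep(grp):
        return bool(((grp["status"] == "ok")
                     & (grp["fpr_total"] >= lo)
                     & (grp["fpr_total"] <= hi)).all())

    mask = sub.groupby(keys, sort=False).apply(keep, include_groups=False)
    good = set(mask[mask].index)
    sel = sub.set_index(keys).index.isin(good)
    return sub[sel].reset_index(drop=True)


def reform_coverage_trials(
    alphas=(0.05,),
    n_trials: int = 500,
    n_calibration: int = 400,
    n_validation: int = 1000,
    n_reference: int = 1000,
    master_seed: int = 0,
    scenario: str = "exp1_large_shift",
    naive_model: str = "bct_lss",
    methods=("reform",),
    fit_config: FitConfig | None = None,
    tail_level_convention: str = "half_alpha",
) -> dict:
    """Coverage simulation with a shifted reference population.

    Fits the naive interval once on ``n_reference`` records drawn from the
    scenario's reference generator (shifted in location and scale relative
    to the test generator), then for each seeded trial draws a fresh
    calibration set of ``n_calibration`` and validation set of
    ``n_validation`` from the test generator, calibrates, and records the
    validation FPR.  Returns ``{(method, alpha): array of per-trial FPR}``.
    """
    ref_params, test_params = scenario_presets(scenario)
    ref_batches = list(ref_params.batch_effects)
    test_batch = list(test_params.batch_effects)[0]
    per_batch = max(1, n_reference // len(ref_batches))
    ref = simulate_study(ref_params, {b: per_batch for b in ref_batches},
                         rng=trial_rng(master_seed, 0))
    naive_by_alpha = _fit_naive(ref, naive_model, alphas, fit_config or FitConfig())
    out = {(m, a): [] for m in methods for a in alphas}
    for t in range(1, n_trials + 1):
        data = simulate_study(
            test_params, {test_batch: n_calibration + n_validation},
            rng=trial_rng(master_seed, t),
        )
        cal, val = data[:n_calibration], data[n_calibration:]
        for a in alphas:
            for m in methods:
                if m == "unadjusted":
                    interval = naive_by_alpha[a]
                elif m == "reform":
                    interval, _ = reform_calibrate(
                        naive_by_alpha[a], cal,
                        tail_level_convention=tail_level_convention,
                    )
                else:
                    raise ConfigError(
                        f"method {m!r} not supported by the coverage helper"
                    )
                out[(m, a)].append(false_positive_rate(interval, val)[0])
    return {k: np.asarray(v) for k, v in out.items()}


def plot_fpr_summary(summary: pd.DataFrame, path, value_col: str = "fpr_total"):
    """Median +/- IQR of FPR (or PR) versus calibration size, one panel per
    alpha, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    alphas = sorted(summary["alpha"].unique())
    fig, axes = plt.subplots(len(alphas), 1, figsize=(7, 2.8 * len(alphas)),
                             squeeze=False)
    for ax, alpha in zip(axes[:, 0], alphas):
        sub = summary[np.isclose(summary["alpha"], alpha)]
        for method, grp in sub.groupby("method"):
            grp = grp.sort_values("n_calibration")
            med = grp[f"{value_col}_median"]
            ax.plot(grp["n_calibration"], med, marker="o", ms=3, label=method)
            ax.fill_between(grp["n_calibration"], grp[f"{value_col}_q25"],
                            grp[f"{value_col}_q75"], alpha=0.2)
        if value_col == "fpr_total":
            ax.axhline(alpha, ls="--", c="k", lw=0.8)
        ax.set_ylabel(value_col)
        ax.set_title(f"alpha = {alpha}", fontsize=9)
        ax.legend(fontsize=7)
    axes[-1, 0].set_xlabel("calibration set size")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
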