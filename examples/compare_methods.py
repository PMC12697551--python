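"""Compare calibration strategies over resampled trials.

Runs a small resampling sweep (30 trials) on the large-shift scenario:
direct application of the reference interval (unadjusted), refitting in the
calibration set, and conformal calibration, at two calibration sizes.
Prints median and interquartile range of the false positive rate per method.
"""

from reformri import (
    ExperimentConfig,
    FitConfig,
    run_resampling_experiment,
    summarize_trials,
)

config = ExperimentConfig(
    scenario="exp1_large_shift",
    n_reference_dataset=800,
    n_test_dataset=1000,
    reference_sizes=("full",),
    calibration_sizes=(40, 400),
    alphas=(0.05,),
    n_trials=30,
    methods=("unadjusted", "refit", "reform"),
    master_seed=12,
    fit_config=FitConfig(min_n=20),
    refit_min_n=20,
)
trials = run_resampling_experiment(config)
summary = summarize_trials(trials)

print(f"{'method':12s} {'nC':>4s} {'median FPR':>11s} {'IQR':>17s} {'errors':>7s}")
for _, row in summary.sort_values(["n_calibration", "method"]).iterrows():
    print(f"{row['method']:12s} {row['n_calibration']:4d} "
          f"{row['fpr_total_median']:11.3f} "
          f"[{row['fpr_total_q25']:.3f}, {row['fpr_total_q75']:.3f}] "
          f"{row['n_error']:7d}")
print()
print("Target FPR is 0.05. Unadjusted intervals inherit the reference-study")
print("shift and overshoot badly at every nC; refitting is wildly inflated")
print("at nC=40 and only approaches target at 400; conformal calibration")
print("sits near target at both sizes.")
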