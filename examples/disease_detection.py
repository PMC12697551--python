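"""Positive rate in a disease subgroup under a calibrated interval.

Simulates the multi-site scenario: 22 reference sites, one target site with
healthy controls plus a disease group whose phenotype runs 0.3 mm lower.
Compares how often disease-group scans fall outside the unadjusted versus
the conformally calibrated 95% interval, at matched specificity.
"""

import reformri as rf

ref_params, test_params = rf.scenario_presets("exp3_multisite")
sites = {b: 130 for b in ref_params.batch_effects}
reference = rf.simulate_study(ref_params, sites)
target = rf.simulate_study(test_params, {"TEST": {"CN": 800, "CASE": 300}},
                           rng=rf.trial_rng(5, 1))
cn = [r for r in target if r.group == "CN"]
cases = [r for r in target if r.group == "CASE"]
calibration, validation = cn[:400], cn[400:]

naive = rf.interval_from_model(rf.fit_location_scale_shape(reference), 0.05)
calibrated, _ = rf.reform_calibrate(naive, calibration)

for name, interval in (("unadjusted", naive), ("calibrated", calibrated)):
    fpr, *_ = rf.false_positive_rate(interval, validation)
    pr = rf.positive_rate(interval, cases)
    print(f"{name:11s}: healthy FPR {fpr:.3f}, disease positive rate {pr:.3f}")
print()
print("The unadjusted multi-site chart is conservative on this target site")
print("(FPR under 0.05) and misses disease cases; calibration brings the")
print("healthy FPR to the nominal level (up to single-split noise) and flags")
print("substantially more disease-group scans at that matched specificity.")
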