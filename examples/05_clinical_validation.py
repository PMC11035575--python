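"""Clinical validation of the calibrated device configuration.

Fits the closed-form ridge on the framework branch (wrist sensor), then
runs the method-comparison statistics on the held-out predictions:
error analysis, Bland–Altman limits of agreement, Clarke Error Grid zone
classification, and the paired t-test against the invasive reference.
"""

from nirglucose import (
    SynthConfig,
    bland_altman,
    build_branch,
    ceg_summary,
    compute_metrics,
    generate_dataset,
    mmol_to_mgdl,
    paired_t_test,
    run_comparison,
)

samples, _ = generate_dataset(SynthConfig(seed=0))
wrist = samples[samples.site == "wrist"].reset_index(drop=True)
ds = build_branch(wrist, "framework")
report = run_comparison(
    {"framework": (ds.features.to_numpy(float), ds.target_mmol.to_numpy(float))},
    models=["RR"],
)
fit = report.fits[("framework", "RR")]
ref_mmol, pred_mmol = fit.y_test, fit.predictions

m = compute_metrics(ref_mmol, pred_mmol)
print(f"held-out metrics: MAE {m.mae:.4f} mmol/L, MSE {m.mse:.4f}, r2 {m.r2:.4f}")

ref, pred = mmol_to_mgdl(ref_mmol), mmol_to_mgdl(pred_mmol)
ba = bland_altman(ref, pred)
print(f"Bland–Altman: bias {ba.bias:+.3f} mg/dL, "
      f"LOA [{ba.loa_lower:.3f}, {ba.loa_upper:.3f}], "
      f"{ba.pct_within_loa:.1f}% of differences within the LOA")

ceg = ceg_summary(ref, pred)
print("CEG zones: " + ", ".join(f"{z} {p:.1f}%" for z, p in ceg.percentages.items()))
print(f"clinically acceptable (A+B): {ceg.clinically_acceptable_pct:.1f}%")

tt = paired_t_test(ref, pred)
print(f"paired t-test: t = {tt.t_calculated:.3f}, df = {tt.df}, "
      f"p = {tt.p_value:.3f}, t_critical = {tt.t_critical:.3f} -> {tt.decision}")
print()
print("Zone A/B points are clinically acceptable; accepting H0 means no")
print("systematic difference between predicted and reference glucose.")
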