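"""The interval-based skin-tone adjustment model.

Voltages of all skin tones falling in the same 5 mg/dL glucose interval are
pooled; the interval variance X_var gives a correction factor
F = 1/sqrt(X_var) and an adjustment factor A = X_var * F = sqrt(X_var),
which multiplies every voltage in the interval.
"""

from nirglucose import (
    SynthConfig,
    adjustment_factor,
    correction_factor,
    fit_adjustment_model,
    generate_dataset,
)

# the worked chain on the pilot study's stated interval variance
x_var = 0.000375
f = correction_factor(x_var)
a = adjustment_factor(x_var, f)
print(f"pilot interval variance X_var = {x_var}")
print(f"correction factor  F = 1/sqrt(X_var) = {f:.4f}")
print(f"adjustment factor  A = X_var * F     = {a:.6f}")
print()

# the same model fitted on a full synthetic campaign (wrist sensor)
samples, _ = generate_dataset(SynthConfig(seed=0))
wrist = samples[samples.site == "wrist"].reset_index(drop=True)
model = fit_adjustment_model(wrist)
table = model.to_frame()
print(f"fitted adjustment model: {len(table)} intervals, "
      f"{int((table.n >= 2).sum())} with a defined variance")
print(table.head(4).to_string(index=False))
print()
print("A ~ sqrt of the pooled within-interval voltage variance; degenerate")
print("intervals (n < 2 or zero variance) keep the identity factor A = 1.")
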