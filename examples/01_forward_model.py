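"""Beer–Lambert forward model: voltage vs glucose for each skin tone.

The reflected-light voltage decreases monotonically with blood glucose
(more chromophore -> more absorption -> weaker reflected signal), and skin
tone shifts the whole curve by a small transmission factor.
"""

from nirglucose import forward_voltage

print(f"{'glucose (mg/dL)':>16} {'dark (V)':>10} {'wheatish (V)':>13} {'fair (V)':>10}")
for glucose in (80, 150, 250, 350, 488):
    volts = [forward_voltage(glucose, tone, "wrist")
             for tone in ("dark", "wheatish", "fair")]
    print(f"{glucose:>16} {volts[0]:>10.5f} {volts[1]:>13.5f} {volts[2]:>10.5f}")

print()
print("Each column decreases with glucose; at fixed glucose the three tones")
print("differ by ~1-2%, the pigmentation interference the adjustment")
print("algorithm is designed to compensate.")
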