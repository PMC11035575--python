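"""Simulate the acquisition campaign: cohort, frame logs, sample table.

The default configuration emulates the study conditions: 101 volunteers
(57 M / 44 F, mostly diabetic), reference glucose spanning 80–488 mg/dL,
three skin tones, 100 voltage frames aggregated per sample, finger and
wrist sensors.
"""

from nirglucose import SynthConfig, generate_cohort, generate_dataset

cfg = SynthConfig(seed=0)
cohort = generate_cohort(cfg)
samples, truth = generate_dataset(cfg)

print(f"cohort: {len(cohort)} volunteers "
      f"({(cohort.sex == 'M').sum()} M / {(cohort.sex == 'F').sum()} F, "
      f"{cohort.diabetic.sum()} diabetic)")
print(f"skin tones: {cohort.skin_tone.value_counts().to_dict()}")
print(f"samples: {len(samples)} acquisitions "
      f"({samples.site.value_counts().to_dict()})")
print(f"reference glucose: {samples.reference_mgdl.min()}–"
      f"{samples.reference_mgdl.max()} mg/dL")
print(f"aggregated voltages: {samples.hv_volts.min():.4f}–"
      f"{samples.hv_volts.max():.4f} V")
print()
print("Each acquisition averages 100 noisy frames; ground_truth keeps the")
print("noise-free forward voltage for recovery tests.")
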