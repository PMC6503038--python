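"""Generate the three synthetic cohorts and look at their structure.

The generator emulates a morphometric MS study: a healthy training cohort
(ages 12-95), a single-scanner case-control set, and a second-scanner
longitudinal patient set with three visits over ~4.4 years. Every scan's
latent brain age is recorded alongside the observed features.
"""

from brainage import GeneratorConfig, generate_case_control, generate_longitudinal_patients, generate_training_cohort
from brainage.io import write_feature_table

config = GeneratorConfig(n_train_hc=200, n_test_hc=60, n_ms=60)

train = generate_training_cohort(config, seed=1)
cc = generate_case_control(config, seed=2)
longitudinal = generate_longitudinal_patients(config.replace(n_ms=30), seed=3)

print(f"training cohort: {train.n_scans} scans, {len(train.feature_names)} features "
      f"({sorted(set(train.feature_meta['region']))[:3]} ...)")
print(f"case-control:    {cc.n_scans} scans "
      f"({(cc.data['group'] == 'HC').sum()} HC / {(cc.data['group'] == 'MS').sum()} MS)")
print(f"longitudinal:    {longitudinal.n_scans} scans from "
      f"{longitudinal.data['subject_id'].nunique()} patients on "
      f"{longitudinal.data['scanner'].iloc[0]}")

# the latent truth behind one patient: brain age = age + u + gap (+ accel * t)
lat = longitudinal.latent.iloc[:3]
print("\nlatent truth, first patient (3 visits):")
print(lat[["subject_id", "session", "u", "gap_dev", "delta", "t_since_first", "ba_global"]]
      .to_string(index=False))
print("\nInterpretation: ba_global - age - u - gap_dev grows by delta (years of "
      "brain age) per year of follow-up; the brain-age model must recover this "
      "from the features alone.")

paths = write_feature_table(cc, "example_output/case_control")
print(f"\nwrote tidy CSVs: {sorted(paths)}")
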