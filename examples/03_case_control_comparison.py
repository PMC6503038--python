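"""Case-control comparison: covariate-adjusted BAG difference and Cohen's D.

The generator injects a 4.4-year global brain-age offset in patients (6.2
years in the subcortical/cerebellar region); the pipeline should recover
both from the features alone.
"""

from brainage import (
    CVSettings,
    GeneratorConfig,
    build_bag_table,
    case_control_compare,
    generate_case_control,
    generate_training_cohort,
    predict_brain_age,
    train_brain_age,
)

config = GeneratorConfig()
train = generate_training_cohort(config, seed=1)
test = generate_case_control(config, seed=2)

for region in ("global", "subcortical_cerebellar"):
    model = train_brain_age(train, region, cv=CVSettings(outer_folds=0), seed=0)
    bt = build_bag_table(test, predict_brain_age(model, test), region=region)
    cmp = case_control_compare(bt)
    print(
        f"{region:>24}: adjusted BAG difference = {cmp.adjusted_difference:+.2f} years, "
        f"Cohen's D = {cmp.cohens_d:.2f}, p = {cmp.p:.2g} "
        f"(n = {cmp.n_case} MS / {cmp.n_control} HC)"
    )
print("\nInjected truth: +4.4 years globally, +6.2 years subcortical/cerebellar. "
      "The difference is adjusted for age, age^2 and sex; Cohen's D is the "
      "standardized group separation of residualized BAG.")
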