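"""Total-collection apparent digestibility on a synthetic trial.

Builds intake and fecal records realising a known digestibility truth,
runs the digestibility pipeline and prints per-nutrient recovery, plus the
metabolic-body-weight intake scaling used to compare animals of different
size.
"""

from rumengrad import (
    default_config,
    dmi_per_metabolic_weight,
    gen_diets,
    gen_digestion_trial,
    mean_digestibility,
    trial_digestibility,
)

cfg = default_config(seed=7)
diets = gen_diets(cfg)
truth = {"dm": 53.19, "cp": 69.17, "ndf": 45.44, "adf": 39.62, "ash": 16.41}
intakes, feces = gen_digestion_trial(diets, cfg, truth)  # noisy collection

results = trial_digestibility(intakes, feces)
means = mean_digestibility(results)
print("apparent digestibility, mean over animal-periods (truth in brackets):")
for nutrient, d in sorted(means.items()):
    t = truth.get(nutrient)
    extra = f" (truth {t:.2f})" if t is not None else ""
    print(f"  {nutrient.upper():6s} {d:6.2f} %{extra}")

rec = intakes[0]
print(
    f"\nintake scaling: {rec.dm_intake:.2f} kg DM/day at {rec.body_weight:.0f} kg BW "
    f"= {dmi_per_metabolic_weight(rec.dm_intake, rec.body_weight):.1f} g/kg W^0.75"
)
print(
    "\nRecovered digestibilities sit within the collection noise of the "
    "configured truths;\nnegative values, if any, would be reported "
    "unclipped with a warning."
)
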