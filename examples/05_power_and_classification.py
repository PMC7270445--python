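"""Sample-size arithmetic and the deterministic classification rules."""

from vdgrs import (
    SampleSizeInput,
    bonferroni,
    classify_vitd,
    compute_bmi,
    sample_size,
)

# two-group mean-difference power: SD 18.5 ng/mL, difference 13.08 ng/mL,
# alpha 0.05 (z=1.96), power 90% (z=1.28)
n, ceiling = sample_size(SampleSizeInput(z_alpha=1.96, z_beta=1.28,
                                         s=18.5, diff=13.08))
print(f"required n per group: {n:.2f} -> {ceiling}")

for m in (9, 18):
    family = bonferroni(0.05, m)
    print(f"Bonferroni family of {m}: threshold {family.threshold:.5f} "
          f"(displayed {family.threshold_display})")

for value in (11.9, 12.0, 19.99, 20.0):
    print(f"25(OH)D {value} ng/mL -> {classify_vitd(value).category}")

bmi, category = compute_bmi(60.0, 160.0)
print(f"BMI 60 kg / 160 cm = {bmi:.2f} kg/m2 -> {category}")
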