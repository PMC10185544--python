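"""Classify a full synthetic cohort against its own control group and build
the per-grade amplitude x power contingency tables with exact Fisher tests.

Category A: no amplitude/power abnormality; B: amplitude reduced >= 50%
without power loss; C: amplitude reduced with >= 30% power loss; D: power
loss without amplitude reduction.
"""

from cordssep import (
    CohortConfig,
    build_control_reference,
    classify_patient,
    extract_features,
    fisher_exact_2x2,
    generate_cohort,
    generate_epoch_set,
    tabulate_by_grade,
)
from cordssep.cohort import epoch_seed

config = CohortConfig(seed=1)  # default study-sized cohort (10, 35, 57, 34)
truths = generate_cohort(config)
features = []
for truth in truths:
    epochs = generate_epoch_set(truth, config.protocol, epoch_seed(config.seed, truth, "right"),
                                side="right", noise_sd_uv=config.noise_sd_uv)
    features.append(extract_features(epochs, stft_params=config.stft, region=config.region))

controls = [f for f, t in zip(features, truths) if t.grade == 0]
reference = build_control_reference(controls)
ref = reference.for_side("right")
print(f"control reference (n={ref.n_controls}): amplitude {ref.mean_amplitude_uv:.2f} uV, "
      f"TFA power {ref.mean_tfa_power:.1f}")

calls = [classify_patient(f, reference) for f in features]
tables = tabulate_by_grade(calls, {t.patient_id: t.grade for t in truths})
for g in (1, 2, 3):
    t = tables[g]
    p = fisher_exact_2x2(t.table).p_value
    print(f"grade {g} (n={t.n}): counts [[A,B],[D,C]] = {t.table.as_array().tolist()}, "
          f"A/B/C = {t.category_pct['A']:.1f}/{t.category_pct['B']:.1f}/"
          f"{t.category_pct['C']:.1f} %, Fisher p = {p:.3f}")
print()
print("Power loss appears only in amplitude-abnormal patients (empty D cell),")
print("and the share of abnormal patients grows with the MRI grade.")
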