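"""Extract the three evoked-potential features from one epoch set.

The ERP is the mean over stimulus-locked trials; amplitude is its
peak-to-peak span over the 100 ms window, latency the time of the maximal
positive peak (the tibial P40), and TFA power the summed spectrogram
magnitude inside 0-100 ms x 10-100 Hz.
"""

from cordssep import CohortConfig, compute_erp, extract_features, generate_cohort, generate_epoch_set

config = CohortConfig(counts=(1, 0, 0, 1), seed=4)
control, compressed = generate_cohort(config)

for truth in (control, compressed):
    epochs = generate_epoch_set(truth, config.protocol, seed=0, side="right",
                                noise_sd_uv=config.noise_sd_uv)
    erp = compute_erp(epochs)
    feats = extract_features(epochs, stft_params=config.stft, region=config.region)
    print(f"{truth.patient_id} (grade {truth.grade}): "
          f"{epochs.n_trials} trials x {epochs.n_samples} samples")
    print(f"  amplitude {feats.amplitude_uv:.3f} uV (truth {truth.amplitude_uv['right']:.3f}), "
          f"latency {feats.latency_ms:.2f} ms (truth {truth.latency_ms['right']:.2f}), "
          f"TFA power {feats.tfa_power:.1f}")

print()
print("The grade-3 patient shows the attenuated amplitude the classifier")
print("will compare against the control mean; residual noise after 300-trial")
print("averaging perturbs the estimates by only a few percent.")
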