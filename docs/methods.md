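# Methods

This note documents the models and procedures implemented in `cordssep`,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real recordings.

## Feature extraction

**ERP.** The event-related potential is the pointwise arithmetic mean over
stimulus-locked trials. Averaging is the only preprocessing: no artifact
rejection, baseline correction or adaptive filtering (out of scope by
design — the analysis targets preoperative tibial P40 data, not montage or
cleaning logic).

**Amplitude and latency.** Amplitude is the peak-to-peak span (max − min)
of the ERP within the analysis window, latency the time of the maximal
positive value, earliest sample on exact ties. The default window is the
full 0–100 ms epoch (the procedure is a global extremum search); a narrower
P40-focused window (e.g. 25–60 ms) can be passed instead.

**TFA power.** The ERP (not single trials — configurable, but the average
is the default input) is short-time-Fourier transformed with a Hann window
of 25% of the epoch, 75% overlap and 4× zero-padding; frames are placed
fully inside the signal with no boundary padding. The spectrogram is the
squared magnitude per frame, and the TFA feature is the **sum** of cells
whose time-frame and frequency-bin centres fall inside a fixed region,
default 0–100 ms × 10–100 Hz. Sum versus mean over the region is
immaterial downstream, where only percent changes against a control mean
are used; both the region and the STFT parameters are recorded in output
provenance. With a rectangular window, non-overlapping frames and no
padding the spectrogram satisfies an exact Parseval identity against framed
signal energy, which the tests exercise.

**Units.** Amplitudes are microvolts throughout. TFA power is reported in
a consistent but arbitrary unit (a squared-magnitude sum depends on window
norm and padding); every use of it in the package is relative.

## Morphometry and grading

CCR = AP/transverse diameter at maximal compression; MSCC =
(1 − d_i/((d_a + d_b)/2)) × 100 with the adjacent-level AP diameters d_a,
d_b. The MSCC expression follows the standard adjacent-level form used in
the spine literature. Negative MSCC (cord wider than its neighbours) is
kept by default; a clamp-at-zero flag exists because control-group
summaries in the literature sometimes floor the index (a grade-0 first
quartile of exactly 0.00 suggests as much), and the choice is recorded in
run provenance.

Grading: grade 3 = deformation ∧ signal change; grade 2 = deformation
without signal change; grade 1 = no deformation with CSF occlusion ≥ 50%;
grade 0 otherwise. Two boundary decisions: exactly 50% occlusion maps to
grade 1 (the published rule texts leave 50% unassigned), and deformation
takes precedence over occlusion (grades 2–3 are defined by deformation
irrespective of the CSF space).

## Classification

The reference statistic is the control group's **mean** (with SEM), per
side, deliberately not the median used in descriptive tables. Percent
changes are signed and never clipped; negative change (patient better than
control) is normal. All three cuts (50% amplitude reduction, 30% power
loss, 10% latency delay) are inclusive; the published latency wording
("increased by > 10% (inclusive)") is internally contradictory and is
resolved as ≥ 10%, matching the amplitude criterion. Boundary comparisons
carry a 1 × 10⁻⁹ relative guard so values mathematically at a cut are not
demoted by float rounding. The right side is the default analysis side
(the side for which control reference means are published and which drives
the contingency analysis); the left is handled symmetrically when asked.
Category D (power loss without amplitude abnormality) is representable and
counted even though compression cohorts typically show none.

## Statistics

- **Fisher exact (2×2, two-sided):** probability-mass rule — conditional on
  both margins, sum the hypergeometric probabilities of every table whose
  probability does not exceed the observed one (relative slack 10⁻⁷ on the
  comparison). All arithmetic is exact rational; a zero margin returns
  p = 1. This matches the default two-sided rule of the major statistics
  packages.
- **Kendall τ_b:** (C − D)/√((n₀ − T_x)(n₀ − T_y)) with tie corrections;
  two-tailed p from the tie-adjusted normal approximation of C − D (the
  study-scale n makes exact permutation unnecessary; an exact permutation
  p-value is available for n ≤ 10). Interpretation bands: |τ| < 0.3 low,
  0.3–0.7 moderate, > 0.7 high.
- **Kruskal–Wallis H** with midranks and the tie-correction divisor; p from
  χ² with k − 1 df. All-identical pooled data is an error (tie factor 0).
- **Mann–Whitney U:** midranks, reported as min(U_x, U_y); permutation-exact
  enumeration (valid under ties) when n_x + n_y ≤ 12, otherwise the
  tie-corrected normal approximation with a 0.5 continuity correction.
- Rank equality uses exact float comparison: inputs are measured scalars,
  not derived quantities, so no epsilon-tying is applied.
- Raw p-values are reported, mirroring the source analysis which applies no
  multiple-testing correction across its correlation table; an optional
  Benjamini–Hochberg column is available and clearly marked as an extra.
- Descriptive quartiles use linear interpolation (recorded in report
  metadata).

## Synthetic cohort model

One virtual patient = grade g ∈ {0..3} + side-specific truth (amplitude,
latency, TFA power) + morphometry scalars + an abnormality category.

**Draws.** Positive quantities are log-normal around the grade's configured
median — medians are then targeted exactly and positivity is guaranteed —
with log-scale sigmas 0.15 (grade-0 amplitudes; controls are a clinically
homogeneous group), 0.20 (amplitudes, grades 1–3), 0.25 (TFA), 0.10 (CCR).
Latency is normal (sd 2 ms) truncated to the epoch; MSCC is normal with
per-grade sd (0.4, 3, 6, 8) — within-grade spread grows with compression
severity. A single `dispersion_scale` multiplies every dispersion; at 0 all
draws collapse onto their targets (a calibration/debug mode in which the
category bands below are deliberately not enforced). Default group sizes
are 10/35/57/34 and default amplitude/latency medians follow the published
grade-wise medians. All samplers are inverse-CDF truncated distributions,
so no rejection loops.

**Categories.** Per grade, the category mixture defaults to the published
per-grade proportions (grade 1: 27/4/4/0 of A/B/C/D out of 35, etc.). By
default the mixture is apportioned exactly (largest remainder) across the
grade's patients; independent per-patient sampling is available
(`category_assignment="sample"`). Apportionment is the right default for a
generator whose purpose is to realise a configured composition: at n ≈ 34
multinomial noise makes the grade median amplitude bimodally unstable,
because the amplitude bands of adjacent categories are disjoint and the
median order statistics sit at a band edge.

**Category bands.** On the analysis side, draws are truncated to bands
consistent with the patient's category *relative to the expected control
mean* (the log-normal mean e^{σ²/2} × control median): amplitude-normal
patients sit at reduction ≤ 0.42, abnormal at ≥ 0.57; power-normal at loss
≤ 0.22, power-lost at ≥ 0.40. The margins absorb the sampling error of the
realised control-group mean (≈ 5–8% sd at n = 10) plus extraction noise, so
the classified categories reproduce the configured mixture with per-patient
flip probabilities at the percent level. The asymmetric amplitude margins
are a calibration: the abnormal-side edge also controls where the grade-2/3
median order statistics land, and 0.57 keeps those medians within 15% of
their targets while leaving a ≥ 0.07 classification margin.

**Waveform.** The epoch template is a Gabor atom — a 30 Hz cosine under a
Gaussian envelope centred at the true latency — rescaled so its *sampled*
peak-to-peak span equals the true amplitude exactly (extraction on the
noiseless template is therefore exact, and the latency lands on the nearest
sample). A Gabor rather than a derivative-of-Gaussian wavelet because its
spectral content stays at the carrier as the envelope width varies, and the
width is the lever that decouples spectral power from amplitude: the
envelope width is solved numerically (grid bracket 0.8–120 ms + Brent
refinement against the actual extractor) so the noiseless extracted region
power equals the patient's power target. Without that degree of freedom
power would be slaved to amplitude², and the clinically central
"amplitude abnormal without power loss" class could not exist. The
physiological reading: controls produce brief, synchronized peaks (narrow
envelope, low spectral energy per peak-to-peak), while compressed cords
produce temporally dispersed oscillatory responses that preserve spectral
power at reduced peak amplitude.

**TFA targets.** The attainable region power per amplitude² spans ≈ [0.13,
3.8] generator units across envelope widths; preserving ~80% of control
power at ≤ 43% of control amplitude (category B) therefore requires
controls near the low-efficiency end. The default TFA targets (right
4.20/2.81/2.17/2.45; left 3.97/2.94/2.48/2.56) preserve the published
grade-to-control *ratios* exactly while placing the absolute scale in that
feasible regime. Absolute published TFA values are not meaningful targets:
their printed unit is ambiguous and the published control-group mean and
median for the same quantity are mutually incompatible for any positive
distribution, so the generator is calibrated to be internally consistent —
the classification reference is the mean of its own control group — and
only relative power enters any decision.

**Noise.** Trials add Gaussian noise band-limited to the acquisition
bandpass (zero-phase 4th-order Butterworth; the post-filter sd is
renormalised to the configured value, default 0.2 µV per trial, 300 trials
per average). The residual ERP noise (≈ 0.012 µV) keeps two artefacts
small: the upward peak-picking bias of max − min extraction, and the
spectrogram signal×noise cross-term at the power decision cuts. Trial
counts per average are not published for the source setting; 300 is a
typical intraoperative figure and is configurable.

**Morphometry.** Adjacent-level diameters default to 8 mm (± 0.25 mm
jitter); the compressed AP diameter is solved from the MSCC draw and the
transverse diameter from the CCR draw, so recomputing the indices from the
emitted scalars recovers the truth exactly and re-grading recovers the
assigned grade (the occlusion fraction and deformation/signal flags are set
deterministically from the grade). Optional Gaussian measurement jitter can
be layered on the diameters.

**Determinism.** Every patient owns RNG streams seeded by (master seed,
grade, index-within-grade, stream), so cohorts are bit-reproducible and a
patient's draws are invariant to other grades' counts.

**Acquisition defaults.** 22 mA, 0.2 ms pulses at 2.66 stimuli/s, 100 ms
epochs, 10–500 Hz bandpass. The synthetic sampling rate is 2000 samples/s:
the clinically reported 200 Hz rate cannot carry a 500 Hz bandpass edge
(Nyquist), so the generator uses a rate consistent with the filter settings
and leaves both configurable.

## Pipeline

Stages exchange only on-disk artifacts (CSV/JSON/TSV) inside a run
directory: any stage can be re-run alone, and conforming epoch or
morphometry files from other producers slot in without code changes. The
report embeds the config hash, seed and package version — no timestamps or
paths — so identical (config, seed) yields byte-identical reports. When a
cohort contains no grade-0 patients the classifier falls back to the
configured control expectations and says so in the report. Logging is one
structured line per stage with output hashes.

## Problem sizes used in validation

The default test and acceptance runs use the study-sized cohort
(136 patients, 300 trials × 200 samples per side) for calibration checks,
and 12–16-patient cohorts for pipeline mechanics; the oracle suites run
~10³ random contingency tables (n ≤ 60) and 200 random vectors (n ≤ 200)
against brute-force enumeration.

## What the synthetic cohorts do not show

The generator reproduces configured medians, category mixtures and
grade-dependent monotone structure; it does not emulate real inter-feature
correlation fine structure, artifact regimes, anesthesia or temperature
effects, multi-segment lesions, or inter-rater variability of the human
grader. Passing tests therefore validate the analysis chain's correctness
and calibration on data with the assumed structure, not the clinical
performance of the thresholds on real recordings. Patient-level descriptive
tables and any learned feature-importance model from the source setting are
not reproducible without raw recordings and are out of scope.
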