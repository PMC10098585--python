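# Methods

This note documents the models, parameter choices and numerical decisions
behind `roma_ppg`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Signal model and preprocessing

The raw PPG sample sequence is modeled as a quasi-periodic pulse riding on
slow baseline drift, plus impulsive contact artifacts and broadband sensor
noise. Preprocessing separates these by time scale:

* **Moving-mean baseline (0.6 s, centered).** The systolic and diastolic
  features are < 0.3 s wide, so a 0.6 s mean suppresses them while tracking
  drift. The window in samples is `round(0.6 · fs)` (30 at 46.3 Hz, 18 at
  30 Hz); windows shrink at the record edges rather than padding, so no
  fabricated samples enter 10 s records. As an interior LTI filter the
  response is the Dirichlet kernel with first null at fs/L; subtracting the
  baseline is the complementary high-pass `δ − h`.
* **Low-pass at 3.5 Hz (210 BPM), steepness 0.8.** Minimum-order elliptic
  design with the stopband edge at `cutoff + (1 − steepness)(fs/2 − cutoff)`,
  0.25 dB ripple / 30 dB attenuation per pass, applied forward-backward
  (≤ 0.5 dB / ≥ 60 dB overall, zero phase). Zero-phase filtering is what
  lets the time-domain branch keep beat timing: peak positions shift only by
  a small constant from amplitude reshaping (the narrow systolic lobe blurs
  into the diastolic bump), which cancels in beat-to-beat differences.
* **Cadence notch (optional).** Stationary-bike pedaling at 50 RPM induces a
  narrowband artifact near 100 BPM. The band-stop is designed with passband
  edges at `center ± 0.6 · width` and stopband edges at `center ± 0.2 ·
  width` (elliptic, 0.4 dB / 16 dB per pass), i.e. ≥ 30 dB suppression at
  the artifact and < 1 dB loss 30 BPM away — a heart rate of 130 BPM
  survives while a 100 BPM artifact of comparable amplitude is removed. The
  notch is off by default and should be enabled only when a second spectral
  line near the cadence frequency is visible.
* **Moving-max normalization (trailing 0.5 s).** Pulse amplitude changes
  slowly, so the trailing maximum tracks the systolic height and `r = z/w`
  pins systolic peaks at +1. The divisor is floored at 0.25× the trailing
  2 s maximum: below ~70 BPM the 0.5 s window briefly loses the previous
  systolic peak, and without the floor the inter-beat quiet would be
  normalized up to noise level, creating spurious threshold crossings.
  The floor preserves scale invariance (it scales with the signal).

## Time-domain heart rate

Systolic peaks are local maxima of `r` above 0.5 with a 0.25 s refractory
separation (240 BPM ceiling, consistent with the 210 BPM low-pass edge).
Peak time is the time of the maximum sample — no sub-sample interpolation,
which keeps the estimator simple at the cost of quantizing each beat period
to the sample grid (≤ 33 ms at ≥ 30 Hz).

Instantaneous HR is 60 / (inter-peak period). Outliers are flagged beyond
3 scaled MADs (consistency factor 1.4826) of a centered 40-beat moving
median and replaced by the previous beat's cleaned value (window median for
a flagged first beat); flagged beats are additionally excluded from all
downstream statistics. Two numerical details matter:

* **Quantization floor.** Because periods are sample-quantized, a 40-beat
  window can hold > 50% of beats on one HR quantization level, making the
  local MAD exactly zero; the raw rule would then flag every off-level beat.
  The scale estimate is therefore floored at the quantization step
  `hr²/(60 fs)` — a one-level deviation is round-off, not an outlier. With
  the floor, clean records flag ≪ 0.1% of beats; heavily corrupted records
  flag 5–25% (the spurious beats caused by artifacts, as intended).
* **Replacement vs masking.** Replacement keeps the series well-defined for
  smoothing; masking keeps corrupted beats out of the reported statistics.

Smoothing is a centered mean over up to 40 beats (~30 s, matching the
spectrogram window), shrinking at the edges and skipping masked beats, with
one output per beat.

## Frequency-domain heart rate and line width

The spectrogram uses the drift-free signal `v` (not the low-passed `z`, so
the broadband signature of impulsive artifacts is preserved), 30 s Hamming
frames, `hop = 7.27 s` (the HR update interval; both configurable), and an
FFT zero-padded to the next power of two ≥ 4× the frame, so line-width
estimates resolve sub-bin variation. Each frame's power spectrum is
normalized to unit peak; slow amplitude changes therefore do not affect any
tracked quantity.

Per frame, the HR is 60× the argmax frequency within [40, 210] BPM — the
lower bound excludes respiratory peaks, the upper equals the low-pass edge.
Tracking is per-frame argmax only; no continuity constraint or harmonic
disambiguation is applied. The pulse's second harmonic is present but
weaker than the fundamental, so argmax stays on the fundamental for any
physiological pulse shape (verified down to 45 BPM, where the baseline
high-pass attenuates the fundamental most).

**Line width** is measured at half of the in-band peak power (the standard
half-maximum convention, on the linear power scale): the width is the
frequency extent between the outermost half-maximum crossings inside the
search band, with the two crossings linearly interpolated on the padded
grid. For clean signal this region is the single mainlobe around the HR
line (~2–3 BPM at 30 s windows). A frame carrying a contact-loss impulse
has nearly white extra power; interference between the loss/re-contact
edges ripples that streak, so above-half-maximum power appears *dispersed
across the band* rather than as one wide contiguous lobe — the extent
measure captures exactly this dispersal (tens of BPM), whereas the width of
the contiguous lobe around the peak would stay narrow and miss the
corruption entirely. The width level (0.5) is the single most consequential
free parameter: raising it shrinks all widths and lowers STD-width roughly
proportionally, so re-derived cut points should always be paired with the
width level used.

For ~10 s records (smartphone datasets) a 2.5 s window with a 0.6 s hop is
used instead (`PipelineConfig.short_record()`), giving ≥ 12 frames per
record at the cost of 24 BPM spectral resolution.

## Quality indices and classification

*Self-consistency* = 100 × fraction of beat-aligned points (frequency-domain
HR interpolated to the systolic time stamps; masked beats excluded) with
|HR_time − HR_freq| ≤ 10 BPM. *STD-width* = sample standard deviation
(n − 1) of the per-frame line width in BPM.

A record is **adequate** iff self-consistency > 30 **and** STD-width < 10
(strict inequalities; boundary values classify poor). Failing either index
marks the record poor — the conservative choice; on real data the two
indices are strongly collinear, so the conjunction/disjunction distinction
rarely binds. ROC-based cut-point discovery maximizes
min(sensitivity, specificity), breaking ties by Youden's J and then by the
smaller threshold, treating *poor* as the positive class.

## Agreement statistics

RMSE is computed with a 1/(n−1) denominator by default — the convention of
the validation literature this package accompanies — with the standard 1/n
form behind `rmse_denominator="n"`. MAE% normalizes by the reference, so it
is not symmetric under swapping reference and estimate. Correlation
intervals are Fisher-z confidence intervals and are labeled as such.
Cohen's kappa uses the Landis–Koch interpretation scale (0.81–1.00 =
almost perfect); when both raters are constant and identical, chance
agreement is 1 and kappa is defined as 1.0 with a warning.

## Synthetic-data generator

The generator emulates a chest-mounted sensor during a 20-minute
stationary-bike session at an effective 46.3 Hz (the default; duration, rate
and trajectory are configurable):

* **Pulse template**: wrapped Gaussians — narrow systolic lobe (σ = 0.05 of
  the period, peak +1 at phase 0.15), diastolic bump (0.20 at phase 0.40),
  and a broad undershoot placed right after the diastolic wave whose depth
  and width are solved so the template has min ≈ −0.5 (the asymmetry
  parameter) and exactly zero mean. The placement keeps the second-harmonic
  amplitude at ~0.15 of the fundamental, so the spectral argmax stays on
  the fundamental even after the baseline high-pass, which amplifies the
  harmonic relative to the fundamental at low heart rates.
* **HR trajectory**: constant, sinusoid, or the bike protocol (50% rest at
  ~72 BPM, 10% pedaling to ~125, 15% ramp to ~155, 25% recovery to ~88,
  first-order-smoothed with τ = 30 s to emulate physiological response lag).
  Trajectories are confined to [45, 200] BPM.
* **Heart-rate variability**: respiratory sinus arrhythmia (1.5 BPM at
  0.25 Hz) plus two Mayer-wave-band components (1.2 BPM at ~0.05/0.1 Hz).
  Real beat sequences always carry this variability; without it, beat
  periods lock to the sample grid and the outlier detector's MAD collapses.
  The reported ground truth is the underlying trajectory (the 30 s-scale
  mean both estimators recover), not the beat-scale HRV.
* **Drift**: three random-phase sinusoids below 0.3 Hz with total amplitude
  ~2× the pulse — band-limited below the baseline filter's first null by
  construction.
* **Contact loss**: Poisson-scheduled events (rate in events/s); during an
  exponential-length gap (mean 2 s) the optical pulse vanishes and the
  baseline steps by ~10× the pulse amplitude; on re-contact the offset
  decays with τ = 0.5 s. The gating and step edges are the impulsive,
  nearly-white-spectrum mechanism behind the spectrogram streaks.
* **Cadence tone** (optional) at 100 BPM and white noise (σ = 0.05 pulse
  amplitudes). At cadence amplitude ≈ 0.5 the tone and the pulse
  fundamental have nearly equal spectral amplitude (the capture crossover);
  the artifact-capture and notch-recovery demonstrations use 0.8, where the
  artifact dominates every frame.

Everything is deterministic given the seed. What the generator does *not*
model: pulse-morphology changes with posture or vascular tone, sensor
saturation, skin-tone-dependent SNR, ECG reference noise, and non-Poisson
(e.g. movement-correlated) artifact timing. Passing tests therefore show
the pipeline's behavior under the stated signal model, not performance
bounds for any particular hardware.

## Test problem sizes

The test suite runs in a few seconds on one CPU: dose-response uses
5-minute records (4 rates × 10 seeds), parameter recovery uses 20 full
20-minute bike sessions, and oracle-equivalence checks use 100 random
instances per statistic at 1e-10 agreement. One acceptance test reproduces
annotation and poor-count figures on a public smartphone PPG dataset and
can only run when that dataset has been downloaded to `data/but-ppg/`.

## Known limitations

* Per-frame argmax tracking has no continuity prior; a strong narrowband
  artifact inside the search band captures frames (by design — that is what
  self-consistency detects) until notched out.
* Line width on a linear power scale at level 0.5 was chosen as the standard
  convention; dB-scale widths would change the STD-width magnitudes and cut
  points together.
* Peak times are sample-quantized; at 30 Hz and 180 BPM the per-beat HR
  quantization reaches ~20 BPM, which the 40-beat smoothing, not the beat
  detector, absorbs.
* The WFDB reader covers header + signal formats 16/80/212, single-segment
  records only.
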