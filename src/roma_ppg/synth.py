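"""Synthetic PPG generator with ground-truth HR and controllable artifacts.

The generator emulates the features of chest-mounted PPG that the pipeline
and both quality indices are sensitive to:

* an asymmetric quasi-periodic pulse: a narrow systolic lobe peaking at +1,
  a small diastolic bump, and a negative undershoot near −0.5 of the
  systolic swing (zero-mean over one period);
* beat-to-beat heart-rate variability: respiratory sinus arrhythmia as a
  sinusoidal modulation (default 1.5 BPM at 0.25 Hz), without which beat
  periods would be unrealistically locked to the sample grid;
* slow non-periodic baseline drift (breathing, sweating, adhesive tension):
  a sum of three random-phase sinusoids band-limited below 0.3 Hz, safely
  under the moving-mean filter's first null;
* impulsive contact-loss artifacts: Poisson-scheduled events during which
  optical coupling is lost — the pulse signal vanishes for the gap, the
  baseline steps by ~10x the pulse amplitude, and on re-contact the offset
  re-baselines exponentially (tau = 0.5 s).  The sharp edges are nearly
  white in frequency and produce the broadband spectrogram streaks that the
  STD-width index detects;
* an optional narrowband pedaling-cadence tone near 100 BPM;
* additive white sensor noise.

The default condition mirrors a 20 min stationary-bike session sampled at
an effective 46.3 Hz: 10 min seated rest, 2 min pedaling at moderate
effort, 3 min at increasing resistance, 5 min recovery, with the heart-rate
trajectory low-pass filtered (tau = 30 s) to emulate physiological response
lag.  Ground-truth HR is emitted at 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError, RomaError
from .signal_io import HRSeries, PPGRecord, write_hr_csv, write_ppg_csv

__all__ = ["ConstantHR", "SinusoidHR", "BikeProtocolHR", "SynthConfig", "SynthRecord",
           "pulse_waveform", "generate", "make_fixture_suite"]

HR_MIN, HR_MAX = 45.0, 200.0


# ---------------------------------------------------------------------------
# heart-rate trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantHR:
    bpm: float = 70.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(t, dtype=float), self.bpm)


@dataclass(frozen=True)
class SinusoidHR:
    mean: float = 90.0
    amp: float = 10.0
    period_s: float = 120.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.mean + self.amp * np.sin(2 * np.pi * t / self.period_s)


@dataclass(frozen=True)
class BikeProtocolHR:
    """Rest -> pedal -> ramp -> recovery, scaled to the record duration.

    Segment fractions follow a 20 min session: 50% seated rest, 10% steady
    pedaling, 15% increasing resistance up to the peak, 25% recovery.  The
    piecewise-linear target is smoothed with a first-order response
    (tau = 30 s) so HR changes at physiological rates.
    """

    rest_bpm: float = 72.0
    moderate_bpm: float = 125.0
    peak_bpm: float = 155.0
    recovery_bpm: float = 88.0
    response_tau_s: float = 30.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        duration = float(t[-1]) if t.size else 0.0
        breaks = np.array([0.0, 0.5, 0.6, 0.75, 1.0]) * max(duration, 1e-9)
        levels = [self.rest_bpm, self.rest_bpm, self.moderate_bpm,
                  self.peak_bpm, self.recovery_bpm]
        # dense 1 Hz target, smoothed, then sampled at t
        grid = np.arange(0.0, duration + 1.0, 1.0)
        target = np.interp(grid, breaks, levels)
        smooth = np.empty_like(target)
        alpha = 1.0 / max(self.response_tau_s, 1.0)
        smooth[0] = target[0]
        for i in range(1, target.size):
            smooth[i] = smooth[i - 1] + alpha * (target[i] - smooth[i - 1])
        return np.interp(t, grid, smooth)


# ---------------------------------------------------------------------------
# pulse template
# ---------------------------------------------------------------------------

_SYSTOLIC_CENTER = 0.15
_TEMPLATE_CACHE: dict = {}


def _circ(p: np.ndarray, center: float) -> np.ndarray:
    d = np.abs(p - center)
    return np.minimum(d, 1.0 - d)


def _template_params(asymmetry: float):
    """Solve the undershoot depth/width so the template is zero-mean with min ~ -asymmetry."""
    key = round(float(asymmetry), 6)
    if key in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[key]
    grid = np.linspace(0.0, 1.0, 4096, endpoint=False)
    g = (np.exp(-0.5 * (_circ(grid, _SYSTOLIC_CENTER) / 0.05) ** 2)
         + 0.20 * np.exp(-0.5 * (_circ(grid, 0.40) / 0.06) ** 2))
    mean_g = float(np.mean(g))
    # undershoot: wrapped Gaussian right after the diastolic wave; width chosen
    # so that depth k equals the requested asymmetry while exactly cancelling the
    # positive mean (the placement keeps the 2nd harmonic well below the
    # fundamental even after the moving-mean high-pass, as in real pulses)
    sigma_u = mean_g / (max(asymmetry, 1e-6) * np.sqrt(2 * np.pi))
    u = np.exp(-0.5 * (_circ(grid, 0.65) / sigma_u) ** 2)
    k = mean_g / float(np.mean(u))
    f = g - k * u
    scale = float(np.max(f))
    params = (sigma_u, k, scale)
    _TEMPLATE_CACHE[key] = params
    return params


def pulse_waveform(phase, asymmetry: float = 0.5) -> np.ndarray:
    """One-period PPG pulse template evaluated at phase in [0, 1).

    Peak value is exactly 1 at the systolic center (phase 0.15); the
    diastolic bump stays below 0.2; the undershoot reaches about
    ``-asymmetry``; the template integrates to ~0 over a period so it
    carries no DC.
    """
    p = np.mod(np.asarray(phase, dtype=float), 1.0)
    sigma_u, k, scale = _template_params(asymmetry)
    f = (np.exp(-0.5 * (_circ(p, _SYSTOLIC_CENTER) / 0.05) ** 2)
         + 0.20 * np.exp(-0.5 * (_circ(p, 0.40) / 0.06) ** 2)
         - k * np.exp(-0.5 * (_circ(p, 0.65) / sigma_u) ** 2))
    return f / scale


# ---------------------------------------------------------------------------
# record generation
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    fs: float = 46.3
    duration_s: float = 1200.0
    hr_trajectory: object = field(default_factory=BikeProtocolHR)
    pulse_asymmetry: float = 0.5
    hrv_amp: float = 1.5             # BPM, respiratory sinus arrhythmia amplitude
    breath_hz: float = 0.25          # breathing rate driving the HRV modulation
    hrv_lf_amp: float = 1.2          # BPM, low-frequency (Mayer-wave band) HRV amplitude
    drift_amp: float = 2.0           # pulse-amplitude units, peak scale of the drift
    drift_band: float = 0.3          # Hz, upper edge of drift sinusoid frequencies
    contact_loss_rate: float = 0.0   # events / s (Poisson)
    contact_loss_amp: float = 10.0   # multiple of pulse amplitude
    contact_loss_tau_s: float = 0.5  # exponential re-baseline time constant
    contact_loss_duration_s: float = 2.0  # mean gap length while contact is lost
    cadence_bpm: Optional[float] = None
    cadence_amp: float = 0.5         # fraction of pulse amplitude
    noise_sd: float = 0.05
    seed: int = 0

    def summary(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "hr_trajectory"}
        d["hr_trajectory"] = {"kind": type(self.hr_trajectory).__name__,
                              **vars(self.hr_trajectory)}
        return d


@dataclass
class SynthRecord:
    record: PPGRecord
    truth_hr: HRSeries
    artifact_log: list  # (onset_s, duration_s, kind)


def generate(config: SynthConfig) -> SynthRecord:
    """Generate one synthetic PPG record; deterministic given ``config.seed``.

    The instantaneous phase integrates the HR trajectory, the pulse template
    is evaluated on it, and drift, contact-loss transients, the optional
    cadence tone and white noise are added.  Samples are emitted in
    ADC-like sensor units (pulse amplitude 100, offset 512) so that the
    pipeline's normalization stages do real work.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    if n < 2:
        raise ConfigurationError("duration too short")
    t = np.arange(n) / config.fs
    hr_t = np.asarray(config.hr_trajectory(t), dtype=float)
    if np.any(hr_t < HR_MIN) or np.any(hr_t > HR_MAX):
        raise ConfigurationError(
            f"HR trajectory leaves the physiological band [{HR_MIN}, {HR_MAX}] BPM")

    # beat-to-beat variability: respiratory sinus arrhythmia plus two
    # Mayer-wave-band components; nuisance realism, not part of the truth HR
    hr_inst = hr_t + config.hrv_amp * np.sin(
        2 * np.pi * config.breath_hz * t + rng.uniform(0, 2 * np.pi))
    for f_lf in (0.052, 0.095):
        hr_inst += config.hrv_lf_amp * np.sin(2 * np.pi * f_lf * t + rng.uniform(0, 2 * np.pi))
    phase = np.cumsum(hr_inst / 60.0) / config.fs + rng.uniform(0.0, 1.0)
    clean = pulse_waveform(phase, config.pulse_asymmetry)

    drift = np.zeros(n)
    for _ in range(3):
        f = rng.uniform(0.04, config.drift_band)
        a = config.drift_amp * rng.uniform(0.2, 0.5)
        drift += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))

    artifact_log = []
    offsets = np.zeros(n)
    coupled = np.ones(n)  # optical coupling: 0 while skin contact is lost
    if config.contact_loss_rate > 0:
        n_events = rng.poisson(config.contact_loss_rate * config.duration_s)
        onsets = np.sort(rng.uniform(0.0, config.duration_s, n_events))
        for onset in onsets:
            dur = float(np.clip(rng.exponential(config.contact_loss_duration_s), 0.3, 8.0))
            sign = rng.choice([-1.0, 1.0])
            amp = config.contact_loss_amp * rng.uniform(0.5, 1.0)
            gap = (t >= onset) & (t < onset + dur)
            coupled[gap] = 0.0
            offsets[gap] += sign * amp
            after = t >= onset + dur
            offsets[after] += sign * amp * np.exp(-(t[after] - onset - dur)
                                                  / config.contact_loss_tau_s)
            artifact_log.append((float(onset), dur, "contact_loss"))

    cadence = np.zeros(n)
    if config.cadence_bpm is not None:
        cadence = config.cadence_amp * np.sin(
            2 * np.pi * (config.cadence_bpm / 60.0) * t + rng.uniform(0, 2 * np.pi))
        artifact_log.append((0.0, config.duration_s, "cadence"))

    noise = rng.normal(0.0, config.noise_sd, n)
    samples = 100.0 * ((clean + cadence) * coupled + drift + offsets + noise) + 512.0

    truth_times = np.arange(0.0, config.duration_s, 1.0)
    truth = HRSeries(truth_times, np.asarray(config.hr_trajectory(truth_times), float),
                     source="reference")
    record = PPGRecord(samples=samples, fs=config.fs,
                       record_id=f"synth-{config.seed}", reference_hr=truth)
    return SynthRecord(record=record, truth_hr=truth, artifact_log=artifact_log)


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------

def _fixture_configs(seed: int) -> list:
    base = seed * 1000
    return [
        ("clean-constant", "good",
         SynthConfig(duration_s=300.0, hr_trajectory=ConstantHR(72.0), seed=base + 1)),
        ("clean-sinusoid", "good",
         SynthConfig(duration_s=300.0, hr_trajectory=SinusoidHR(90.0, 10.0, 120.0), seed=base + 2)),
        ("clean-bike", "good",
         SynthConfig(duration_s=600.0, seed=base + 3)),
        ("marginal-cadence", "good",
         SynthConfig(duration_s=300.0, hr_trajectory=ConstantHR(75.0),
                     cadence_bpm=100.0, cadence_amp=0.4, seed=base + 4)),
        ("corrupted-moderate", "poor",
         SynthConfig(duration_s=300.0, hr_trajectory=ConstantHR(80.0),
                     contact_loss_rate=0.2, seed=base + 5)),
        ("corrupted-severe", "poor",
         SynthConfig(duration_s=300.0, contact_loss_rate=0.3, seed=base + 6)),
    ]


def make_fixture_suite(out_dir, seed: int = 0) -> list:
    """Write a deterministic suite of fixture records spanning quality conditions.

    Produces, per fixture, a PPG CSV in the package dialect and a 1 Hz truth
    HR CSV, plus a ``manifest.yaml`` listing paths, designed quality labels
    and generator settings.  Re-running with the same seed reproduces every
    file byte for byte.  Returns the list of written paths.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise RomaError(f"cannot create fixture directory {out_dir}: {exc}") from exc

    written = []
    manifest = {"version": 1, "seed": seed, "records": []}
    for name, label, cfg in _fixture_configs(seed):
        synth = generate(cfg)
        rec_path = out_dir / f"{name}.csv"
        truth_path = out_dir / f"{name}-truth.csv"
        write_ppg_csv(synth.record, rec_path)
        write_hr_csv(synth.truth_hr, truth_path)
        written += [rec_path, truth_path]
        manifest["records"].append({
            "id": name,
            "record": rec_path.name,
            "truth": truth_path.name,
            "label": label,
            "config": cfg.summary(),
        })
    man_path = out_dir / "manifest.yaml"
    with open(man_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    written.append(man_path)
    return written
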