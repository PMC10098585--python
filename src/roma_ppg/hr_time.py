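"""Beat-by-beat heart rate from the normalized pulse signal.

Systolic peaks are local maxima of the unit-normalized signal exceeding a
0.5 height threshold (diastolic peaks sit near 0 or below and are rejected
by the threshold alone).  Inter-beat periods T0_k give instantaneous HR
HR_k = 60 / T0_k in BPM; impulsive artifacts produce isolated nonsense
beats, which are flagged by a 40-beat moving-median / scaled-MAD rule,
replaced by the previous beat's value, and excluded from downstream
statistics.  A centered 40-beat (~30 s) moving mean then yields a smooth HR
emitted at every beat, matching the time resolution of the spectral branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DataError
from .signal_io import HRSeries

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates a normal sigma

__all__ = [
    "BeatTrain",
    "detect_systolic_peaks",
    "instantaneous_hr",
    "replace_outliers",
    "smooth_hr",
    "extract_beats",
]


@dataclass
class BeatTrain:
    """Detected beats and derived HR sequences.

    ``periods``, ``inst_hr``, ``smoothed_hr`` and ``outlier_mask`` all have
    length ``len(peak_times) - 1``: the k-th entry belongs to the interval
    ending at ``peak_times[k+1]``.
    """

    peak_times: np.ndarray
    periods: np.ndarray
    inst_hr: np.ndarray
    smoothed_hr: np.ndarray
    outlier_mask: np.ndarray

    @property
    def outlier_fraction(self) -> float:
        return float(np.mean(self.outlier_mask)) if self.outlier_mask.size else 0.0

    def hr_series(self) -> HRSeries:
        """Smoothed time-domain HR stamped at each beat (interval end) time."""
        return HRSeries(self.peak_times[1:], self.smoothed_hr, source="time_domain")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beat_index": np.arange(1, self.peak_times.size),
            "time_s": self.peak_times[1:],
            "period_s": self.periods,
            "inst_hr": self.inst_hr,
            "outlier": self.outlier_mask,
            "smoothed_hr": self.smoothed_hr,
        })


def detect_systolic_peaks(r, fs: float, threshold: float = 0.5,
                          min_separation_s: float = 0.25, t0: float = 0.0) -> np.ndarray:
    """Times (s) of local maxima of ``r`` above ``threshold``.

    Peaks closer than ``min_separation_s`` are resolved in favour of the
    larger one; 0.25 s corresponds to a 240 BPM physiological ceiling and
    prevents double-counting a single systolic upstroke.  Returns an empty
    array (with a warning) when nothing crosses the threshold.
    """
    r = np.asarray(r, dtype=float)
    distance = max(1, int(round(min_separation_s * fs)))
    idx, _ = sps.find_peaks(r, height=threshold, distance=distance)
    if idx.size == 0:
        logger.warning("no systolic peaks found above threshold %.2f", threshold)
        return np.array([], dtype=float)
    return t0 + idx / fs


def instantaneous_hr(peak_times):
    """Successive-difference periods and instantaneous HR = 60 / period (BPM)."""
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        raise DataError("need at least 2 peaks for instantaneous HR")
    periods = np.diff(peak_times)
    if np.any(periods <= 0):
        raise DataError("peak times must be strictly increasing")
    return periods, 60.0 / periods


def _rolling_mad(s: pd.Series, window: int) -> np.ndarray:
    def mad(w: np.ndarray) -> float:
        return float(np.median(np.abs(w - np.median(w))))
    return s.rolling(window, center=True, min_periods=1).apply(mad, raw=True).to_numpy()


def replace_outliers(inst_hr, window_beats: int = 40, n_mads: float = 3.0,
                     fs: Optional[float] = None):
    """Flag and replace impulsive HR outliers.

    A beat is an outlier when it lies more than ``n_mads`` scaled MADs
    (scale 1.4826) from the median of its centered ``window_beats`` window.
    Flagged beats are replaced by the previous beat's cleaned value (the
    window median for a flagged first beat) and recorded in a mask so that
    downstream statistics can exclude them.  Returns ``(cleaned, mask)``.

    When ``fs`` is given, the local scale estimate is floored at the HR
    timing-quantization step ``hr^2 / (60 fs)`` (peak times live on the
    sample grid, so a one-step deviation is round-off, not an outlier;
    without the floor a zero-MAD window would flag every beat off the modal
    quantization level).
    """
    inst_hr = np.asarray(inst_hr, dtype=float)
    if inst_hr.size == 0:
        raise DataError("empty HR sequence")
    if window_beats < 3:
        raise DataError("window_beats must be >= 3")
    s = pd.Series(inst_hr)
    med = s.rolling(window_beats, center=True, min_periods=1).median().to_numpy()
    mad = _rolling_mad(s, window_beats)
    scale = MAD_SCALE * mad
    if fs is not None:
        scale = np.maximum(scale, med ** 2 / (60.0 * fs))
    mask = np.abs(inst_hr - med) > n_mads * scale
    if np.all(mask):
        raise DataError("every beat flagged as an outlier; signal unusable")
    cleaned = inst_hr.copy()
    for i in np.flatnonzero(mask):
        cleaned[i] = cleaned[i - 1] if i > 0 else med[0]
    return cleaned, mask


def smooth_hr(cleaned_hr, window_beats: int = 40, outlier_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Centered moving mean over up to ``window_beats`` beats, one value per beat.

    Windows shrink at the sequence edges, and beats marked in
    ``outlier_mask`` are excluded from every window's average (a window with
    no valid beat falls back to the beat's own value).  40 beats is about
    30 s at rest, matching the spectrogram window.
    """
    hr = np.asarray(cleaned_hr, dtype=float)
    if hr.size == 0:
        raise DataError("empty HR sequence")
    valid = np.ones(hr.size, dtype=bool) if outlier_mask is None else ~np.asarray(outlier_mask, bool)
    half_l = (window_beats - 1) // 2
    half_r = window_beats // 2
    csum_v = np.concatenate(([0.0], np.cumsum(hr * valid)))
    csum_n = np.concatenate(([0.0], np.cumsum(valid.astype(float))))
    idx = np.arange(hr.size)
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r + 1, hr.size)
    num = csum_v[hi] - csum_v[lo]
    den = csum_n[hi] - csum_n[lo]
    out = np.where(den > 0, num / np.maximum(den, 1.0), hr)
    return out


def extract_beats(r, fs: float, threshold: float = 0.5, min_separation_s: float = 0.25,
                  window_beats: int = 40, n_mads: float = 3.0, t0: float = 0.0) -> BeatTrain:
    """Full time-domain chain: peaks -> instantaneous HR -> outliers -> smoothing."""
    peaks = detect_systolic_peaks(r, fs, threshold, min_separation_s, t0)
    if peaks.size < 2:
        raise DataError("fewer than 2 systolic peaks detected")
    periods, inst = instantaneous_hr(peaks)
    cleaned, mask = replace_outliers(inst, window_beats, n_mads, fs=fs)
    smoothed = smooth_hr(cleaned, window_beats, mask)
    frac = float(np.mean(mask))
    logger.info("extracted %d beats, %.3f%% flagged as outliers", peaks.size, 100 * frac)
    return BeatTrain(peak_times=peaks, periods=periods, inst_hr=inst,
                     smoothed_hr=smoothed, outlier_mask=mask)
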