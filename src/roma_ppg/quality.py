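"""The two ROMA signal-quality indices and cut-point discovery.

Self-consistency: time-domain (beat counting) and frequency-domain
(spectrogram) HR estimates agree on clean signal but diverge under
corruption; the index is the percentage of beat-aligned points where the
two agree within 10 BPM.

STD-width: impulsive contact-loss artifacts smear the spectral HR line into
broad streaks whose width fluctuates frame to frame; the index is the
sample standard deviation of the per-frame line width, in BPM.

A record is classified *adequate* when self-consistency exceeds its cut
point AND STD-width stays below its cut point (defaults 30 and 10); failing
either index marks the record poor.  Cut points can be re-derived from
labeled data by ROC analysis, choosing the threshold that balances
sensitivity and specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

from .errors import DataError
from .hr_freq import SpectralTrack
from .signal_io import HRSeries

logger = logging.getLogger(__name__)

__all__ = ["QualityMetrics", "CutpointResult", "self_consistency", "std_width",
           "classify_quality", "assess_quality", "roc_cutpoint"]


@dataclass
class QualityMetrics:
    self_consistency: float  # percent in [0, 100]
    std_width: float         # BPM
    label: str               # "adequate" | "poor"
    n_compared_points: int

    def to_dict(self) -> dict:
        return {"self_consistency": self.self_consistency, "std_width": self.std_width,
                "label": self.label, "n_compared_points": self.n_compared_points}


@dataclass
class CutpointResult:
    metric_name: str
    threshold: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: list = field(default_factory=list)  # (fpr, tpr) pairs


def self_consistency(hr_time: HRSeries, hr_freq: HRSeries, tol_bpm: float = 10.0,
                     outlier_mask=None) -> float:
    """Percentage of beat-aligned points where the two HR estimates agree.

    Both series must already sit on the same time grid (interpolate the
    frequency-domain series to the beat stamps first).  Agreement is
    ``|hr_time − hr_freq| <= tol_bpm`` (inclusive); beats flagged as
    outliers are excluded from the count.
    """
    if len(hr_time) != len(hr_freq) or not np.allclose(hr_time.times, hr_freq.times):
        raise DataError("HR series are on different time grids; align first")
    diff = np.abs(hr_time.hr - hr_freq.hr)
    if outlier_mask is not None:
        keep = ~np.asarray(outlier_mask, dtype=bool)
        if keep.size != diff.size:
            raise DataError("outlier mask length does not match the series")
        diff = diff[keep]
    if diff.size == 0:
        raise DataError("no points left to compare")
    return float(100.0 * np.mean(diff <= tol_bpm))


def std_width(track: SpectralTrack) -> float:
    """Sample standard deviation (n−1) of the spectral line width, in BPM."""
    if track.line_width is None:
        raise DataError("run track_peak_and_width first")
    if track.line_width.size < 2:
        raise DataError("need at least 2 frames for a standard deviation")
    return float(np.std(track.line_width, ddof=1))


def classify_quality(sc: float, sw: float, sc_cut: float = 30.0, width_cut: float = 10.0) -> str:
    """Adequate iff sc > sc_cut and sw < width_cut (strict; boundaries are poor)."""
    return "adequate" if (sc > sc_cut and sw < width_cut) else "poor"


def assess_quality(hr_time: HRSeries, hr_freq: HRSeries, track: SpectralTrack,
                   tol_bpm: float = 10.0, sc_cut: float = 30.0, width_cut: float = 10.0,
                   outlier_mask=None) -> QualityMetrics:
    """Compute both indices and the binary label for one record."""
    sc = self_consistency(hr_time, hr_freq, tol_bpm, outlier_mask)
    sw = std_width(track)
    n = len(hr_time) if outlier_mask is None else int(np.sum(~np.asarray(outlier_mask, bool)))
    return QualityMetrics(self_consistency=sc, std_width=sw,
                          label=classify_quality(sc, sw, sc_cut, width_cut),
                          n_compared_points=n)


def _as_good_bool(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind == "O" and labels.size and isinstance(labels.flat[0], str):
        labels = labels.astype(str)
    if labels.dtype.kind in "US":
        bad = set(np.unique(labels)) - {"good", "poor"}
        if bad:
            raise DataError(f"labels must be 'good'/'poor', got {sorted(bad)}")
        return labels == "good"
    return labels.astype(bool)


def roc_cutpoint(scores, labels, direction: str = "higher_is_good",
                 metric_name: str = "") -> CutpointResult:
    """ROC analysis of a quality index against binary good/poor labels.

    The positive class is *poor* (the event being detected).  ``direction``
    states which way the index points: ``higher_is_good`` (self-consistency)
    or ``higher_is_poor`` (STD-width).  The chosen threshold maximizes
    min(sensitivity, specificity), with ties broken by larger Youden's J and
    then by smaller threshold; it is reported on the original score scale.
    """
    scores = np.asarray(scores, dtype=float)
    good = _as_good_bool(labels)
    if scores.size != good.size or scores.size < 2:
        raise DataError("scores and labels must be equal-length, n >= 2")
    if good.all() or (~good).all():
        raise DataError("ROC analysis needs both classes present")
    if direction not in ("higher_is_good", "higher_is_poor"):
        raise DataError(f"unknown direction {direction!r}")
    y_poor = ~good
    score_poor = -scores if direction == "higher_is_good" else scores
    fpr, tpr, thresholds = skm.roc_curve(y_poor, score_poor)
    auc = float(skm.auc(fpr, tpr))

    sens, spec = tpr, 1.0 - fpr
    # skip the sentinel first threshold (inf); evaluate real operating points
    cand = np.arange(1, thresholds.size)
    balance = np.minimum(sens[cand], spec[cand])
    youden = sens[cand] + spec[cand] - 1.0
    orig_thr = -thresholds[cand] if direction == "higher_is_good" else thresholds[cand]
    order = np.lexsort((orig_thr, -youden, -balance))
    best = cand[order[0]]
    threshold = float(-thresholds[best]) if direction == "higher_is_good" else float(thresholds[best])
    return CutpointResult(metric_name=metric_name, threshold=threshold,
                          sensitivity=float(sens[best]), specificity=float(spec[best]),
                          auc=auc, roc_points=list(zip(fpr.tolist(), tpr.tolist())))
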