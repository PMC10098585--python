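"""Agreement and association statistics against a reference HR.

Error metrics follow the conventions used throughout this line of work:

    RMSE    = sqrt( sum (x_i − y_i)^2 / (n − 1) )
    MAE     = mean |x_i − y_i|
    MAE(%)  = 100 · mean( |x_i − y_i| / x_i )
    accuracy = percentage of points with |x_i − y_i| <= 5 BPM

with x the reference (ECG/telemetry) and y the PPG estimate at aligned
time points.  Note the RMSE uses an n−1 denominator; the conventional 1/n
form is available via ``rmse_denominator="n"``.

Also provided: point-biserial correlation (Pearson on a 0/1 coding),
Cohen's kappa with its Landis–Koch interpretation band, Welch's unequal-
variance t-test, and Fisher-z confidence intervals for Pearson
correlations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import cohen_kappa_score

from .errors import DataError
from .signal_io import HRSeries

logger = logging.getLogger(__name__)

__all__ = ["AgreementStats", "error_metrics", "point_biserial", "cohens_kappa",
           "landis_koch_band", "welch_t", "pearson_with_ci"]


@dataclass
class AgreementStats:
    rmse: float
    mae: float
    mae_pct: float
    accuracy5: float
    n: int

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "mae_pct": self.mae_pct,
                "accuracy5": self.accuracy5, "n": self.n}


def error_metrics(reference: HRSeries, estimate: HRSeries, tol_bpm: float = 5.0,
                  outlier_mask=None, rmse_denominator: str = "n-1") -> AgreementStats:
    """RMSE / MAE / MAE% / accuracy-within-``tol_bpm`` on aligned series.

    Both series must share a time grid; beats flagged in ``outlier_mask``
    are excluded.  MAE% divides by the reference, so reference values must
    be positive (guaranteed by HRSeries).
    """
    if len(reference) != len(estimate) or not np.allclose(reference.times, estimate.times):
        raise DataError("series are on different time grids; align first")
    x = reference.hr.copy()
    y = estimate.hr.copy()
    if outlier_mask is not None:
        keep = ~np.asarray(outlier_mask, dtype=bool)
        if keep.size != x.size:
            raise DataError("outlier mask length mismatch")
        x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise DataError("need at least 2 aligned points")
    d = x - y
    if rmse_denominator == "n-1":
        rmse = math.sqrt(float(np.sum(d ** 2)) / (n - 1))
    elif rmse_denominator == "n":
        rmse = math.sqrt(float(np.mean(d ** 2)))
    else:
        raise DataError("rmse_denominator must be 'n-1' or 'n'")
    mae = float(np.mean(np.abs(d)))
    mae_pct = float(100.0 * np.mean(np.abs(d) / x))
    accuracy5 = float(100.0 * np.mean(np.abs(d) <= tol_bpm))
    return AgreementStats(rmse=rmse, mae=mae, mae_pct=mae_pct, accuracy5=accuracy5, n=int(n))


def point_biserial(binary, continuous) -> float:
    """Point-biserial correlation: Pearson r between a 0/1 variable and a continuous one."""
    binary = np.asarray(binary, dtype=float)
    continuous = np.asarray(continuous, dtype=float)
    if binary.size != continuous.size:
        raise DataError("unequal lengths")
    if np.unique(binary).size < 2:
        raise DataError("binary variable has a single class")
    return float(sstats.pointbiserialr(binary, continuous).statistic)


def landis_koch_band(kappa: float) -> str:
    """Landis–Koch interpretation of a kappa value."""
    if kappa <= 0:
        return "poor agreement"
    if kappa <= 0.20:
        return "slight agreement"
    if kappa <= 0.40:
        return "fair agreement"
    if kappa <= 0.60:
        return "moderate agreement"
    if kappa <= 0.80:
        return "substantial agreement"
    return "almost perfect agreement"


def cohens_kappa(labels_a, labels_b):
    """Chance-corrected agreement between two binary raters.

    Returns ``(kappa, band)`` where band is the Landis–Koch interpretation.
    When both raters are constant and identical the chance agreement p_e is
    1 and kappa is defined as 1.0 (with a warning).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size or a.size < 1:
        raise DataError("label vectors must be equal-length and non-empty")
    if np.unique(a).size == 1 and np.unique(b).size == 1 and a[0] == b[0]:
        logger.warning("both raters constant and equal; kappa defined as 1.0")
        return 1.0, landis_koch_band(1.0)
    kappa = float(cohen_kappa_score(a, b))
    return kappa, landis_koch_band(kappa)


def welch_t(group_a, group_b):
    """Welch's unequal-variance two-sample t-test; returns (t, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        raise DataError("both groups have zero variance; t undefined")
    res = sstats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pearson_with_ci(x, y, level: float = 0.95):
    """Pearson r with a Fisher-z confidence interval.

    Returns ``(r, lo, hi)``.  Fisher-z intervals are the standard
    frequentist interval for a correlation; they are reported as such.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise DataError("need n >= 4 for a Fisher-z interval")
    r = float(np.corrcoef(x, y)[0, 1])
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    se = 1.0 / math.sqrt(n - 3)
    zcrit = float(sstats.norm.ppf(0.5 + level / 2.0))
    return r, math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)
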