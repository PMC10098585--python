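"""End-to-end record processing and dataset-level evaluation.

``process_record`` runs preprocess -> time-domain HR -> frequency-domain HR
-> quality indices (-> agreement when a reference is attached) on one
record.  ``evaluate_dataset`` applies it to a manifest of records and
produces the two dataset-level analyses: agreement of the quality labels
with external annotations (counts, kappa, point-biserial, ROC cut points)
and the association between the continuous quality indices and HR accuracy
(correlations of self-consistency and STD-width with RMSE/MAE).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import hr_freq, hr_time, preprocess as pp, quality as qual
from .errors import DataError, RomaError
from .signal_io import HRSeries, PPGRecord, align_to_times, read_hr_csv, read_ppg_csv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ProcessResult", "process_record",
           "load_manifest", "evaluate_dataset"]


@dataclass
class PipelineConfig:
    """Every tunable of the processing chain, with the published defaults.

    Defaults: 0.6 s baseline window, 3.5 Hz low-pass with steepness 0.8,
    0.5 s normalization window, 0.5 peak threshold, 40-beat outlier and
    smoothing windows with 3 scaled MADs, 30 s spectrogram window with
    ~7.27 s hop, [40, 210] BPM search band, half-maximum line width,
    10 BPM self-consistency tolerance, 5 BPM accuracy tolerance, and
    quality cut points of 30 (self-consistency) / 10 BPM (STD-width).
    Short-record mode (10 s smartphone recordings) swaps in a 2.5 s window
    with a 0.6 s hop.
    """

    baseline_window_s: float = 0.6
    cutoff_hz: float = 3.5
    steepness: float = 0.8
    norm_window_s: float = 0.5
    notch: bool = False
    notch_center_bpm: float = 100.0
    notch_width_bpm: float = 50.0
    peak_threshold: float = 0.5
    min_separation_s: float = 0.25
    outlier_window_beats: int = 40
    outlier_n_mads: float = 3.0
    smooth_window_beats: int = 40
    spec_window_s: float = 30.0
    spec_hop_s: float = 7.27
    band_bpm: tuple = (40.0, 210.0)
    width_level: float = 0.5
    sc_tol_bpm: float = 10.0
    sc_cut: float = 30.0
    width_cut: float = 10.0
    accuracy_tol_bpm: float = 5.0
    rmse_denominator: str = "n-1"

    @classmethod
    def short_record(cls, **overrides) -> "PipelineConfig":
        """Configuration for ~10 s records: 2.5 s window, 0.6 s hop."""
        return cls(spec_window_s=2.5, spec_hop_s=0.6, **overrides)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def with_overrides(self, pairs: dict) -> "PipelineConfig":
        """Apply string key=value overrides with field-type coercion."""
        kwargs = {}
        for key, value in pairs.items():
            f = {f.name: f for f in dataclasses.fields(self)}.get(key)
            if f is None:
                raise DataError(f"unknown config key {key!r}")
            if f.type in ("bool", bool):
                kwargs[key] = str(value).lower() in ("1", "true", "yes", "on")
            elif f.type in ("int", int):
                kwargs[key] = int(value)
            elif f.type in ("tuple", tuple):
                kwargs[key] = tuple(float(x) for x in str(value).split(","))
            elif f.type in ("str", str):
                kwargs[key] = str(value)
            else:
                kwargs[key] = float(value)
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_bpm"] = list(d["band_bpm"])
        return d


@dataclass
class ProcessResult:
    record_id: str
    processed: pp.ProcessedSignal
    beats: hr_time.BeatTrain
    track: hr_freq.SpectralTrack
    hr_time: HRSeries
    hr_freq: HRSeries
    quality: qual.QualityMetrics
    agreement: Optional[agr.AgreementStats] = None

    def quality_report(self, config: PipelineConfig) -> dict:
        report = {
            "record_id": self.record_id,
            **self.quality.to_dict(),
            "cutpoints": {"self_consistency": config.sc_cut, "std_width": config.width_cut},
            "n_frames": int(self.track.n_frames),
            "n_beats": int(self.beats.peak_times.size),
            "outlier_fraction": self.beats.outlier_fraction,
        }
        if self.agreement is not None:
            report["agreement"] = self.agreement.to_dict()
        return report


def process_record(record: PPGRecord, config: Optional[PipelineConfig] = None) -> ProcessResult:
    """Run the full chain on one record.

    The spectrogram consumes the drift-free signal v (after the optional
    cadence notch); beat counting consumes the normalized low-passed signal.
    When ``record.reference_hr`` is set, agreement statistics against it
    (interpolated to the beat stamps) are included.
    """
    cfg = config or PipelineConfig()
    try:
        processed = pp.preprocess(
            record, cfg.baseline_window_s, cfg.cutoff_hz, cfg.steepness,
            cfg.norm_window_s, cfg.notch, cfg.notch_center_bpm, cfg.notch_width_bpm)
        beats = hr_time.extract_beats(
            processed.normalized, record.fs, cfg.peak_threshold, cfg.min_separation_s,
            cfg.outlier_window_beats, cfg.outlier_n_mads, record.t0)
        series_t = beats.hr_series()
        track = hr_freq.compute_spectrogram(
            processed.highpassed, record.fs, cfg.spec_window_s, cfg.spec_hop_s, record.t0)
        hr_freq.track_peak_and_width(track, cfg.band_bpm, cfg.width_level)
        series_f = hr_freq.hr_freq_series(track, series_t.times)
        quality = qual.assess_quality(series_t, series_f, track, cfg.sc_tol_bpm,
                                      cfg.sc_cut, cfg.width_cut, beats.outlier_mask)
    except RomaError as exc:
        raise type(exc)(f"[{record.record_id}] {exc}") from exc

    agreement = None
    if record.reference_hr is not None:
        ref = align_to_times(record.reference_hr, series_t.times)
        agreement = agr.error_metrics(ref, series_t, cfg.accuracy_tol_bpm,
                                      beats.outlier_mask, cfg.rmse_denominator)
    return ProcessResult(record_id=record.record_id, processed=processed, beats=beats,
                         track=track, hr_time=series_t, hr_freq=series_f,
                         quality=quality, agreement=agreement)


def load_manifest(path) -> list:
    """Load a fixture/dataset manifest (YAML) into record entries.

    Each entry gets keys ``id``, ``record`` (a PPGRecord with any reference
    HR attached) and optional ``label``.  Missing files are collected and
    reported together.
    """
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    entries = []
    missing = []
    for item in manifest.get("records", []):
        rec_path = path.parent / item["record"]
        if not rec_path.exists():
            missing.append(str(rec_path))
            continue
        record = read_ppg_csv(rec_path, record_id=item.get("id"))
        truth = item.get("truth")
        if truth:
            truth_path = path.parent / truth
            if not truth_path.exists():
                missing.append(str(truth_path))
                continue
            record.reference_hr = read_hr_csv(truth_path)
        record.quality_label = item.get("label")
        entries.append({"id": item.get("id", rec_path.stem), "record": record,
                        "label": item.get("label")})
    if missing:
        raise RomaError("manifest references missing files: " + ", ".join(missing))
    return entries


def evaluate_dataset(entries: list, config: Optional[PipelineConfig] = None) -> dict:
    """Process every record and aggregate the dataset-level analyses.

    Part 1 (requires labels): poor counts per index, kappa of the pipeline
    label vs the annotation, point-biserial correlations, ROC cut points.
    Part 2 (requires references): Pearson correlations of each index with
    RMSE and MAE, and a Welch t-test of accuracy between label groups.
    Either part is omitted with a warning when its inputs are absent.
    """
    cfg = config or PipelineConfig()
    rows = []
    for entry in entries:
        res = process_record(entry["record"], cfg)
        row = {"id": entry["id"],
               "self_consistency": res.quality.self_consistency,
               "std_width": res.quality.std_width,
               "label": res.quality.label,
               "annotation": entry.get("label")}
        if res.agreement is not None:
            row.update({"accuracy": res.agreement.accuracy5, "rmse": res.agreement.rmse,
                        "mae": res.agreement.mae, "mae_pct": res.agreement.mae_pct})
        rows.append(row)
    table = pd.DataFrame(rows)
    report = {"n_records": len(rows), "per_record": rows, "config": cfg.to_dict()}

    have_labels = table["annotation"].notna().all() if len(table) else False
    if have_labels:
        annotated_good = (table["annotation"] == "good").to_numpy()
        predicted_good = (table["label"] == "adequate").to_numpy()
        sc = table["self_consistency"].to_numpy()
        sw = table["std_width"].to_numpy()
        kappa, band = agr.cohens_kappa(annotated_good, predicted_good)
        part1 = {
            "n_poor_by_self_consistency": int(np.sum(sc <= cfg.sc_cut)),
            "n_poor_by_std_width": int(np.sum(sw >= cfg.width_cut)),
            "n_poor_combined": int(np.sum(~predicted_good)),
            "kappa": kappa, "kappa_band": band,
            "point_biserial_self_consistency": agr.point_biserial(annotated_good.astype(int), sc),
            "point_biserial_std_width": agr.point_biserial(annotated_good.astype(int), sw),
        }
        labels = np.where(annotated_good, "good", "poor")
        for name, scores, direction in (("self_consistency", sc, "higher_is_good"),
                                        ("std_width", sw, "higher_is_poor")):
            cut = qual.roc_cutpoint(scores, labels, direction, metric_name=name)
            part1[f"roc_{name}"] = {"auc": cut.auc, "threshold": cut.threshold,
                                    "sensitivity": cut.sensitivity,
                                    "specificity": cut.specificity}
        report["part1_signal_quality_agreement"] = part1
    else:
        logger.warning("no (complete) quality annotations; Part 1 agreement stats omitted")

    have_refs = "rmse" in table.columns and table["rmse"].notna().all() if len(table) else False
    if have_refs and len(table) >= 4:
        part2 = {}
        for metric in ("rmse", "mae"):
            for index in ("self_consistency", "std_width"):
                r, lo, hi = agr.pearson_with_ci(table[index], table[metric])
                part2[f"r_{index}_vs_{metric}"] = {"r": r, "ci95": [lo, hi]}
        adequate = table[table["label"] == "adequate"]["accuracy"]
        poor = table[table["label"] == "poor"]["accuracy"]
        if len(adequate) >= 2 and len(poor) >= 2:
            t, p = agr.welch_t(adequate, poor)
            part2["accuracy_t_test"] = {"t": t, "p": p,
                                        "mean_adequate": float(adequate.mean()),
                                        "mean_poor": float(poor.mean())}
        report["part2_quality_vs_accuracy"] = part2
    elif not have_refs:
        logger.warning("no reference HR series; Part 2 accuracy stats omitted")
    return report
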