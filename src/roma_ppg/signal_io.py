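"""Reading, writing and time-alignment of PPG records and heart-rate series.

A :class:`PPGRecord` is a uniformly sampled single-channel photoplethysmogram:
samples in arbitrary sensor units at a known sampling rate ``fs``, with the
n-th sample taken at ``t0 + n / fs`` seconds.  An :class:`HRSeries` is a
time-stamped heart-rate trace in beats per minute (BPM), used both for the
package's own time-/frequency-domain estimates and for external references
(e.g. ECG telemetry).

Two on-disk formats are supported:

* CSV with columns ``time_s`` and ``ppg`` (case-insensitive; ``value`` is
  accepted as an alias for ``ppg``), comma-separated, header row required.
* PhysioNet-style waveform records (paired ``.hea`` header + ``.dat`` signal
  files, formats 16/80/212) as used by public smartphone and wrist PPG
  datasets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "PPGRecord",
    "HRSeries",
    "read_ppg_csv",
    "write_ppg_csv",
    "read_hr_csv",
    "write_hr_csv",
    "read_physionet_record",
    "align_to_times",
]


@dataclass
class HRSeries:
    """A heart-rate trace: strictly increasing times (s) and HR values (BPM).

    ``source`` records provenance: ``time_domain``, ``frequency_domain`` or
    ``reference``.
    """

    times: np.ndarray
    hr: np.ndarray
    source: str = "reference"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.hr.shape:
            raise DataError("times and hr must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise DataError("empty HR series")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise DataError("HR series times must be strictly increasing")
        if not np.all(np.isfinite(self.hr)) or np.any(self.hr <= 0):
            raise DataError("HR values must be finite and > 0")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class PPGRecord:
    """A raw PPG sample sequence with its sampling rate.

    Implied timestamps are ``t0 + n / fs`` for 0-based sample index ``n``.
    ``quality_label``, when present, is one of ``{"good", "poor"}``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    record_id: str = ""
    quality_label: Optional[str] = None
    reference_hr: Optional[HRSeries] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise DataError("a PPG record needs at least one sample")
        if not self.fs > 0:
            raise DataError("sampling rate must be > 0")
        if self.quality_label is not None and self.quality_label not in ("good", "poor"):
            raise DataError("quality_label must be 'good' or 'poor'")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def _find_column(df: pd.DataFrame, names: tuple[str, ...]) -> Optional[str]:
    lower = {c.lower().strip(): c for c in df.columns}
    for name in names:
        if name in lower:
            return lower[name]
    return None


def read_ppg_csv(path, fs_override: Optional[float] = None, record_id: Optional[str] = None) -> PPGRecord:
    """Read a PPG record from CSV.

    The file must contain a ``ppg`` (or ``value``) column, and either a
    ``time_s`` column or an explicit ``fs_override``.  When a time column is
    present, ``fs`` is estimated as ``1 / median(diff(time_s))`` and the
    timestamps are checked for uniformity within 1% (non-uniformity is logged,
    not fatal).  If both a time column and ``fs_override`` are supplied, the
    override wins and a warning is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    value_col = _find_column(df, ("ppg", "value"))
    if value_col is None:
        raise FormatError(f"{path}: no 'ppg' (or 'value') column found")
    samples = df[value_col].to_numpy(dtype=float)

    time_col = _find_column(df, ("time_s", "time"))
    t0 = 0.0
    if time_col is not None:
        times = df[time_col].to_numpy(dtype=float)
        diffs = np.diff(times)
        if times.size > 1 and np.any(diffs <= 0):
            raise DataError(f"{path}: time column is not strictly increasing")
        if times.size > 1:
            dt = float(np.median(diffs))
            if np.max(np.abs(diffs - dt)) > 0.01 * dt:
                logger.warning("%s: sample times deviate from uniform spacing by more than 1%%", path)
            fs = 1.0 / dt
        else:
            fs = None
        t0 = float(times[0])
        if fs_override is not None:
            if fs is not None:
                logger.warning("%s: fs_override=%g overrides fs=%g estimated from the time column",
                               path, fs_override, fs)
            fs = fs_override
    else:
        fs = fs_override

    if fs is None:
        raise ConfigurationError(f"{path}: sampling rate unresolvable (no time column and no fs_override)")
    return PPGRecord(samples=samples, fs=float(fs), t0=t0,
                     record_id=record_id if record_id is not None else path.stem)


def write_ppg_csv(record: PPGRecord, path) -> None:
    """Write a record as ``time_s,ppg`` CSV. Sample values round-trip bit-exactly."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,ppg\n")
        for t, v in zip(record.times, record.samples):
            fh.write(f"{t:.12f},{v:.17g}\n")


def read_hr_csv(path, source: str = "reference") -> HRSeries:
    """Read an HR series from CSV with columns ``time_s`` and ``hr_bpm`` (or ``hr``)."""
    path = Path(path)
    df = pd.read_csv(path)
    tcol = _find_column(df, ("time_s", "time"))
    hcol = _find_column(df, ("hr_bpm", "hr"))
    if tcol is None or hcol is None:
        raise FormatError(f"{path}: expected columns time_s and hr_bpm")
    return HRSeries(df[tcol].to_numpy(float), df[hcol].to_numpy(float), source=source)


def write_hr_csv(series: HRSeries, path) -> None:
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,hr_bpm\n")
        for t, h in zip(series.times, series.hr):
            fh.write(f"{t:.6f},{h:.10g}\n")


# ---------------------------------------------------------------------------
# PhysioNet waveform records (WFDB format, minimal reader)
# ---------------------------------------------------------------------------

_PPG_NAME = re.compile(r"ppg|pleth", re.IGNORECASE)


def _parse_header(hea_path: Path):
    """Parse a WFDB ``.hea`` file into (record name, fs, n_samples, signal specs)."""
    lines = []
    for raw in hea_path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        lines.append(line)
    if not lines:
        raise FormatError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"{hea_path}: malformed record line")
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    if len(lines) - 1 < n_sig:
        raise FormatError(f"{hea_path}: header declares {n_sig} signals but lists fewer")
    specs = []
    for line in lines[1:1 + n_sig]:
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"{hea_path}: malformed signal line: {line!r}")
        fname = parts[0]
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, None
        if len(parts) > 2:
            g = parts[2]
            gain_part = g.split("/")[0]
            m = re.match(r"(-?[\d.eE+]+)(?:\((-?\d+)\))?", gain_part)
            if m:
                gain = float(m.group(1)) or 200.0
                if m.group(2) is not None:
                    baseline = int(m.group(2))
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(parts[8:]) if len(parts) > 8 else f"sig{len(specs)}"
        specs.append({"file": fname, "fmt": fmt, "gain": gain, "baseline": baseline, "desc": desc})
    return name, fs, n_samples, specs


def _read_dat(dat_path: Path, fmt: str, n_sig: int) -> np.ndarray:
    """Decode a WFDB signal file into an (n_frames, n_sig) int array."""
    raw = dat_path.read_bytes()
    if fmt == "16":
        data = np.frombuffer(raw, dtype="<i2")
    elif fmt == "80":
        data = np.frombuffer(raw, dtype=np.uint8).astype(np.int16) - 128
    elif fmt == "212":
        b = np.frombuffer(raw, dtype=np.uint8).astype(np.int32)
        n_pairs = len(b) // 3
        b = b[: n_pairs * 3].reshape(-1, 3)
        first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        first = np.where(first > 2047, first - 4096, first)
        second = np.where(second > 2047, second - 4096, second)
        data = np.empty(n_pairs * 2, dtype=np.int32)
        data[0::2] = first
        data[1::2] = second
    else:
        raise FormatError(f"{dat_path}: unsupported WFDB signal format {fmt!r}")
    n_frames = len(data) // n_sig
    return np.asarray(data[: n_frames * n_sig]).reshape(n_frames, n_sig)


def _load_quality_annotations(directory: Path) -> dict:
    """Load record->quality mapping from a sibling annotation CSV, if any.

    Looks for a ``quality-hr-ann.csv``-style file: first column the record id,
    and a column whose name contains 'quality' holding 1/0 (good/poor).
    """
    for cand in sorted(directory.glob("*ann*.csv")):
        try:
            df = pd.read_csv(cand)
        except Exception:  # pragma: no cover - malformed sidecar, not fatal
            continue
        qcol = next((c for c in df.columns if "quality" in c.lower()), None)
        if qcol is None:
            continue
        ids = df.iloc[:, 0].astype(str)
        return {i: ("good" if int(q) == 1 else "poor") for i, q in zip(ids, df[qcol])}
    return {}


def read_physionet_record(path, channel=None) -> PPGRecord:
    """Read a PhysioNet-style waveform record and return its PPG channel.

    ``path`` is the record path with or without the ``.hea`` extension.  The
    PPG channel is located by name (matching ``ppg``/``pleth``,
    case-insensitive) unless ``channel`` selects one explicitly by index or
    name; selection is exposed because some wrist datasets carry two PPG
    channels.  A sibling annotation CSV with a binary quality column, when
    present, supplies ``quality_label``.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"header file not found: {hea}")
    try:
        name, fs, n_samples, specs = _parse_header(hea)
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{hea}: corrupt header ({exc})") from exc

    if channel is None:
        idx = next((i for i, s in enumerate(specs) if _PPG_NAME.search(s["desc"])), None)
        if idx is None:
            raise DataError(
                f"{name}: no PPG channel found (channels: {[s['desc'] for s in specs]})")
    elif isinstance(channel, int):
        idx = channel
        if not 0 <= idx < len(specs):
            raise DataError(f"{name}: channel index {idx} out of range")
    else:
        idx = next((i for i, s in enumerate(specs) if channel.lower() in s["desc"].lower()), None)
        if idx is None:
            raise DataError(f"{name}: no channel matching {channel!r}")

    spec = specs[idx]
    # signals sharing one .dat file are interleaved frame by frame
    group = [i for i, s in enumerate(specs) if s["file"] == spec["file"]]
    dat = hea.parent / spec["file"]
    if not dat.exists():
        raise FormatError(f"signal file not found: {dat}")
    matrix = _read_dat(dat, spec["fmt"], len(group))
    raw = matrix[:, group.index(idx)]
    if n_samples:
        raw = raw[:n_samples]
    physical = (raw.astype(float) - spec["baseline"]) / spec["gain"]

    quality = _load_quality_annotations(hea.parent).get(name)
    return PPGRecord(samples=physical, fs=fs, record_id=name, quality_label=quality)


def align_to_times(series: HRSeries, target_times) -> HRSeries:
    """Linearly interpolate an HR series onto ``target_times``.

    Inside the series' span this is plain linear interpolation; outside it the
    endpoint values are held constant.  Used to carry frequency-domain HR back
    onto the systolic time stamps found in the time domain.
    """
    if len(series) < 2:
        raise DataError("need at least 2 points to interpolate an HR series")
    target = np.asarray(target_times, dtype=float)
    if target.size == 0:
        raise DataError("target_times is empty")
    if target.size > 1 and not np.all(np.diff(target) > 0):
        raise DataError("target_times must be strictly increasing")
    hr = np.interp(target, series.times, series.hr)
    return HRSeries(times=target, hr=hr, source=series.source)
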