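import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roma_ppg.errors import ConfigurationError, DataError, FormatError
from roma_ppg.signal_io import (HRSeries, PPGRecord, align_to_times, read_physionet_record,
                                read_ppg_csv, write_ppg_csv)


class TestPPGRecordInvariants:
    def test_timestamps_are_zero_based_over_fs(self):
        rec = PPGRecord(samples=[1.0, 2.0, 3.0], fs=30.0)
        assert np.allclose(rec.times, [0.0, 1 / 30, 2 / 30])

    @pytest.mark.parametrize("kwargs", [
        dict(samples=[], fs=30.0),
        dict(samples=[1.0], fs=0.0),
        dict(samples=[1.0], fs=30.0, quality_label="great"),
    ])
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(DataError):
            PPGRecord(**kwargs)

    def test_hr_series_requires_positive_finite_hr(self):
        with pytest.raises(DataError):
            HRSeries([0.0, 1.0], [60.0, -5.0])
        with pytest.raises(DataError):
            HRSeries([0.0, 0.0], [60.0, 60.0])


class TestCsvRoundTrip:
    def test_value_column_with_fs_override(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("ppg\n1\n2\n3\n")
        rec = read_ppg_csv(p, fs_override=30.0)
        assert rec.fs == 30.0 and rec.samples.size == 3

    def test_fs_estimated_from_time_column(self, tmp_path):
        p = tmp_path / "r.csv"
        times = np.arange(4) / 46.3
        p.write_text("time_s,ppg\n" + "\n".join(f"{t:.9f},{v}" for t, v in zip(times, [1, 2, 3, 4])))
        rec = read_ppg_csv(p)
        assert rec.fs == pytest.approx(46.3, rel=1e-6)

    def test_shuffled_time_column_is_data_error(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("time_s,ppg\n0.0,1\n0.2,2\n0.1,3\n")
        with pytest.raises(DataError):
            read_ppg_csv(p)

    def test_missing_value_column_is_format_error(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(FormatError):
            read_ppg_csv(p)

    def test_no_fs_resolvable_is_configuration_error(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("ppg\n1\n2\n")
        with pytest.raises(ConfigurationError):
            read_ppg_csv(p)

    def test_round_trip_bit_exact_samples_and_fs(self, tmp_path, rng):
        rec = PPGRecord(samples=rng.normal(512, 100, 500), fs=46.3, record_id="rt")
        p = tmp_path / "rt.csv"
        write_ppg_csv(rec, p)
        back = read_ppg_csv(p)
        assert np.array_equal(back.samples, rec.samples)
        assert back.fs == pytest.approx(rec.fs, rel=1e-9)


def _write_wfdb(d, name="rec1", fs=30, n=300, desc=("PPG", "ECG")):
    sig = (np.sin(2 * np.pi * 1.2 * np.arange(n) / fs) * 1000).astype("<i2")
    other = np.zeros(n, dtype="<i2")
    inter = np.empty(2 * n, dtype="<i2")
    inter[0::2], inter[1::2] = sig, other
    (d / f"{name}.dat").write_bytes(inter.tobytes())
    lines = [f"{name} 2 {fs} {n}"]
    for ch in desc:
        lines.append(f"{name}.dat 16 200(0) 16 0 0 0 0 {ch}")
    (d / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return sig


class TestPhysionetReader:
    def test_reads_ppg_channel_with_gain(self, tmp_path):
        sig = _write_wfdb(tmp_path)
        rec = read_physionet_record(tmp_path / "rec1")
        assert rec.fs == 30.0 and rec.samples.size == 300
        assert np.allclose(rec.samples * 200.0, sig)

    def test_quality_annotation_sidecar_attached(self, tmp_path):
        _write_wfdb(tmp_path)
        (tmp_path / "quality-hr-ann.csv").write_text("ID,Quality,HR\nrec1,0,72\n")
        rec = read_physionet_record(tmp_path / "rec1")
        assert rec.quality_label == "poor"

    def test_no_ppg_channel_is_data_error(self, tmp_path):
        _write_wfdb(tmp_path, desc=("ECG I", "ECG II"))
        with pytest.raises(DataError):
            read_physionet_record(tmp_path / "rec1")

    def test_explicit_channel_selection(self, tmp_path):
        _write_wfdb(tmp_path, desc=("PPG green", "PPG ir"))
        rec = read_physionet_record(tmp_path / "rec1", channel=1)
        assert np.allclose(rec.samples, 0.0)

    def test_corrupt_header_is_format_error(self, tmp_path):
        (tmp_path / "bad.hea").write_text("bad 2 30 300\nonly-one-field\n")
        with pytest.raises(FormatError):
            read_physionet_record(tmp_path / "bad")


class TestAlignToTimes:
    def test_linear_midpoint(self):
        s = HRSeries([0.0, 10.0], [60.0, 80.0])
        assert align_to_times(s, [5.0]).hr[0] == pytest.approx(70.0)

    def test_hand_interpolation(self):
        s = HRSeries([0.0, 2.0, 4.0], [60.0, 60.0, 90.0])
        assert align_to_times(s, [3.0]).hr[0] == pytest.approx(75.0)

    def test_endpoints_held_outside_span(self):
        s = HRSeries([0.0, 10.0], [60.0, 80.0])
        out = align_to_times(s, [-5.0, 20.0])
        assert out.hr[0] == 60.0 and out.hr[1] == 80.0

    def test_single_point_series_rejected(self):
        with pytest.raises(DataError):
            align_to_times(HRSeries([0.0], [60.0]), [1.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 30))
    def test_identity_on_own_time_grid(self, n):
        times = np.cumsum(np.arange(1, n + 1).astype(float))
        hr = 60.0 + 30.0 * np.sin(np.arange(n))**2 + 1.0
        s = HRSeries(times, hr)
        out = align_to_times(s, times)
        assert np.allclose(out.hr, s.hr)
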