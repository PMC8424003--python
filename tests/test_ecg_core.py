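"""Record I/O, preprocessing, and the stand-in beat detector."""

import numpy as np
import pytest

from ecmaf import ecg_core, synth_ecg, wfdb_io
from ecmaf.ecg_core import (
    AF, NONAF, ECGRecord, PreprocessConfig, RhythmInterval,
    clip_amplitude, detect_beats, highpass_baseline, read_csv_record,
    read_wfdb_record, resample_record, write_csv_record, write_wfdb_record,
)


def _flat_record(n=5000, fs=500.0, value=0.0, n_ch=1):
    return ECGRecord(
        record_id="flat",
        channels=[f"ch{i+1}" for i in range(n_ch)],
        signal=np.full((n_ch, n), value),
        fs=fs,
    )


class TestDomainTypes:
    def test_beats_must_increase_and_stay_in_bounds(self):
        with pytest.raises(ValueError, match="increasing"):
            ECGRecord("r", ["ch1"], np.zeros((1, 100)), 500.0, beats=[10, 10])
        with pytest.raises(ValueError, match="outside"):
            ECGRecord("r", ["ch1"], np.zeros((1, 100)), 500.0, beats=[10, 100])

    def test_overlapping_rhythm_rejected_with_offenders_listed(self):
        with pytest.raises(ValueError, match=r"\[0,5\).*overlaps.*\[3,8\)"):
            ECGRecord(
                "r", ["ch1"], np.zeros((1, 10)), 500.0,
                rhythm=[RhythmInterval(0, 5, AF), RhythmInterval(3, 8, NONAF)],
            )

    def test_interval_requires_onset_before_offset(self):
        with pytest.raises(ValueError):
            RhythmInterval(5, 5, AF)

    def test_preprocess_config_invariants(self):
        with pytest.raises(ValueError):
            PreprocessConfig(clip_mv=0)
        with pytest.raises(ValueError):
            PreprocessConfig(target_fs=0.9, highpass_cutoff=0.5)


class TestWfdbIO:
    def test_header_metadata_passthrough(self, tmp_path):
        rec = ECGRecord("twoch", ["I", "II"], np.zeros((2, 1280)), 128.0)
        write_wfdb_record(rec, tmp_path / "twoch")
        back = read_wfdb_record(tmp_path / "twoch")
        assert back.fs == 128.0
        assert back.channels == ["I", "II"]
        assert back.n_samples == 1280

    def test_rhythm_intervals_from_aux_stream(self, tmp_path):
        # (N @0, (AFIB @1000, (N @3000 over a 5000-sample record
        wfdb_io.write_signal(tmp_path / "r", "r", ["ch1"], np.zeros((1, 5000)), 250.0)
        anns = [
            wfdb_io.Annotation(0, wfdb_io.RHYTHM, "(N"),
            wfdb_io.Annotation(1000, wfdb_io.RHYTHM, "(AFIB"),
            wfdb_io.Annotation(3000, wfdb_io.RHYTHM, "(N"),
        ]
        wfdb_io.write_annotations(tmp_path / "r.atr", anns)
        rec = read_wfdb_record(tmp_path / "r")
        assert [(iv.onset, iv.offset, iv.label) for iv in rec.rhythm] == [
            (0, 1000, NONAF), (1000, 3000, AF), (3000, 5000, NONAF)
        ]

    def test_missing_annotation_file_defaults_to_nonaf(self, tmp_path):
        wfdb_io.write_signal(tmp_path / "p", "p", ["ch1"], np.zeros((1, 700)), 128.0)
        rec = read_wfdb_record(tmp_path / "p")
        assert rec.beats.size == 0
        assert [(iv.onset, iv.offset, iv.label) for iv in rec.rhythm] == [(0, 700, NONAF)]

    def test_unknown_aux_maps_to_nonaf_with_warning(self, tmp_path, caplog):
        wfdb_io.write_signal(tmp_path / "u", "u", ["ch1"], np.zeros((1, 500)), 128.0)
        wfdb_io.write_annotations(
            tmp_path / "u.atr", [wfdb_io.Annotation(0, wfdb_io.RHYTHM, "(WEIRD")]
        )
        with caplog.at_level("WARNING"):
            rec = read_wfdb_record(tmp_path / "u")
        assert rec.rhythm[0].label == NONAF
        assert "WEIRD" in caplog.text

    def test_missing_file_is_io_error_naming_it(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nothere"):
            read_wfdb_record(tmp_path / "nothere")

    def test_full_roundtrip_preserves_beats_rhythm_and_quantized_signal(self, tmp_path):
        plan = synth_ecg.RhythmPlan([(20.0, "NSR"), (15.0, "AF")], "RT", seed=3)
        rec = synth_ecg.generate_record(plan)
        write_wfdb_record(rec, tmp_path / "rt")
        back = read_wfdb_record(tmp_path / "rt")
        assert np.array_equal(back.beats, rec.beats)
        assert [(i.onset, i.offset, i.label) for i in back.rhythm] == [
            (i.onset, i.offset, i.label) for i in rec.rhythm
        ]
        # format-16 stores 200 adu/mV -> half-LSB quantization bound
        assert np.abs(back.signal - rec.signal).max() <= 0.5 / 200 + 1e-12


class TestCsvIO:
    def test_single_interval_record(self, tmp_path):
        rec = ECGRecord(
            "tiny", ["ch1"], np.arange(10.0)[None] / 10, 100.0,
            rhythm=[RhythmInterval(0, 10, AF)],
        )
        write_csv_record(rec, tmp_path / "s.csv", tmp_path / "a.csv")
        back = read_csv_record(tmp_path / "s.csv", tmp_path / "a.csv")
        assert back.rhythm[0].label == AF
        assert back.rhythm[0].offset == 10

    def test_roundtrip_is_field_identical(self, tmp_path):
        plan = synth_ecg.RhythmPlan([(10.0, "NSR"), (8.0, "AF")], "CSVRT", seed=4)
        rec = synth_ecg.generate_record(plan, n_channels=2)
        write_csv_record(rec, tmp_path / "s.csv", tmp_path / "a.csv")
        back = read_csv_record(tmp_path / "s.csv", tmp_path / "a.csv")
        assert back.record_id == rec.record_id
        assert back.channels == rec.channels
        assert back.fs == rec.fs
        assert np.array_equal(back.signal, rec.signal)
        assert np.array_equal(back.beats, rec.beats)
        assert [(i.onset, i.offset, i.label) for i in back.rhythm] == [
            (i.onset, i.offset, i.label) for i in rec.rhythm
        ]

    def test_overlapping_intervals_rejected(self, tmp_path):
        (tmp_path / "s.csv").write_text("# record_id=x fs=100\nch1\n0.0\n0.1\n")
        (tmp_path / "a.csv").write_text(
            "kind,onset,offset,label\nrhythm,0,5,AF\nrhythm,3,8,NONAF\n"
        )
        with pytest.raises(ValueError, match="overlap"):
            read_csv_record(tmp_path / "s.csv", tmp_path / "a.csv")

    def test_non_numeric_cell_reports_row(self, tmp_path):
        (tmp_path / "s.csv").write_text("# record_id=x fs=100\nch1\n0.0\noops\n")
        (tmp_path / "a.csv").write_text("kind,onset,offset,label\n")
        with pytest.raises(ValueError, match="row 1"):
            read_csv_record(tmp_path / "s.csv", tmp_path / "a.csv")


class TestResample:
    def test_duration_preserved_128_to_500(self):
        rec = _flat_record(n=1280, fs=128.0)
        out = resample_record(rec, 500.0)
        assert out.fs == 500.0
        assert out.n_samples == 5000

    def test_identity_at_target_rate(self):
        rec = _flat_record(fs=500.0)
        assert resample_record(rec, 500.0) is rec

    def test_sinusoid_against_analytic_oracle(self):
        fs_in, fs_out, f = 250.0, 500.0, 5.0
        t_in = np.arange(int(2 * fs_in)) / fs_in
        rec = ECGRecord("sine", ["ch1"], np.sin(2 * np.pi * f * t_in)[None], fs_in)
        out = resample_record(rec, fs_out)
        t_out = np.arange(out.n_samples) / fs_out
        ref = np.sin(2 * np.pi * f * t_out)
        lo, hi = int(0.1 * out.n_samples), int(0.9 * out.n_samples)
        corr = np.corrcoef(out.signal[0, lo:hi], ref[lo:hi])[0, 1]
        assert corr > 0.999

    def test_round_trip_reproduces_slow_sinusoid(self):
        fs = 128.0
        t = np.arange(int(10 * fs)) / fs
        rec = ECGRecord("s1", ["ch1"], np.sin(2 * np.pi * 1.0 * t)[None], fs)
        back = resample_record(resample_record(rec, 500.0), fs)
        n = min(back.n_samples, rec.n_samples)
        lo, hi = int(0.1 * n), int(0.9 * n)
        assert np.corrcoef(back.signal[0, lo:hi], rec.signal[0, lo:hi])[0, 1] > 0.999

    def test_annotations_rescaled(self):
        rec = ECGRecord(
            "r", ["ch1"], np.zeros((1, 1280)), 128.0, beats=[128, 640],
            rhythm=[RhythmInterval(0, 1280, NONAF)],
        )
        out = resample_record(rec, 500.0)
        assert list(out.beats) == [500, 2500]
        assert (out.rhythm[0].onset, out.rhythm[0].offset) == (0, 5000)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            resample_record(_flat_record(), 0.0)


class TestHighpass:
    def test_dc_rejection(self):
        rec = _flat_record(value=0.3)
        out = highpass_baseline(rec)
        assert np.abs(out.signal).max() < 1e-6

    def test_sub_cutoff_wander_strongly_attenuated(self):
        # single-pass |H| at 0.05 Hz is ~1e-4; forward-backward squares it
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        rec = ECGRecord("w", ["ch1"], np.sin(2 * np.pi * 0.05 * t)[None], fs)
        out = highpass_baseline(rec)
        mid = slice(int(20 * fs), int(40 * fs))
        assert np.abs(out.signal[0, mid]).max() < 0.01

    def test_zero_phase_keeps_peak_position(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        rec = ECGRecord("p", ["ch1"], np.sin(2 * np.pi * 5.0 * t)[None], fs)
        out = highpass_baseline(rec)
        # first positive peak of a 5 Hz sine is at 50 ms
        window = slice(0, int(0.1 * fs))
        assert abs(int(np.argmax(out.signal[0, window])) - int(np.argmax(rec.signal[0, window]))) <= 1

    def test_too_short_record_advises_minimum(self):
        with pytest.raises(ValueError, match="need >"):
            highpass_baseline(_flat_record(n=10))


class TestClip:
    @pytest.mark.parametrize("value,expected", [(1.5, 1.0), (-2.0, -1.0), (0.4, 0.4)])
    def test_pointwise_clipping(self, value, expected):
        out = clip_amplitude(_flat_record(value=value), 1.0)
        assert out.signal[0, 0] == pytest.approx(expected)

    def test_pipeline_output_always_within_clip(self, mixed_record):
        assert np.abs(mixed_record.signal).max() <= 1.0 + 1e-12


class TestDetectBeats:
    def test_matches_ground_truth_within_10ms_no_extras(self, nsr_record):
        det = detect_beats(nsr_record)
        gt = nsr_record.beats
        tol = int(0.010 * nsr_record.fs)
        # every true beat matched
        assert all(np.abs(det - b).min() <= tol for b in gt)
        # no extra detections on a clean record
        assert all(np.abs(gt - d).min() <= tol for d in det)

    def test_all_zero_record_yields_nothing(self):
        assert detect_beats(_flat_record(n=5000)).size == 0

    def test_deterministic(self, nsr_record):
        assert np.array_equal(detect_beats(nsr_record), detect_beats(nsr_record))

    def test_refractory_period_enforced(self, mixed_record):
        det = detect_beats(mixed_record)
        assert np.diff(det).min() >= int(0.2 * mixed_record.fs)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="3 s"):
            detect_beats(_flat_record(n=1000))
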