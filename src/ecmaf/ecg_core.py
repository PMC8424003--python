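"""Domain types, file I/O, and signal preprocessing for AF detection.

The pipeline expects single- or multi-channel ECG in millivolts with
ground-truth R-peak positions and rhythm annotations.  All sample indices
are 0-based; rhythm intervals are half-open ``[onset, offset)`` in samples
of the record's own sampling rate.

Preprocessing follows the standard chain for electrocardiomatrix
construction: polyphase resampling to 500 Hz, zero-phase 4th-order
Butterworth highpass at 0.5 Hz for baseline-wander removal, and amplitude
clipping to +/- 1 mV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import wfdb_io

log = logging.getLogger(__name__)

AF = "AF"
NONAF = "NONAF"

#: WFDB aux rhythm strings mapped to the binary task.  Anything not listed
#: is treated as NONAF (with a logged warning for genuinely unknown codes).
_AUX_TO_LABEL = {
    "(AFIB": AF,
    "(AFL": NONAF,
    "(N": NONAF,
    "(NSR": NONAF,
    "(SBR": NONAF,
    "(SVTA": NONAF,
    "(B": NONAF,
    "(T": NONAF,
    "(VT": NONAF,
    "(IVR": NONAF,
    "(AB": NONAF,
    "(BII": NONAF,
    "(PREX": NONAF,
}


@dataclass
class RhythmInterval:
    """Half-open annotated rhythm stretch ``[onset, offset)`` in samples."""

    onset: int
    offset: int
    label: str

    def __post_init__(self) -> None:
        self.onset = int(self.onset)
        self.offset = int(self.offset)
        if self.onset >= self.offset:
            raise ValueError(
                f"rhythm interval must satisfy onset < offset, got "
                f"[{self.onset}, {self.offset})"
            )
        if self.label not in (AF, NONAF):
            raise ValueError(f"rhythm label must be AF or NONAF, got {self.label!r}")

    @property
    def duration(self) -> int:
        return self.offset - self.onset


@dataclass
class ECGRecord:
    """Multichannel sampled ECG with beat and rhythm ground truth.

    signal has shape ``(n_channels, n_samples)`` in mV; ``beats`` holds
    R-peak sample indices shared across channels.
    """

    record_id: str
    channels: list[str]
    signal: np.ndarray
    fs: float
    beats: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    rhythm: list[RhythmInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        self.beats = np.asarray(self.beats, dtype=np.int64)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.signal.ndim != 2:
            raise ValueError("signal must be (n_channels, n_samples)")
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if self.beats.size:
            if np.any(np.diff(self.beats) <= 0):
                raise ValueError("beat indices must be strictly increasing")
            if self.beats[0] < 0 or self.beats[-1] >= self.n_samples:
                raise ValueError("beat index outside record")
        validate_rhythm(self.rhythm)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def patient_id(self) -> str:
        """Patient identifier; the record id up to an optional ``/`` suffix."""
        return self.record_id.split("/")[0]


def validate_rhythm(rhythm: list[RhythmInterval]) -> None:
    """Check rhythm intervals are sorted and non-overlapping."""
    bad = [
        (a, b)
        for a, b in zip(rhythm, rhythm[1:])
        if b.onset < a.offset
    ]
    if bad:
        desc = "; ".join(
            f"[{a.onset},{a.offset}) {a.label} overlaps [{b.onset},{b.offset}) {b.label}"
            for a, b in bad
        )
        raise ValueError(f"overlapping/unsorted rhythm intervals: {desc}")


@dataclass
class PreprocessConfig:
    """Preprocessing constants: 500 Hz target, 0.5 Hz 4th-order highpass, 1 mV clip."""

    target_fs: float = 500.0
    highpass_cutoff: float = 0.5
    filter_order: int = 4
    clip_mv: float = 1.0

    def __post_init__(self) -> None:
        if self.target_fs <= 2 * self.highpass_cutoff:
            raise ValueError("target_fs must exceed twice the highpass cutoff")
        if self.clip_mv <= 0:
            raise ValueError("clip_mv must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_wfdb_record(path: str | Path) -> ECGRecord:
    """Read a WFDB header/signal pair (and ``.atr`` annotations if present).

    Rhythm aux labels open an interval closed by the next rhythm label or
    the record end; records without an annotation file get a single NONAF
    interval and no beats.
    """
    path = Path(path)
    header, sig = wfdb_io.read_signal(path)
    ann_path = path.with_suffix(".atr")
    beats: list[int] = []
    rhythm: list[RhythmInterval] = []
    if ann_path.exists():
        anns = wfdb_io.read_annotations(ann_path)
        open_onset: int | None = None
        open_label = NONAF
        for a in anns:
            if a.code == wfdb_io.RHYTHM:
                if open_onset is not None and a.time > open_onset:
                    rhythm.append(RhythmInterval(open_onset, a.time, open_label))
                open_onset = a.time
                if a.aux in _AUX_TO_LABEL:
                    open_label = _AUX_TO_LABEL[a.aux]
                else:
                    log.warning("unknown rhythm aux %r mapped to NONAF", a.aux)
                    open_label = NONAF
            elif a.code in wfdb_io.BEAT_CODES:
                beats.append(a.time)
        if open_onset is not None and header.n_samples > open_onset:
            rhythm.append(RhythmInterval(open_onset, header.n_samples, open_label))
    if not rhythm:
        rhythm = [RhythmInterval(0, header.n_samples, NONAF)]
    return ECGRecord(
        record_id=header.record_name,
        channels=list(header.channel_names),
        signal=sig,
        fs=header.fs,
        beats=np.asarray(sorted(set(beats)), dtype=np.int64),
        rhythm=rhythm,
    )


def write_wfdb_record(rec: ECGRecord, path: str | Path) -> None:
    """Write ``rec`` as WFDB format-16 signal + header + ``.atr`` annotations."""
    path = Path(path)
    wfdb_io.write_signal(path, rec.record_id, rec.channels, rec.signal, rec.fs)
    anns = []
    label_to_aux = {AF: "(AFIB", NONAF: "(N"}
    for iv in rec.rhythm:
        anns.append(wfdb_io.Annotation(iv.onset, wfdb_io.RHYTHM, label_to_aux[iv.label]))
    for b in rec.beats:
        anns.append(wfdb_io.Annotation(int(b), wfdb_io.NORMAL, None))
    anns.sort(key=lambda a: (a.time, a.code != wfdb_io.RHYTHM))
    wfdb_io.write_annotations(path.with_suffix(".atr"), anns)


def read_csv_record(signal_path: str | Path, annotation_path: str | Path) -> ECGRecord:
    """Read the CSV dialect written by :func:`write_csv_record`.

    Signal file: a ``# record_id=... fs=...`` comment line, then one column
    per channel of mV values.  Annotation file: columns
    ``kind,onset,offset,label`` where ``kind`` is ``rhythm`` or ``beat``.
    """
    signal_path = Path(signal_path)
    first = signal_path.read_text().splitlines()[0]
    if not first.startswith("#"):
        raise ValueError(f"{signal_path}: missing '# record_id=... fs=...' line")
    meta = dict(tok.split("=", 1) for tok in first.lstrip("# ").split())
    try:
        fs = float(meta["fs"])
        record_id = meta["record_id"]
    except KeyError as e:  # pragma: no cover - malformed by hand only
        raise ValueError(f"{signal_path}: missing {e} in metadata line") from e
    sig_df = pd.read_csv(signal_path, comment="#", float_precision="round_trip")
    for col in sig_df.columns:
        bad = pd.to_numeric(sig_df[col], errors="coerce").isna() & sig_df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{signal_path}: non-numeric value in column {col!r}, row {row}")
    ann_df = pd.read_csv(annotation_path)
    rhythm = []
    beats = []
    for _, r in ann_df.iterrows():
        if r["kind"] == "rhythm":
            rhythm.append(RhythmInterval(int(r["onset"]), int(r["offset"]), str(r["label"])))
        elif r["kind"] == "beat":
            beats.append(int(r["onset"]))
        else:
            raise ValueError(f"{annotation_path}: unknown annotation kind {r['kind']!r}")
    return ECGRecord(
        record_id=record_id,
        channels=list(sig_df.columns),
        signal=sig_df.to_numpy(dtype=np.float64).T,
        fs=fs,
        beats=np.asarray(sorted(beats), dtype=np.int64),
        rhythm=sorted(rhythm, key=lambda iv: iv.onset),
    )


def write_csv_record(rec: ECGRecord, signal_path: str | Path, annotation_path: str | Path) -> None:
    """Exact inverse of :func:`read_csv_record` (round-trip identity)."""
    signal_path = Path(signal_path)
    with open(signal_path, "w") as f:
        f.write(f"# record_id={rec.record_id} fs={rec.fs:g}\n")
        pd.DataFrame(rec.signal.T, columns=rec.channels).to_csv(
            f, index=False, float_format="%.17g"
        )
    rows = [
        {"kind": "rhythm", "onset": iv.onset, "offset": iv.offset, "label": iv.label}
        for iv in rec.rhythm
    ] + [{"kind": "beat", "onset": int(b), "offset": "", "label": ""} for b in rec.beats]
    pd.DataFrame(rows, columns=["kind", "onset", "offset", "label"]).to_csv(
        annotation_path, index=False
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _rescale_index(idx: np.ndarray, ratio: Fraction) -> np.ndarray:
    # nearest-sample rounding, ties to even (np.rint semantics)
    return np.rint(np.asarray(idx, dtype=np.float64) * float(ratio)).astype(np.int64)


def resample_record(rec: ECGRecord, target_fs: float) -> ECGRecord:
    """Polyphase rational resampling of all channels to ``target_fs``.

    Beat indices and rhythm bounds are rescaled by ``target_fs/fs`` and
    rounded to the nearest sample.  A record already at the target rate is
    returned unchanged.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if math.isclose(rec.fs, target_fs):
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    sig = sps.resample_poly(rec.signal, up, down, axis=1)
    n_out = sig.shape[1]
    beats = _rescale_index(rec.beats, ratio)
    beats = beats[beats < n_out]
    rhythm = []
    for iv in rec.rhythm:
        onset = int(min(_rescale_index(np.array([iv.onset]), ratio)[0], n_out))
        offset = int(min(_rescale_index(np.array([iv.offset]), ratio)[0], n_out))
        if offset > onset:
            rhythm.append(RhythmInterval(onset, offset, iv.label))
    return replace(rec, signal=sig, fs=float(target_fs), beats=beats, rhythm=rhythm)


def highpass_baseline(rec: ECGRecord, cfg: PreprocessConfig | None = None) -> ECGRecord:
    """Zero-phase (forward-backward) Butterworth highpass per channel.

    Forward-backward application achieves the linear-phase behaviour wanted
    for baseline removal at the cost of squaring the magnitude response.
    """
    cfg = cfg or PreprocessConfig()
    sos = sps.butter(
        cfg.filter_order, cfg.highpass_cutoff, btype="highpass", fs=rec.fs, output="sos"
    )
    # sosfiltfilt pads with 3 * (2 * n_sections + 1 - min count) samples
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.n_samples <= padlen:
        raise ValueError(
            f"record too short for zero-phase filtering: need > {padlen} samples, "
            f"got {rec.n_samples}"
        )
    sig = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return replace(rec, signal=sig)


def clip_amplitude(rec: ECGRecord, clip_mv: float = 1.0) -> ECGRecord:
    """Confine every sample to ``[-clip_mv, +clip_mv]``."""
    if clip_mv <= 0:
        raise ValueError("clip_mv must be positive")
    return replace(rec, signal=np.clip(rec.signal, -clip_mv, clip_mv))


def preprocess(rec: ECGRecord, cfg: PreprocessConfig | None = None) -> ECGRecord:
    """Full chain: resample to target_fs, highpass, clip."""
    cfg = cfg or PreprocessConfig()
    rec = resample_record(rec, cfg.target_fs)
    rec = highpass_baseline(rec, cfg)
    return clip_amplitude(rec, cfg.clip_mv)


# ---------------------------------------------------------------------------
# Stand-in beat detector
# ---------------------------------------------------------------------------

def detect_beats(rec: ECGRecord, channel: int = 0) -> np.ndarray:
    """Classical energy-threshold QRS detector (deterministic stand-in).

    Bandpass 8-25 Hz to isolate QRS energy, square, integrate over 150 ms,
    threshold at 30% of the 99th percentile, enforce a 200 ms refractory
    period, then refine each detection to the local absolute-amplitude
    maximum of the preprocessed signal.  Ground-truth or externally supplied
    beat lists should be preferred whenever available.
    """
    if rec.duration < 3.0:
        raise ValueError("record shorter than 3 s: insufficient context for thresholding")
    fs = rec.fs
    x = rec.signal[channel]
    sos = sps.butter(3, [8.0, 25.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    env = np.convolve(bp**2, np.ones(int(round(0.15 * fs))) / (0.15 * fs), mode="same")
    thr = 0.3 * np.percentile(env, 99)
    if thr < 1e-10:
        return np.empty(0, dtype=np.int64)
    peaks, _ = sps.find_peaks(env, height=thr, distance=int(round(0.2 * fs)))
    half = int(round(0.05 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    refined = np.asarray(sorted(set(refined)), dtype=np.int64)
    if refined.size:  # re-enforce refractory after refinement
        keep = [0]
        for i in range(1, refined.size):
            if refined[i] - refined[keep[-1]] >= int(round(0.2 * fs)):
                keep.append(i)
        refined = refined[keep]
    return refined
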