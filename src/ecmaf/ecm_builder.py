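"""Electrocardiomatrix (ECM) image construction.

An ECM-image stacks ten beat-aligned 3.0 s ECG subsegments as matrix rows:
row *i* starts 0.5 s before the *i*:th R peak of a 10-beat window.  Each
1500-sample row (at 500 Hz) is downsampled in two sections - the 0.5 s
before the R peak at high rate (decimate by 4: 63 columns) to preserve
P-wave morphology, the remaining 2.496 s at low rate (decimate by 8:
156 columns) to keep only local rhythm patterns - yielding a 10x219
intensity image.  Windows are labeled AF when at least half of the
underlying segment is annotated AF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .ecg_core import AF, NONAF, ECGRecord, PreprocessConfig, RhythmInterval

log = logging.getLogger(__name__)

ECM_FS = 500.0          # working rate of the subsegment matrix
ROW_SAMPLES = 1500      # 3.0 s rows
PRE_R_SAMPLES = 250     # 0.5 s before the R peak
POST_LAST_SAMPLES = 1250  # 2.5 s after the last beat
N_BEATS = 10
N_ROWS = 10
N_COLS = 219
LEFT_COLS = 63
RIGHT_COLS = 156


@dataclass(frozen=True)
class DownsampleMap:
    """Two-section decimation grid mapping ECM columns to 500 Hz row offsets."""

    left_source_indices: np.ndarray = field(
        default_factory=lambda: np.arange(0, 252, 4, dtype=np.int64)
    )
    right_source_indices: np.ndarray = field(
        default_factory=lambda: np.arange(252, 1500, 8, dtype=np.int64)
    )

    def __post_init__(self) -> None:
        assert len(self.left_source_indices) == LEFT_COLS
        assert len(self.right_source_indices) == RIGHT_COLS

    @property
    def source_indices(self) -> np.ndarray:
        return np.concatenate([self.left_source_indices, self.right_source_indices])


@dataclass
class ECMWindow:
    """A 10-beat window: segment spans 0.5 s before R1 to 2.5 s after R10."""

    record_id: str
    channel: int
    beat_indices: np.ndarray  # the 10 R-peak sample indices (record time)
    segment_start: int
    segment_end: int  # exclusive
    label: str | None = None
    af_fraction: float | None = None

    def __post_init__(self) -> None:
        self.beat_indices = np.asarray(self.beat_indices, dtype=np.int64)
        if len(self.beat_indices) != N_BEATS:
            raise ValueError(f"window needs exactly {N_BEATS} beats")


@dataclass
class ECMImage:
    window: ECMWindow
    pixels: np.ndarray  # (10, 219) in mV
    row_time_offsets: np.ndarray  # per-row record sample of column 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (N_ROWS, N_COLS):
            raise ValueError(f"ECM image must be {N_ROWS}x{N_COLS}, got {self.pixels.shape}")


def segment_windows(
    beats: np.ndarray, record_len: int, fs: float, hop_beats: int
) -> list[ECMWindow]:
    """Enumerate 10-beat windows starting at beat 0, hop, 2*hop, ...

    Windows whose segment would fall outside the record are dropped.  A
    hop of 5 produces the overlapping training stream, 10 the
    non-overlapping testing stream.
    """
    if hop_beats not in (5, 10):
        raise ValueError("hop_beats must be 5 (training) or 10 (testing)")
    beats = np.asarray(beats, dtype=np.int64)
    if len(beats) < N_BEATS:
        log.info("fewer than %d beats: no windows", N_BEATS)
        return []
    pre = int(round(0.5 * fs))
    post = int(round(2.5 * fs))
    out = []
    for start in range(0, len(beats) - N_BEATS + 1, hop_beats):
        b = beats[start : start + N_BEATS]
        seg_start = int(b[0]) - pre
        seg_end = int(b[-1]) + post
        if seg_start < 0 or seg_end > record_len:
            log.debug("window at beat %d dropped: segment out of bounds", start)
            continue
        out.append(
            ECMWindow(
                record_id="", channel=0, beat_indices=b,
                segment_start=seg_start, segment_end=seg_end,
            )
        )
    return out


def extract_subsegments(rec: ECGRecord, window: ECMWindow, channel: int = 0) -> np.ndarray:
    """Stack the ten beat-aligned 3.0 s subsegments: row i = [Ri-250, Ri+1250)."""
    if not np.isclose(rec.fs, ECM_FS):
        raise ValueError(f"record must be at {ECM_FS:g} Hz, got {rec.fs:g}")
    x = rec.signal[channel]
    sub = np.empty((N_ROWS, ROW_SAMPLES), dtype=np.float64)
    for i, r in enumerate(window.beat_indices):
        lo = int(r) - PRE_R_SAMPLES
        hi = lo + ROW_SAMPLES
        if lo < 0 or hi > len(x):
            raise RuntimeError(
                f"subsegment [{lo},{hi}) outside record of length {len(x)}"
            )
        sub[i] = x[lo:hi]
    return sub


def downsample_two_section(sub: np.ndarray, antialias: bool = True) -> np.ndarray:
    """Two-section decimation of a (10, 1500) matrix to (10, 219).

    Each section is lowpass-filtered (zero-phase 8th-order Butterworth at
    0.4x the section's output rate) before subsampling; ``antialias=False``
    takes the raw source samples, which keeps the index map exact for
    inverse-mapping checks.
    """
    sub = np.asarray(sub, dtype=np.float64)
    if sub.shape != (N_ROWS, ROW_SAMPLES):
        raise ValueError(f"expected {(N_ROWS, ROW_SAMPLES)}, got {sub.shape}")
    dmap = DownsampleMap()
    if not antialias:
        return sub[:, dmap.source_indices]
    out = np.empty((N_ROWS, N_COLS), dtype=np.float64)
    for rate_out, cols, idx in (
        (125.0, slice(0, LEFT_COLS), dmap.left_source_indices),
        (62.5, slice(LEFT_COLS, N_COLS), dmap.right_source_indices),
    ):
        sos = sps.butter(8, 0.4 * rate_out, btype="lowpass", fs=ECM_FS, output="sos")
        filtered = sps.sosfiltfilt(sos, sub, axis=1)
        out[:, cols] = filtered[:, idx]
    return out


def label_window(window: ECMWindow, rhythm: list[RhythmInterval]) -> ECMWindow:
    """AF iff >= 50% of the segment's samples are annotated AF (uncovered = NONAF)."""
    seg_lo, seg_hi = window.segment_start, window.segment_end
    af_samples = 0
    for iv in rhythm:
        if iv.label == AF:
            af_samples += max(0, min(iv.offset, seg_hi) - max(iv.onset, seg_lo))
    frac = af_samples / (seg_hi - seg_lo)
    window.af_fraction = frac
    window.label = AF if frac >= 0.5 else NONAF
    return window


def build_ecm_dataset(
    rec: ECGRecord,
    channel: int = 0,
    hop_beats: int = 10,
    cfg: PreprocessConfig | None = None,
    antialias: bool = True,
) -> "ECMDataset":
    """Full chain on a preprocessed record: windows -> subsegments -> 10x219 -> labels."""
    cfg = cfg or PreprocessConfig()
    windows = segment_windows(rec.beats, rec.n_samples, rec.fs, hop_beats)
    images = []
    for w in windows:
        w.record_id = rec.record_id
        w.channel = channel
        sub = extract_subsegments(rec, w, channel)
        pix = np.clip(downsample_two_section(sub, antialias=antialias), -cfg.clip_mv, cfg.clip_mv)
        label_window(w, rec.rhythm)
        images.append(
            ECMImage(
                window=w,
                pixels=pix,
                row_time_offsets=w.beat_indices - PRE_R_SAMPLES,
            )
        )
    return ECMDataset.from_images(images)


@dataclass
class ECMDataset:
    """Array-of-images container with parallel label/metadata arrays."""

    pixels: np.ndarray        # (N, 10, 219)
    labels: np.ndarray        # (N,) of "AF"/"NONAF"
    af_fractions: np.ndarray  # (N,)
    record_ids: np.ndarray    # (N,)
    channels: np.ndarray      # (N,)
    beat_indices: np.ndarray  # (N, 10)
    segment_bounds: np.ndarray  # (N, 2)

    def __len__(self) -> int:
        return len(self.pixels)

    @classmethod
    def from_images(cls, images: list[ECMImage]) -> "ECMDataset":
        if not images:
            return cls(
                pixels=np.empty((0, N_ROWS, N_COLS)),
                labels=np.empty(0, dtype="U5"),
                af_fractions=np.empty(0),
                record_ids=np.empty(0, dtype="U64"),
                channels=np.empty(0, dtype=np.int64),
                beat_indices=np.empty((0, N_BEATS), dtype=np.int64),
                segment_bounds=np.empty((0, 2), dtype=np.int64),
            )
        return cls(
            pixels=np.stack([im.pixels for im in images]),
            labels=np.array([im.window.label or NONAF for im in images], dtype="U5"),
            af_fractions=np.array(
                [im.window.af_fraction if im.window.af_fraction is not None else 0.0
                 for im in images]
            ),
            record_ids=np.array([im.window.record_id for im in images], dtype="U64"),
            channels=np.array([im.window.channel for im in images], dtype=np.int64),
            beat_indices=np.stack([im.window.beat_indices for im in images]),
            segment_bounds=np.array(
                [[im.window.segment_start, im.window.segment_end] for im in images],
                dtype=np.int64,
            ),
        )

    def windows(self) -> list[ECMWindow]:
        return [
            ECMWindow(
                record_id=str(self.record_ids[i]),
                channel=int(self.channels[i]),
                beat_indices=self.beat_indices[i],
                segment_start=int(self.segment_bounds[i, 0]),
                segment_end=int(self.segment_bounds[i, 1]),
                label=str(self.labels[i]),
                af_fraction=float(self.af_fractions[i]),
            )
            for i in range(len(self))
        ]

    def subset(self, mask: np.ndarray) -> "ECMDataset":
        return ECMDataset(
            self.pixels[mask], self.labels[mask], self.af_fractions[mask],
            self.record_ids[mask], self.channels[mask], self.beat_indices[mask],
            self.segment_bounds[mask],
        )

    @staticmethod
    def concatenate(parts: list["ECMDataset"]) -> "ECMDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            return ECMDataset.from_images([])
        return ECMDataset(
            *[np.concatenate([getattr(p, f) for p in parts]) for f in (
                "pixels", "labels", "af_fractions", "record_ids", "channels",
                "beat_indices", "segment_bounds")]
        )

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, pixels=self.pixels, labels=self.labels,
            af_fractions=self.af_fractions, record_ids=self.record_ids,
            channels=self.channels, beat_indices=self.beat_indices,
            segment_bounds=self.segment_bounds,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ECMDataset":
        with np.load(path) as z:
            return cls(**{k: z[k] for k in z.files})

    def export_png(self, path: str | Path, index: int, clip_mv: float = 1.0) -> None:
        """Viewing-only export: [-clip, +clip] mV mapped to [0, 255] grayscale."""
        from PIL import Image

        pix = np.clip(self.pixels[index], -clip_mv, clip_mv)
        img = ((pix + clip_mv) / (2 * clip_mv) * 255).astype(np.uint8)
        Image.fromarray(img, mode="L").save(path)
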