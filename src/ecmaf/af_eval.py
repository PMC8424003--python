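"""Classification and EC57-style evaluation of AF detections.

Window-level confusion metrics (accuracy, sensitivity, specificity, PPV,
F1, normalized Matthews correlation), remapping of window decisions to a
per-sample label stream, extraction of maximal AF episodes, and the EC57
episode/duration statistics:

    Se_Epi  = TP_Epi / (TP_Epi + FN_Epi)      PPV_Epi = TP_Epi / (TP_Epi + FP_Epi)
    Se_Dur  = |T_AF ^ T^_AF| / |T_AF|          PPV_Dur = |T_AF ^ T^_AF| / |T^_AF|

where an annotated episode counts as detected if it overlaps at least one
detected sample (the permissive EC57 reading).  Metrics with a zero
denominator are reported as NaN, never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ecg_core import AF, NONAF
from .ecm_builder import ECMWindow

UNDEFINED = math.nan

DEFAULT_THRESHOLDS_S = (10.0, 15.0, 20.0, 30.0, 60.0, 90.0, 120.0, math.inf)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_from_labels(truth: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    return ConfusionCounts(
        TP=int(np.sum((truth == AF) & (predicted == AF))),
        TN=int(np.sum((truth == NONAF) & (predicted == NONAF))),
        FP=int(np.sum((truth == NONAF) & (predicted == AF))),
        FN=int(np.sum((truth == AF) & (predicted == NONAF))),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Acc, Se, Sp, PPV, F1 and normalized Mcc ((Mcc+1)/2), NaN when undefined."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else UNDEFINED
    return {
        "Acc": _ratio(tp + tn, c.total),
        "Se": _ratio(tp, tp + fn),
        "Sp": _ratio(tn, tn + fp),
        "PPV": _ratio(tp, tp + fp),
        "F1": _ratio(2 * tp, 2 * tp + fp + fn),
        "Mcc_norm": (mcc + 1) / 2 if not math.isnan(mcc) else UNDEFINED,
    }


# ---------------------------------------------------------------------------
# Sample streams and episodes
# ---------------------------------------------------------------------------

def remap_to_samples(
    decisions: list[tuple[ECMWindow, str]], record_len: int
) -> np.ndarray:
    """Per-sample boolean AF stream from window decisions.

    A sample covered by several windows is AF iff any covering window voted
    AF; uncovered samples are non-AF.
    """
    stream = np.zeros(record_len, dtype=bool)
    for window, label in decisions:
        if label == AF:
            lo = max(0, window.segment_start)
            hi = min(record_len, window.segment_end)
            stream[lo:hi] = True
    return stream


@dataclass(frozen=True)
class Episode:
    onset: int
    offset: int  # exclusive

    @property
    def duration(self) -> int:
        return self.offset - self.onset


def episodes_from_labels(stream: np.ndarray) -> list[Episode]:
    """Maximal runs of AF samples as half-open episodes."""
    stream = np.asarray(stream, dtype=bool)
    if stream.size == 0:
        return []
    edges = np.diff(stream.astype(np.int8))
    onsets = list(np.flatnonzero(edges == 1) + 1)
    offsets = list(np.flatnonzero(edges == -1) + 1)
    if stream[0]:
        onsets.insert(0, 0)
    if stream[-1]:
        offsets.append(len(stream))
    return [Episode(int(a), int(b)) for a, b in zip(onsets, offsets)]


def episodes_from_rhythm(rhythm, label: str = AF) -> list[Episode]:
    """Ground-truth episode set from a rhythm interval list."""
    return [Episode(iv.onset, iv.offset) for iv in rhythm if iv.label == label]


def _overlap(a: Episode, b: Episode) -> int:
    return max(0, min(a.offset, b.offset) - max(a.onset, b.onset))


@dataclass
class EC57Counts:
    TP_Epi: int
    FN_Epi: int
    FP_Epi: int
    T_AF: float       # seconds annotated
    T_AF_hat: float   # seconds detected
    overlap: float    # seconds of intersection


def ec57_counts(truth: list[Episode], detected: list[Episode], fs: float) -> EC57Counts:
    tp_epi = sum(1 for t in truth if any(_overlap(t, d) > 0 for d in detected))
    fp_epi = sum(1 for d in detected if all(_overlap(d, t) == 0 for t in truth))
    overlap = sum(_overlap(t, d) for t in truth for d in detected)
    return EC57Counts(
        TP_Epi=tp_epi,
        FN_Epi=len(truth) - tp_epi,
        FP_Epi=fp_epi,
        T_AF=sum(t.duration for t in truth) / fs,
        T_AF_hat=sum(d.duration for d in detected) / fs,
        overlap=overlap / fs,
    )


def ec57_metrics(truth: list[Episode], detected: list[Episode], fs: float) -> dict[str, float]:
    c = ec57_counts(truth, detected, fs)
    return {
        "Se_Epi": _ratio(c.TP_Epi, c.TP_Epi + c.FN_Epi),
        "PPV_Epi": _ratio(c.TP_Epi, c.TP_Epi + c.FP_Epi),
        "Se_Dur": _ratio(c.overlap, c.T_AF),
        "PPV_Dur": _ratio(c.overlap, c.T_AF_hat),
    }


def brief_episode_sensitivity(
    truth: list[Episode],
    detected: list[Episode],
    fs: float,
    thresholds_s: tuple[float, ...] = DEFAULT_THRESHOLDS_S,
) -> list[dict[str, float]]:
    """Se_Epi restricted to annotated episodes shorter than each threshold.

    The infinite bin covers all episodes; bins with no qualifying episode
    report NaN.  Episode counts per bin are cumulative by construction.
    """
    rows = []
    for d in thresholds_s:
        subset = [t for t in truth if t.duration / fs < d]
        n_hit = sum(1 for t in subset if any(_overlap(t, det) > 0 for det in detected))
        rows.append({
            "threshold_s": d,
            "n_episodes": len(subset),
            "Se_Epi": _ratio(n_hit, len(subset)),
        })
    return rows
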