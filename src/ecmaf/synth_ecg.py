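"""Seeded synthetic ECG generator with AF/NSR ground truth.

Emulates the two statistical signatures that separate atrial fibrillation
from normal sinus rhythm on the surface ECG: RR-interval irregularity
(i.i.d. log-normal RR draws with a large coefficient of variation during
AF versus a tight one during NSR) and atrial activity (a P wave before
every QRS in NSR, replaced during AF by a low-amplitude 4-10 Hz
fibrillatory sinusoid with jittered frequency).  Beats render a
sum-of-Gaussians P-QRS-T template; baseline wander and white noise are
added on top.  The generator returns exact beat positions and rhythm
intervals, so it doubles as ground truth for detector and classifier
tests.  It does not model ectopy, conduction abnormalities, electrode
artefacts, or realistic 12-lead projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ecg_core import AF, NONAF, ECGRecord, RhythmInterval

NSR = "NSR"

#: (amplitude mV, center offset s relative to R, width sigma s)
_TEMPLATE = {
    "P": (0.20, -0.17, 0.025),
    "Q": (-0.15, -0.025, 0.008),
    "R": (1.10, 0.0, 0.012),
    "S": (-0.25, 0.030, 0.010),
    "T": (0.25, 0.25, 0.040),
}


@dataclass
class MorphologyParams:
    """Rhythm statistics and waveform template parameters (mV, s, Hz)."""

    nsr_rr_mean: float = 0.8
    nsr_rr_cv: float = 0.03
    af_rr_mean: float = 0.6
    af_rr_cv: float = 0.20
    wave_amplitudes: dict = field(default_factory=lambda: {k: v[0] for k, v in _TEMPLATE.items()})
    wave_centers: dict = field(default_factory=lambda: {k: v[1] for k, v in _TEMPLATE.items()})
    wave_widths: dict = field(default_factory=lambda: {k: v[2] for k, v in _TEMPLATE.items()})
    f_wave_freq: float = 6.0
    f_wave_amp: float = 0.06
    baseline_amp: float = 0.05
    baseline_freq: float = 0.25
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.af_rr_cv <= self.nsr_rr_cv:
            raise ValueError("AF RR variability must exceed NSR RR variability")
        if not 4.0 <= self.f_wave_freq <= 10.0:
            raise ValueError("f-wave frequency must lie in [4, 10] Hz")
        for name, w in self.wave_widths.items():
            if w <= 0:
                raise ValueError(f"non-positive width for wave {name}")
        if self.f_wave_amp < 0 or self.noise_sd < 0 or self.baseline_amp < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class RhythmPlan:
    """Ordered (duration s, rhythm) schedule for one synthetic patient."""

    segments: list[tuple[float, str]]
    patient_id: str = "P000"
    seed: int = 0

    def __post_init__(self) -> None:
        for dur, rhythm in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if rhythm not in (NSR, AF):
                raise ValueError(f"rhythm must be NSR or AF, got {rhythm!r}")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)


def _lognormal_rr(rng: np.random.Generator, mean: float, cv: float) -> float:
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _rhythm_at(plan: RhythmPlan, t: float) -> str:
    acc = 0.0
    for dur, rhythm in plan.segments:
        acc += dur
        if t < acc:
            return rhythm
    return plan.segments[-1][1]


def generate_record(
    plan: RhythmPlan,
    morph: MorphologyParams | None = None,
    fs: float = 500.0,
    n_channels: int = 1,
) -> ECGRecord:
    """Render a synthetic record with exact beats and rhythm annotations.

    A beat whose RR interval straddles a rhythm transition belongs to the
    rhythm active at its R peak.
    """
    morph = morph or MorphologyParams()
    if fs < 250:
        raise ValueError("fs must be at least 250 Hz")
    rng = np.random.default_rng(plan.seed)
    total = plan.total_duration
    n = int(round(total * fs))
    t_axis = np.arange(n) / fs
    x = np.zeros(n)

    # beat placement driven by the rhythm active at each R peak
    beat_times: list[float] = []
    beat_rhythms: list[str] = []
    t = 0.3 + 0.1 * rng.random()  # first beat shortly after record start
    while t < total - 1e-9:
        rhythm = _rhythm_at(plan, t)
        beat_times.append(t)
        beat_rhythms.append(rhythm)
        if rhythm == NSR:
            t += _lognormal_rr(rng, morph.nsr_rr_mean, morph.nsr_rr_cv)
        else:
            t += _lognormal_rr(rng, morph.af_rr_mean, morph.af_rr_cv)

    # waveform rendering: sum-of-Gaussians per beat, P suppressed in AF.
    # Repolarization adapts to cycle length: the T wave contracts toward the
    # QRS as the following RR shortens (square-root rate correction).
    for i, (bt, rhythm) in enumerate(zip(beat_times, beat_rhythms)):
        rr_next = (
            beat_times[i + 1] - bt if i + 1 < len(beat_times) else morph.nsr_rr_mean
        )
        t_scale = min(1.0, np.sqrt(rr_next / morph.nsr_rr_mean))
        for name in ("P", "Q", "R", "S", "T"):
            if name == "P" and rhythm == AF:
                continue
            amp = morph.wave_amplitudes[name]
            c = bt + morph.wave_centers[name] * (t_scale if name == "T" else 1.0)
            w = morph.wave_widths[name] * (t_scale if name == "T" else 1.0)
            lo = max(0, int((c - 5 * w) * fs))
            hi = min(n, int((c + 5 * w) * fs) + 1)
            if hi > lo:
                x[lo:hi] += amp * np.exp(-0.5 * ((t_axis[lo:hi] - c) / w) ** 2)

    # rhythm annotation intervals from the plan boundaries
    rhythm_ivs: list[RhythmInterval] = []
    acc = 0.0
    for dur, rhythm in plan.segments:
        onset = int(round(acc * fs))
        acc += dur
        offset = min(int(round(acc * fs)), n)
        if offset > onset:
            label = AF if rhythm == AF else NONAF
            if rhythm_ivs and rhythm_ivs[-1].label == label and rhythm_ivs[-1].offset == onset:
                rhythm_ivs[-1] = RhythmInterval(rhythm_ivs[-1].onset, offset, label)
            else:
                rhythm_ivs.append(RhythmInterval(onset, offset, label))

    # fibrillatory baseline over AF stretches (frequency/amplitude jitter)
    for iv in rhythm_ivs:
        if iv.label != AF:
            continue
        seg = slice(iv.onset, iv.offset)
        freq = morph.f_wave_freq * (1 + 0.1 * rng.standard_normal())
        amp = morph.f_wave_amp * (1 + 0.2 * rng.standard_normal())
        phase = 2 * np.pi * rng.random()
        wobble = 0.15 * np.sin(2 * np.pi * 0.3 * t_axis[seg] + 2 * np.pi * rng.random())
        x[seg] += abs(amp) * np.sin(2 * np.pi * freq * t_axis[seg] * (1 + 0.02 * wobble) + phase)

    # baseline wander + white noise
    x += morph.baseline_amp * np.sin(
        2 * np.pi * morph.baseline_freq * t_axis + 2 * np.pi * rng.random()
    )
    x += morph.noise_sd * rng.standard_normal(n)

    sig = np.tile(x, (n_channels, 1))
    for ch in range(1, n_channels):
        sig[ch] = 0.8 * sig[ch] + morph.noise_sd * rng.standard_normal(n)

    beats = np.asarray(np.round(np.array(beat_times) * fs), dtype=np.int64)
    beats = beats[beats < n]
    rec = ECGRecord(
        record_id=plan.patient_id,
        channels=[f"ch{i + 1}" for i in range(n_channels)],
        signal=sig,
        fs=fs,
        beats=beats,
        rhythm=rhythm_ivs,
    )
    rec.validate()
    return rec


def generate_cohort(
    n_patients: int,
    plan_template: list[tuple[float, str]],
    seed: int = 0,
    morph: MorphologyParams | None = None,
    fs: float = 500.0,
) -> list[ECGRecord]:
    """Generate patients with seeded per-patient morphology jitter."""
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    base = morph or MorphologyParams()
    records = []
    ss = np.random.SeedSequence(seed)
    for i, child in enumerate(ss.spawn(n_patients)):
        rng = np.random.default_rng(child)
        amps = {
            k: v * float(1 + 0.1 * rng.standard_normal())
            for k, v in base.wave_amplitudes.items()
        }
        amps["P"] = abs(amps["P"])
        m = replace(
            base,
            wave_amplitudes=amps,
            nsr_rr_mean=base.nsr_rr_mean * float(1 + 0.08 * rng.standard_normal()),
            af_rr_mean=base.af_rr_mean * float(1 + 0.08 * rng.standard_normal()),
            f_wave_freq=float(np.clip(base.f_wave_freq * (1 + 0.08 * rng.standard_normal()), 4.0, 10.0)),
        )
        plan = RhythmPlan(
            segments=list(plan_template),
            patient_id=f"P{i:03d}",
            seed=int(rng.integers(2**31)),
        )
        records.append(generate_record(plan, m, fs=fs))
    return records


def generate_brief_af_plan(
    durations_s: list[float],
    gap_s: float = 30.0,
    seed: int = 0,
    pad_s: float = 30.0,
) -> RhythmPlan:
    """NSR background with AF insertions of exactly the requested durations,
    separated by at least ``gap_s`` of NSR."""
    segments: list[tuple[float, str]] = [(pad_s, NSR)]
    for i, d in enumerate(durations_s):
        if d <= 0:
            raise ValueError("AF insertion durations must be positive")
        if i > 0:
            segments.append((gap_s, NSR))
        segments.append((float(d), AF))
    segments.append((pad_s, NSR))
    return RhythmPlan(segments=segments, seed=seed)
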