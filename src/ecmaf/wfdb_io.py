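"""Minimal reader/writer for the PhysioNet WFDB format.

Supports what the AF pipeline needs: text headers, format-16 (little-endian
int16) and format-212 (packed 12-bit) signal files, and MIT annotation
files carrying beat marks and rhythm-change aux strings such as ``(AFIB``.
Writing emits format 16 only; the writers produce exactly the dialect the
readers parse, so synthetic fixtures round-trip bit-faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

# annotation codes (MIT table)
NORMAL = 1
RHYTHM = 28
_SKIP = 59
_NUM = 60
_SUB = 61
_CHN = 62
_AUX = 63

#: codes that mark a QRS detection of any morphology
BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 30, 34, 35, 38, 41})

_DEFAULT_GAIN = 200.0  # adu per mV


@dataclass
class Header:
    record_name: str
    fs: float
    n_samples: int
    channel_names: list[str]
    formats: list[int]
    gains: list[float]
    baselines: list[int]
    dat_files: list[str]


@dataclass
class Annotation:
    time: int  # sample index
    code: int
    aux: str | None = None


def read_header(path: Path) -> Header:
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    record_name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    names, fmts, gains, baselines, dats = [], [], [], [], []
    for i, ln in enumerate(lines[1 : 1 + n_sig]):
        tok = ln.split()
        dats.append(tok[0])
        fmts.append(int(tok[1].split("x")[0].split(":")[0].split("+")[0]))
        gain_tok = tok[2] if len(tok) > 2 else f"{_DEFAULT_GAIN:g}"
        gain_tok = gain_tok.split("/")[0]  # strip units
        if "(" in gain_tok:
            g, b = gain_tok.split("(")
            gains.append(float(g))
            baselines.append(int(b.rstrip(")")))
        else:
            gains.append(float(gain_tok) or _DEFAULT_GAIN)
            baselines.append(int(tok[4]) if len(tok) > 4 else 0)
        names.append(tok[8] if len(tok) > 8 else f"ch{i + 1}")
    return Header(record_name, fs, n_samples, names, fmts, gains, baselines, dats)


def read_signal(path: Path) -> tuple[Header, np.ndarray]:
    """Read header + signal, returning amplitudes in mV, shape (n_sig, n)."""
    path = Path(path)
    h = read_header(path)
    n_sig = len(h.channel_names)
    dat = path.parent / h.dat_files[0]
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    raw = dat.read_bytes()
    fmt = h.formats[0]
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2")
        flat = flat[: (len(flat) // n_sig) * n_sig]
        digital = flat.reshape(-1, n_sig).T.astype(np.int64)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int64)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s0 = np.where(s0 > 2047, s0 - 4096, s0)
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        flat = np.empty(2 * len(b), dtype=np.int64)
        flat[0::2], flat[1::2] = s0, s1
        flat = flat[: (len(flat) // n_sig) * n_sig]
        digital = flat.reshape(-1, n_sig).T
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    if h.n_samples:
        digital = digital[:, : h.n_samples]
    mv = np.empty(digital.shape, dtype=np.float64)
    for i in range(n_sig):
        mv[i] = (digital[i] - h.baselines[i]) / h.gains[i]
    return h, mv


def write_signal(
    path: Path, record_name: str, channels: list[str], signal_mv: np.ndarray, fs: float
) -> None:
    """Write a format-16 .dat + .hea pair; amplitudes quantized at 200 adu/mV."""
    path = Path(path)
    signal_mv = np.atleast_2d(signal_mv)
    n_sig, n = signal_mv.shape
    digital = np.clip(np.rint(signal_mv * _DEFAULT_GAIN), -32768, 32767).astype("<i2")
    dat_name = path.stem + ".dat"
    (path.parent / dat_name).write_bytes(digital.T.tobytes())
    lines = [f"{record_name} {n_sig} {fs:g} {n}"]
    for i, name in enumerate(channels):
        first = int(digital[i, 0]) if n else 0
        lines.append(f"{dat_name} 16 {_DEFAULT_GAIN:g}(0)/mV 16 0 {first} 0 0 {name}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")


def read_annotations(path: Path) -> list[Annotation]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"WFDB annotation file not found: {path}")
    data = path.read_bytes()
    out: list[Annotation] = []
    i, t = 0, 0
    pending_skip = 0
    while i + 1 < len(data):
        b0, b1 = data[i], data[i + 1]
        i += 2
        code = b1 >> 2
        interval = ((b1 & 3) << 8) | b0
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            # 4 following bytes: PDP-11 long (high word first, words LE)
            hi = data[i] | (data[i + 1] << 8)
            lo = data[i + 2] | (data[i + 3] << 8)
            i += 4
            v = (hi << 16) | lo
            if v >= 1 << 31:
                v -= 1 << 32
            pending_skip += v
        elif code == _AUX:
            n = interval
            s = data[i : i + n].rstrip(b"\x00").decode("latin-1")
            i += n + (n & 1)
            if out:
                out[-1].aux = s
        elif code in (_NUM, _SUB, _CHN):
            pass  # fields ignored by this pipeline
        else:
            t += interval + pending_skip
            pending_skip = 0
            out.append(Annotation(t, code))
    return out


def write_annotations(path: Path, anns: list[Annotation]) -> None:
    buf = bytearray()
    prev = 0
    for a in sorted(anns, key=lambda a: a.time):
        delta = a.time - prev
        prev = a.time
        if delta > 1023:
            buf += bytes([0, _SKIP << 2])
            hi, lo = (delta >> 16) & 0xFFFF, delta & 0xFFFF
            buf += bytes([hi & 0xFF, hi >> 8, lo & 0xFF, lo >> 8])
            delta = 0
        buf += bytes([delta & 0xFF, (a.code << 2) | (delta >> 8)])
        if a.aux:
            raw = a.aux.encode("latin-1")
            buf += bytes([len(raw) & 0xFF, (_AUX << 2) | (len(raw) >> 8)]) + raw
            if len(raw) & 1:
                buf += b"\x00"
    buf += bytes([0, 0])
    Path(path).write_bytes(bytes(buf))
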