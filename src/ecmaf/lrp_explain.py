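"""Layer-wise relevance propagation (epsilon rule) for the ECM classifier.

The winning class's score is propagated backward through the network: a
linear (or convolutional) neuron *n* with pre-activation
``z_n = sum_k a_k w_nk + b_n`` redistributes its relevance to input *k* in
proportion to ``a_k w_nk / (z_n + eps * sign(z_n))``; the stabilizer eps
absorbs part of the relevance, keeping the decomposition numerically sane
(eps = 1 is the working default).  ReLU passes relevance unchanged,
max-pooling routes each output's relevance to its winning input, and
batch-norm is folded into the adjacent convolution as its frozen inference
affine.  The result is a signed 10x219 relevance map which can be collapsed
into beat-relative "leftside" and record-time "rightside" traces by
reversing the ECM construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nnet import BatchNorm2d, Conv2d, Flatten, Linear, MaxPool2d, ReLU, softmax
from .cnn_classifier import NetworkModel
from .ecm_builder import (
    LEFT_COLS, N_COLS, N_ROWS, PRE_R_SAMPLES, DownsampleMap, ECMWindow,
)


@dataclass
class LRPConfig:
    epsilon: float = 1.0
    start: str = "softmax_output"  # or "logit"
    sign_stabilized: bool = True

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.start not in ("softmax_output", "logit"):
            raise ValueError("start must be 'softmax_output' or 'logit'")


@dataclass
class RelevanceMap:
    scores: np.ndarray          # (10, 219) signed relevance
    R_top: float                # initial relevance at the output
    winning_class: int          # 0 = AF, 1 = NONAF
    layer_sums: list[float] = field(default_factory=list)  # audit trail, top-down


@dataclass
class SideTraces:
    """Collapsed relevance: 63-point beat-relative leftside over [-0.5, 0) s,
    and a record-time rightside covering the segment (with coverage counts)."""

    leftside: np.ndarray
    rightside: np.ndarray       # len = segment length in samples; NaN = no coverage
    rightside_counts: np.ndarray
    segment_start: int
    segment_end: int


def _stabilize(z: np.ndarray, eps: float, signed: bool) -> np.ndarray:
    if signed:
        return z + eps * np.where(z >= 0, 1.0, -1.0)
    return z + eps


def lrp_epsilon(model: NetworkModel, image: np.ndarray, cfg: LRPConfig | None = None) -> RelevanceMap:
    """Propagate the winning class's score back to the 10x219 input pixels."""
    cfg = cfg or LRPConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image (normally {N_ROWS}x{N_COLS}), got {image.shape}")
    logits = model.forward_batch(image[None], training=False)[0]
    probs = softmax(logits[None])[0]
    winner = int(np.argmax(probs))
    r_top = float(probs[winner] if cfg.start == "softmax_output" else logits[winner])

    # group layers into relevance blocks: conv absorbs a following batch-norm
    blocks: list[tuple[str, object, object | None]] = []
    layers = model.layers
    i = 0
    while i < len(layers):
        layer = layers[i]
        if isinstance(layer, Conv2d):
            bn = layers[i + 1] if i + 1 < len(layers) and isinstance(layers[i + 1], BatchNorm2d) else None
            blocks.append(("conv", layer, bn))
            i += 2 if bn is not None else 1
        elif isinstance(layer, Linear):
            blocks.append(("linear", layer, None))
            i += 1
        elif isinstance(layer, MaxPool2d):
            blocks.append(("pool", layer, None))
            i += 1
        elif isinstance(layer, (ReLU, Flatten)):
            blocks.append(("pass", layer, None))
            i += 1
        else:  # pragma: no cover - architecture is fixed
            raise TypeError(f"no relevance rule for {type(layer).__name__}")

    r = np.zeros_like(logits)
    r[winner] = r_top
    r = r[None]
    sums = [r_top]
    for kind, layer, bn in reversed(blocks):
        if kind == "linear":
            a = layer.last_input                       # (1, K)
            z = layer.last_output                      # (1, N)
            s = r / _stabilize(z, cfg.epsilon, cfg.sign_stabilized)
            r = a * (s @ layer.params["w"])
        elif kind == "conv":
            a = layer.last_input
            if bn is not None:
                scale, _ = bn.inference_affine()
                w_eff = layer.params["w"] * scale[:, None, None, None]
                z = bn.last_output
            else:
                w_eff = layer.params["w"]
                z = layer.last_output
            s = r / _stabilize(z, cfg.epsilon, cfg.sign_stabilized)
            r = a * layer.input_grad(s, a, w=w_eff)
        elif kind == "pool":
            r = layer.scatter(r)
        elif kind == "pass" and isinstance(layer, Flatten):
            r = layer.backward(r)
        # ReLU: relevance passes through unchanged
        sums.append(float(r.sum()))
    scores = r[0, 0]
    return RelevanceMap(scores=scores, R_top=r_top, winning_class=winner, layer_sums=sums)


def collapse_sides(
    rmap: RelevanceMap,
    window: ECMWindow,
    dmap: DownsampleMap | None = None,
    fs: float = 500.0,
    absolute: bool = False,
) -> SideTraces:
    """Collapse the 10x219 map into leftside/rightside time-domain traces.

    Leftside: the rows are beat-aligned over the 0.5 s before each R peak,
    so the first 63 columns are averaged straight down the rows.  Rightside:
    each remaining pixel is mapped back to its record-time source sample via
    the downsample grid and the row's R-peak position; samples covered by
    several rows average their contributions.
    """
    dmap = dmap or DownsampleMap()
    scores = np.abs(rmap.scores) if absolute else rmap.scores
    leftside = scores[:, :LEFT_COLS].mean(axis=0)

    seg_lo, seg_hi = window.segment_start, window.segment_end
    length = seg_hi - seg_lo
    acc = np.zeros(length)
    cnt = np.zeros(length, dtype=np.int64)
    for i, r_peak in enumerate(window.beat_indices):
        row_t0 = int(r_peak) - PRE_R_SAMPLES
        t = row_t0 + dmap.right_source_indices - seg_lo
        ok = (t >= 0) & (t < length)
        np.add.at(acc, t[ok], scores[i, LEFT_COLS:][ok])
        np.add.at(cnt, t[ok], 1)
    rightside = np.full(length, np.nan)
    covered = cnt > 0
    rightside[covered] = acc[covered] / cnt[covered]
    return SideTraces(
        leftside=leftside, rightside=rightside, rightside_counts=cnt,
        segment_start=seg_lo, segment_end=seg_hi,
    )


def render_lrp(
    rmap: RelevanceMap,
    image: np.ndarray,
    traces: SideTraces,
    out_path,
    fs: float = 500.0,
) -> None:
    """Four-panel PNG: ECM-image, relevance heatmap (diverging, centered at
    0), rightside trace, leftside trace."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 1, figsize=(8, 10))
    axes[0].imshow(image, aspect="auto", cmap="gray", interpolation="nearest")
    axes[0].set_title("ECM-image")
    vmax = max(np.abs(rmap.scores).max(), 1e-12)
    im = axes[1].imshow(
        rmap.scores, aspect="auto", cmap="seismic", vmin=-vmax, vmax=vmax,
        interpolation="nearest",
    )
    axes[1].set_title("LRP-image")
    fig.colorbar(im, ax=axes[1])
    t = (np.arange(len(traces.rightside)) + traces.segment_start) / fs
    axes[2].plot(t, traces.rightside, lw=0.8)
    axes[2].set_title("rightside-LRP")
    axes[2].set_xlabel("record time (s)")
    tl = np.linspace(-0.5, 0, LEFT_COLS, endpoint=False)
    axes[3].plot(tl, traces.leftside, lw=1.0)
    axes[3].set_title("leftside-LRP")
    axes[3].set_xlabel("time before R peak (s)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
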