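# Methods

## The problem

Brief atrial-fibrillation (AF) episodes — under roughly 30 s — matter
clinically because they can precede sustained AF and raise stroke risk, yet
they are easy to miss in day-long ambulatory ECG. `ecmaf` implements an
image-based detector: the ECG around every run of 10 heartbeats is refolded
into a small beat-aligned matrix (an *electrocardiomatrix*, ECM), a compact
convolutional network classifies each matrix as AF or non-AF, window
decisions are mapped back to sample time, and detection quality is scored
with the EC57 episode/duration statistics. A layer-wise relevance
propagation (LRP) pass attributes each decision back to individual pixels,
so the features the network uses can be inspected against the two classical
AF signatures: irregular RR intervals and absent P waves.

## ECM construction

Input ECG is resampled to 500 Hz (polyphase rational resampling), baseline
wander is removed with a 4th-order Butterworth highpass at 0.5 Hz, and the
signal is clipped to ±1 mV. The Butterworth filter is applied
forward-backward: a causal IIR highpass cannot be linear-phase, so
zero-phase filtering is the only reading consistent with both "linear
phase" and "Butterworth"; the magnitude response is squared as a side
effect, which only sharpens the (already far-away) stopband.

From the beat list, windows of 10 consecutive beats are taken every 5 beats
(training, overlapping) or every 10 beats (testing, disjoint). The segment
spans 0.5 s before the first R peak to 2.5 s after the last. Ten 3.0 s
subsegments — row *i* starting 0.5 s before R_i — are stacked into a
10×1500 matrix and downsampled in two sections:

* columns 1–63: the 0.5 s before each R peak, decimated by 4 (125 Hz), to
  preserve P-wave morphology;
* columns 64–219: the remaining 2.496 s, decimated by 8 (62.5 Hz), keeping
  only local rhythm patterns.

The printed geometry (63 + 156 = 219 columns) is honored exactly; a literal
50 Hz right section would give 125 columns and break both the network input
size and the left/right LRP split, so the right-section rate is taken as
62.5 Hz. Each section is anti-alias filtered (zero-phase 8th-order
Butterworth at 0.4× the section's output rate, the standard decimation
cutoff) before subsampling; a no-filter mode exists so index-map tests stay
exact. Windows that would reach outside the record are dropped rather than
padded — padding would fabricate morphology. A window is labeled AF when at
least 50% of its segment samples (margins included) are annotated AF.

## Network and training

The classifier is the fixed small CNN

| layer | kernel (H,L,W) | stride | activations |
|---|---|---|---|
| input | – | – | 10×219×1 |
| conv 1 + BN + ReLU | (3,9,10) | (1,1) | 10×219×10 |
| max pool 1 | (3,3) | (1,2) | 10×110×10 |
| conv 2 + BN + ReLU | (3,9,15) | (1,1) | 10×110×15 |
| max pool 2 | (3,3) | (2,2) | 5×55×15 |
| conv 3 + BN + ReLU | (2,4,20) | (2,2) | 3×28×20 |
| fully connected + softmax | – | – | 2 |

for 10,217 trainable parameters. Two published table entries require
interpretation: conv 2 is listed with stride (1,2) but its output equals its
input's spatial size, so stride (1,1) is used — the only reading under which
the activation chain and the parameter count are self-consistent.
"Same"-style zero padding is resolved asymmetrically per layer so the
printed shapes are reproduced exactly; the shapes, not a padding formula,
are the contract.

Training is stochastic gradient descent with momentum 0.9, learning rate
0.01, L2 penalty 1e-4, 3 epochs, minimizing cross-entropy on the softmax
output. Classes are balanced by randomly discarding the surplus of the
larger class. Three networks are trained on three seeded patient-disjoint
80/20 splits (no patient contributes windows to both sides), and final
labels are the majority of the three votes. The layers are implemented
directly in NumPy (im2col convolutions, exact analytic gradients, verified
against central differences); weight initialization is seeded scaled-uniform
(fan-in). Batch size defaults to 256 at desk scale — the published 3,000
assumes millions of training images — and after the last epoch the
batch-norm running statistics are replaced by population statistics from one
full pass over the training data under the final weights, the same
finalization the original training toolbox performs; without it, few-step
training leaves inference statistics stale.

## Relevance propagation

Attribution starts from the winning class's softmax score (a logit start is
available) and walks backward. Linear and convolutional neurons
redistribute relevance to their inputs in proportion to the input's signed
contribution `a_k·w_nk` over the stabilized pre-activation
`z_n + ε·sign(z_n)`; the bias term stays in `z_n`, so part of the relevance
is absorbed rather than redistributed. The sign-stabilized denominator is
the standard safeguard against cancellation when `z_n < 0`; a plain `+ε`
mode is kept behind a flag. ε defaults to 1, a value that suppresses noise
contributions while retaining the dominant evidence. ReLU passes relevance
unchanged; max-pooling routes each output's relevance entirely to its
winning input (winner-take-all, which conserves relevance exactly); the
batch-norm affine is folded into the adjacent convolution before
redistribution, since normalization has no redistribution rule of its own.
At ε = 0 and zero biases the decomposition is exactly conservative, which
the tests verify to 1e-6.

The 10×219 relevance map is collapsed into two traces. The *leftside* trace
(63 points, [−0.5, 0) s before the R peak) is a plain column mean over the
ten rows, which are beat-aligned in this region by construction. The
*rightside* trace maps each remaining pixel back to its record-time source
sample via the downsample grid and the row's R position; samples covered by
several rows average their contributions (coverage-weighted). Signed
averaging is the default — negative relevance is informative — with an
absolute-value mode available.

## Evaluation

Window decisions are remapped to per-sample labels (a sample under any
AF-voting window is AF; uncovered samples are non-AF), maximal AF runs
become detected episodes, and scoring reports both window-level confusion
metrics (accuracy, sensitivity, specificity, PPV, F1, and Matthews
correlation rescaled to [0,1] via (Mcc+1)/2) and the EC57 statistics:
episode sensitivity/PPV (an annotated episode counts as detected if it
overlaps at least one detected sample — the permissive EC57 reading; no
merging of nearby detections is applied) and duration sensitivity/PPV
(intersection time over annotated/detected AF time). Brief-episode
sensitivity restricts Se_Epi to annotated episodes shorter than 10, 15, 20,
30, 60, 90, 120 s and all. Metrics with zero denominators are reported as
NaN, never coerced to 0 — silent zeros inflate nothing but hide one-class
degenerate inputs.

## Synthetic data

The generator emulates exactly the statistical structure the detector
exploits, with everything seeded:

* **Rhythm**: RR intervals are i.i.d. log-normal. NSR: mean 0.8 s, CV 0.03.
  AF: mean 0.6 s, CV 0.20, serially uncorrelated — an intentionally simple
  stand-in for atrioventricular-node models that still produces the
  irregularity signature.
* **Morphology**: each beat renders a sum-of-Gaussians P-QRS-T template
  (P: 0.2 mV at −170 ms; R: 1.1 mV; T: 0.25 mV at +250 ms). The T wave
  contracts toward the QRS as the following RR shortens (square-root rate
  correction), as real repolarization does — without this, T waves from
  short AF cycles leak into the pre-R window that the P-wave contrast tests
  measure. During AF the P wave is removed and a 4–10 Hz (default 6 Hz)
  fibrillatory sinusoid of 0.06 mV with jittered frequency/amplitude is
  added over the AF stretches.
* **Noise**: 0.25 Hz baseline wander (0.05 mV) and white noise (0.02 mV SD).
* **Cohorts**: per-patient seeded jitter of amplitudes, RR means, and f-wave
  frequency makes patients distinct, enabling honest patient-wise splits.
  A beat whose RR straddles a rhythm transition belongs to the rhythm active
  at its R peak.

What the generator does **not** model: ectopy and bigeminy (the main
real-world confounder), conduction abnormalities, electrode artefacts,
noise bursts, or realistic multi-lead projections. Passing tests therefore
demonstrate that the pipeline learns and attributes the two AF signatures
it was built around, not that real-data accuracy figures transfer.

## Desk-scale study conditions

The end-to-end checks train the three-split ensemble on a 20-patient
synthetic cohort (4-minute records alternating NSR and AF) and evaluate on
6 held-out patients whose records carry AF insertions of 8, 20, 45, and
90 s in an NSR background — the brief-episode strata of interest. At these
sizes a full run (generation, preprocessing, ECM construction, three
trainings, scoring) completes in a few minutes on one CPU. The engineering
bars — ≥0.90 held-out window accuracy, ≥80% of episodes ≥15 s detected —
are deliberately below published real-data figures, which require
multi-hundred-hour proprietary and PhysioNet corpora plus a commercial beat
detector; `scripts/afdb_pathway.py` reproduces the real-data pathway for
users who download the AFDB themselves, reporting rather than asserting its
numbers.

## Numerical and design notes

* 0-based sample indices and half-open `[onset, offset)` intervals
  everywhere; rescaled annotation bounds round to nearest sample, ties to
  even.
* WFDB aux rhythm strings: `(AFIB` → AF; everything else (including
  `(AFL`) → non-AF; unknown strings warn. The binary task deliberately
  folds atrial flutter into non-AF.
* The bundled beat detector (bandpass-energy thresholding with a 200 ms
  refractory period and a local amplitude refinement) is a deterministic
  stand-in for the commercial detector used on real data; every pipeline
  accepts externally supplied or ground-truth beat lists, which take
  precedence. Beat-detection accuracy is explicitly not the point of the
  method.
* Overlapping windows (training hop) resolve per-sample vote conflicts in
  favor of AF; test-time windows never overlap, so EC57 scoring is
  unaffected.
* Training computes in float32; attribution and conservation checks run in
  float64 end to end.
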