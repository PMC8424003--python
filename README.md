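# ecmaf — brief AF detection from electrocardiomatrix images

`ecmaf` detects brief episodes of atrial fibrillation (AF) in long-term ECG
by refolding the signal around every run of 10 heartbeats into a compact
beat-aligned image — the *electrocardiomatrix* (ECM) — and classifying each
image with a small convolutional network. It is aimed at physiological
signal-processing researchers who want an inspectable, fully seeded AF
detection pipeline that runs at desk scale, including an interpretability
pass that ties each decision back to the clinical AF signatures: irregular
RR intervals and absent P waves.

## Method in brief

1. **Preprocess**: resample to 500 Hz, zero-phase 4th-order Butterworth
   highpass at 0.5 Hz, clip to ±1 mV.
2. **ECM-images**: for each 10-beat window, stack ten 3 s subsegments (row
   *i* starts 0.5 s before R_i) and downsample in two sections — 125 Hz
   over the 0.5 s before each R peak (63 columns, morphology), 62.5 Hz over
   the rest (156 columns, rhythm) — giving a 10×219 image, labeled AF when
   ≥ 50 % of the segment is annotated AF.
3. **Classify**: a CNN (3 conv + batch-norm + ReLU stages, 2 max-pools, one
   fully connected layer; 10,217 trainable parameters) outputs softmax
   likelihoods (p_AF, p_nonAF). Three networks trained on patient-disjoint
   80/20 splits vote; the majority decides.
4. **Explain**: layer-wise relevance propagation with the ε-rule
   (R_k = Σ_n a_k·w_nk / (z_n + ε·sign z_n) · R_n, ε = 1) produces a signed
   10×219 relevance map, collapsed into beat-relative *leftside* and
   record-time *rightside* traces.
5. **Score**: window decisions are remapped to samples; maximal AF runs
   become episodes; reporting covers Acc/Se/Sp/PPV/F1/normalized Mcc and
   the EC57 statistics Se_Epi, PPV_Epi, Se_Dur = |T_AF ∩ T̂_AF|/|T_AF|,
   PPV_Dur = |T_AF ∩ T̂_AF|/|T̂_AF|, plus sensitivity stratified over
   episodes shorter than 10…120 s.

A seeded synthetic ECG generator (log-normal RR with rhythm-dependent
variability, sum-of-Gaussians P-QRS-T templates, fibrillatory baseline
during AF) provides ground-truth data for the whole pipeline; WFDB and CSV
records are read natively. See `docs/methods.md` for the model details and
design decisions.

## Worked example

```sh
ecmaf run --out runs/demo --seed 0
```

generates a 10-patient synthetic training cohort plus 4 held-out brief-AF
patients, trains the three-split ensemble, classifies the held-out records,
and ends with (abbreviated):

```
INFO ecmaf.cnn_classifier: split 0: validation accuracy 0.9788
INFO ecmaf.cnn_classifier: split 1: validation accuracy 0.9643
INFO ecmaf.cnn_classifier: split 2: validation accuracy 0.9310
{
  "Acc": 0.978021978021978,
  "Se": 1.0,
  "Sp": 0.9459459459459459,
  "PPV": 0.9642857142857143,
  "F1": 0.9818181818181818,
  "Mcc_norm": 0.97753590497526
}
artifacts in runs/demo
```

Validation accuracy is window-level accuracy of each network on its
held-out patients; the JSON block is the majority-vote confusion metrics on
the test patients' non-overlapping windows. `runs/demo/metrics.json` also
carries the EC57 scores — for this run Se_Epi = 1.0 and Se_Dur = 0.993
(all 16 synthetic AF insertions found, nearly their full duration) with
PPV_Dur = 0.903 (detected AF time slightly overshoots the annotation
boundaries) — and the per-duration-bin brief-episode table. The model
checkpoint and per-image votes land in `runs/demo/model/` and
`runs/demo/predictions.csv`.

Individual stages are available as `ecmaf synth / preprocess / build-ecm /
train / classify / explain / evaluate`; `ecmaf explain` writes the
four-panel figure (ECM-image, LRP heatmap, rightside/leftside traces).

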