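"""Shared fixtures: synthetic records and one desk-scale end-to-end run.

The expensive experiment (20-patient training cohort, 6 held-out brief-AF
patients, three-split ensemble) is session-scoped so every test that needs
a trained model shares the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecmaf import af_eval, cnn_classifier, ecg_core, ecm_builder, synth_ecg

TRAIN_PLAN = [(45.0, "NSR"), (60.0, "AF"), (45.0, "NSR"), (60.0, "AF"), (30.0, "NSR")]
BRIEF_AF_DURATIONS = [8.0, 20.0, 45.0, 90.0]
EXPERIMENT_SEED = 11


@pytest.fixture(scope="session")
def nsr_record():
    """60 s preprocessed normal-sinus-rhythm record with ground truth."""
    plan = synth_ecg.RhythmPlan([(60.0, "NSR")], patient_id="NSR0", seed=7)
    return ecg_core.preprocess(synth_ecg.generate_record(plan))


@pytest.fixture(scope="session")
def mixed_record():
    """Preprocessed record alternating NSR and AF."""
    plan = synth_ecg.RhythmPlan(
        [(40.0, "NSR"), (40.0, "AF"), (40.0, "NSR")], patient_id="MIX0", seed=9
    )
    return ecg_core.preprocess(synth_ecg.generate_record(plan))


@pytest.fixture(scope="session")
def experiment():
    """Full desk-scale study: train the three-split MoV ensemble on a
    20-patient synthetic cohort and classify 6 held-out brief-AF patients."""
    train_records = [
        ecg_core.preprocess(r)
        for r in synth_ecg.generate_cohort(20, TRAIN_PLAN, seed=EXPERIMENT_SEED)
    ]
    test_plan = synth_ecg.generate_brief_af_plan(
        BRIEF_AF_DURATIONS, gap_s=25.0, pad_s=25.0, seed=EXPERIMENT_SEED + 1
    )
    test_records = []
    for r in synth_ecg.generate_cohort(6, test_plan.segments, seed=EXPERIMENT_SEED + 1):
        r.record_id = "T" + r.record_id  # disjoint from training patient ids
        test_records.append(ecg_core.preprocess(r))

    cfg = cnn_classifier.TrainConfig(seed=EXPERIMENT_SEED)
    ensemble = cnn_classifier.train_three_splits(train_records, cfg, hop_beats=5)

    per_record = []
    truth_eps, detected_eps = [], []
    offset = 0
    all_truth, all_pred = [], []
    for rec in test_records:
        ds = ecm_builder.build_ecm_dataset(rec, hop_beats=10)
        labels, votes = cnn_classifier.mov_classify(ensemble, ds.pixels)
        all_truth.append(ds.labels)
        all_pred.append(labels)
        stream = af_eval.remap_to_samples(list(zip(ds.windows(), labels)), rec.n_samples)
        for e in af_eval.episodes_from_rhythm(rec.rhythm):
            truth_eps.append(af_eval.Episode(e.onset + offset, e.offset + offset))
        for e in af_eval.episodes_from_labels(stream):
            detected_eps.append(af_eval.Episode(e.onset + offset, e.offset + offset))
        offset += rec.n_samples + 1
        per_record.append((rec, ds, labels, votes))
    return {
        "ensemble": ensemble,
        "train_records": train_records,
        "test_records": test_records,
        "per_record": per_record,
        "truth": np.concatenate(all_truth),
        "predicted": np.concatenate(all_pred),
        "truth_episodes": truth_eps,
        "detected_episodes": detected_eps,
        "fs": 500.0,
    }
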