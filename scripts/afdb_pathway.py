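"""Evaluate the trained ensemble on locally downloaded MIT-BIH AFDB records.

This pathway needs data that is not bundled: download the MIT-BIH Atrial
Fibrillation Database from physionet.org (records as .hea/.dat/.atr plus
.qrs beat annotations) into a directory, then run::

    python scripts/afdb_pathway.py --afdb-dir /path/to/afdb \
        --model runs/model --channel 0 --out results/afdb.json

Numbers are reported, not asserted: the bundled models are trained on
synthetic data, so scores on real records are informative only.  Records
00735 and 03665 (rhythm-only) are skipped when present.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from ecmaf import af_eval, cnn_classifier, ecg_core, ecm_builder, wfdb_io

EXCLUDED = {"00735", "03665"}


def evaluate_record(path: Path, ens, channel: int) -> dict | None:
    rec = ecg_core.read_wfdb_record(path)
    qrs = path.with_suffix(".qrs")
    if rec.beats.size == 0 and qrs.exists():
        anns = wfdb_io.read_annotations(qrs)
        rec.beats = np.asarray(
            sorted({a.time for a in anns if a.code in wfdb_io.BEAT_CODES}), dtype=np.int64
        )
    rec = ecg_core.preprocess(rec)
    if rec.beats.size == 0:
        rec.beats = ecg_core.detect_beats(rec, channel)
    ds = ecm_builder.build_ecm_dataset(rec, channel=channel, hop_beats=10)
    if not len(ds):
        return None
    labels, _ = cnn_classifier.mov_classify(ens, ds.pixels)
    conf = af_eval.confusion_from_labels(ds.labels, labels)
    stream = af_eval.remap_to_samples(list(zip(ds.windows(), labels)), rec.n_samples)
    truth = af_eval.episodes_from_rhythm(rec.rhythm)
    detected = af_eval.episodes_from_labels(stream)
    return {
        "record": rec.record_id,
        "n_images": len(ds),
        "classification": af_eval.classification_metrics(conf),
        "ec57": af_eval.ec57_metrics(truth, detected, rec.fs),
        "brief": af_eval.brief_episode_sensitivity(truth, detected, rec.fs),
    }


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--afdb-dir", type=Path, required=True)
    parser.add_argument("--model", type=Path, required=True,
                        help="Ensemble directory from `ecmaf train`.")
    parser.add_argument("--channel", type=int, default=0)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    ens = cnn_classifier.load_ensemble(args.model)
    reports = []
    for hea in sorted(args.afdb_dir.glob("*.hea")):
        if hea.stem in EXCLUDED:
            continue
        report = evaluate_record(hea.with_suffix(""), ens, args.channel)
        if report:
            reports.append(report)
            print(f"{report['record']}: Acc={report['classification']['Acc']:.4f}")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(reports, indent=2))
    print(f"wrote {len(reports)} record reports to {args.out}")


if __name__ == "__main__":
    main()
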