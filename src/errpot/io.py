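"""Serialization of epoch sets, feature matrices and reports.

Epoch sets are stored as one ``.npy`` array per subject (trials x
channels x samples) plus a JSON sidecar with labels and geometry;
feature matrices as a delimited table (subject, label, feature columns)
plus a JSON layout sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import RawEpochSet
from .preprocessing import FeatureMatrix

__all__ = [
    "save_epochs", "load_epochs",
    "save_features", "load_features",
    "save_report",
]


def save_epochs(epochs: RawEpochSet, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = out_dir / epochs.subject_id
    np.save(base.with_suffix(".npy"), epochs.data)
    sidecar = {
        "subject_id": epochs.subject_id,
        "fs": epochs.fs,
        "channel_names": list(epochs.channel_names),
        "times": epochs.times.tolist(),
        "task_label": list(map(str, epochs.task_label)),
        "feedback_label": list(map(str, epochs.feedback_label)),
        "correctness": list(map(str, epochs.correctness)),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar))
    return base.with_suffix(".npy")


def load_epochs(base: str | Path) -> RawEpochSet:
    base = Path(base)
    if base.suffix:
        base = base.with_suffix("")
    meta = json.loads(base.with_suffix(".json").read_text())
    data = np.load(base.with_suffix(".npy"))
    return RawEpochSet(
        subject_id=meta["subject_id"], fs=meta["fs"],
        channel_names=tuple(meta["channel_names"]),
        times=np.array(meta["times"]), data=data,
        task_label=np.array(meta["task_label"], dtype=object),
        feedback_label=np.array(meta["feedback_label"], dtype=object),
        correctness=np.array(meta["correctness"], dtype=object),
    )


def save_features(features: list[FeatureMatrix], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for fm in features:
        df = pd.DataFrame(fm.X, columns=[f"f{i}" for i in range(fm.X.shape[1])])
        df.insert(0, "y", fm.y.astype(str))
        df.insert(0, "subject_id", fm.subject_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    layout = {"feature_layout": [[ch, int(b)]
                                 for ch, b in features[0].feature_layout]}
    path.with_suffix(".layout.json").write_text(json.dumps(layout))
    return path


def load_features(path: str | Path) -> list[FeatureMatrix]:
    path = Path(path)
    df = pd.read_csv(path)
    layout = json.loads(path.with_suffix(".layout.json").read_text())
    feature_layout = [(ch, int(b)) for ch, b in layout["feature_layout"]]
    out = []
    cols = [c for c in df.columns if c.startswith("f")]
    for sid, grp in df.groupby("subject_id", sort=False):
        out.append(FeatureMatrix(
            subject_id=str(sid), X=grp[cols].to_numpy(float),
            y=grp["y"].to_numpy(object), feature_layout=feature_layout))
    return out


def save_report(report, out_dir: str | Path) -> Path:
    """Write a MetricsReport as a per-subject table + JSON bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"{report.pipeline}_{report.classifier}_{report.label_mode}".replace("/", "-")
    csv_path = out_dir / f"{tag}.csv"
    report.to_frame().to_csv(csv_path)
    bundle = {
        "pipeline": report.pipeline,
        "classifier": report.classifier,
        "label_mode": report.label_mode,
        "subjects": report.subjects,
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
        "weighted_f1": report.weighted_f1,
        "confusion": report.confusion,
    }
    (out_dir / f"{tag}.json").write_text(json.dumps(bundle, indent=1))
    return csv_path
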