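"""Plain-text file formats: recordings as TSV with a JSON ground-truth
sidecar, epochs as JSON records plus long-format TSV samples, feature tables
as TSV, results as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording, TrialGroundTruth, Epoch, EpochSet, CHANNEL_NAMES


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_recording(
    base: Path | str,
    recording: Recording,
    ground_truth: TrialGroundTruth | None = None,
    metadata: dict | None = None,
) -> tuple[Path, Path]:
    """Write ``<base>.tsv`` (header C1..C8, one row per sample) and
    ``<base>.json`` (labels, ground truth, metadata)."""
    base = Path(base)
    tsv = base.with_suffix(".tsv")
    df = pd.DataFrame(recording.samples, columns=list(recording.channel_names))
    df.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    sidecar = {
        "fs": recording.fs,
        "subject_id": recording.subject_id,
        "group": recording.group,
        "trial_id": recording.trial_id,
        "channel_names": list(recording.channel_names),
        "ground_truth": None
        if ground_truth is None
        else {
            "intervals": {
                ch: [list(iv) for iv in ivals]
                for ch, ivals in ground_truth.intervals.items()
            },
            "sub_threshold": ground_truth.sub_threshold,
        },
        "metadata": metadata or {},
    }
    jpath = base.with_suffix(".json")
    jpath.write_text(json.dumps(sidecar, indent=1))
    return tsv, jpath


def read_recording(tsv: Path | str) -> tuple[Recording, TrialGroundTruth | None]:
    """Read a recording TSV and its JSON sidecar (if present)."""
    tsv = Path(tsv)
    df = pd.read_csv(tsv, sep="\t")
    sidecar_path = tsv.with_suffix(".json")
    fs, subject, group, trial = 1000.0, "", "", 0
    gt = None
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        fs = side.get("fs", 1000.0)
        subject = side.get("subject_id", "")
        group = side.get("group", "")
        trial = side.get("trial_id", 0)
        raw_gt = side.get("ground_truth")
        if raw_gt is not None:
            gt = TrialGroundTruth(
                intervals={
                    ch: [tuple(iv) for iv in ivals]
                    for ch, ivals in raw_gt["intervals"].items()
                },
                sub_threshold=raw_gt.get("sub_threshold", False),
            )
    names = tuple(df.columns)
    if set(CHANNEL_NAMES) <= set(names):
        df = df[list(CHANNEL_NAMES)]
        names = CHANNEL_NAMES
    rec = Recording(
        samples=df.to_numpy(dtype=float),
        fs=fs,
        channel_names=names,
        subject_id=subject,
        group=group,
        trial_id=trial,
    )
    return rec, gt


def write_epochs(base: Path | str, epoch_set: EpochSet) -> tuple[Path, Path]:
    """Write epoch metadata as JSON records and samples as long-format TSV
    keyed by record id."""
    base = Path(base)
    records = []
    frames = []
    for rid, ep in enumerate(epoch_set):
        records.append(
            {
                "record_id": rid,
                "subject": ep.subject_id,
                "group": ep.group,
                "trial": ep.trial_id,
                "channel": ep.channel,
                "start_sample": ep.start_sample,
                "end_sample": ep.end_sample,
            }
        )
        frames.append(
            pd.DataFrame(
                {"record_id": rid, "sample_index": np.arange(len(ep)),
                 "value": ep.samples}
            )
        )
    jpath = base.with_suffix(".json")
    jpath.write_text(
        json.dumps(
            {
                "records": records,
                "normalization_divisors": {
                    f"{s}|{c}": d
                    for (s, c), d in epoch_set.normalization_divisors.items()
                },
            },
            indent=1,
        )
    )
    tsv = Path(str(base) + "_samples.tsv")
    if frames:
        pd.concat(frames).to_csv(tsv, sep="\t", index=False, float_format="%.8g")
    else:
        tsv.write_text("record_id\tsample_index\tvalue\n")
    return jpath, tsv


def read_epochs(base: Path | str) -> EpochSet:
    base = Path(base)
    side = json.loads(base.with_suffix(".json").read_text())
    samples = pd.read_csv(Path(str(base) + "_samples.tsv"), sep="\t")
    by_id = {int(k): g["value"].to_numpy(dtype=float)
             for k, g in samples.groupby("record_id")}
    out = EpochSet()
    for rec in side["records"]:
        out.epochs.append(
            Epoch(
                samples=by_id.get(rec["record_id"], np.empty(0)),
                channel=rec["channel"],
                start_sample=rec["start_sample"],
                end_sample=rec["end_sample"],
                subject_id=rec["subject"],
                group=rec["group"],
                trial_id=rec["trial"],
            )
        )
    for key, d in side.get("normalization_divisors", {}).items():
        s, c = key.split("|")
        out.normalization_divisors[(s, c)] = d
    return out


def write_feature_table(path: Path | str, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_feature_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def write_json(path: Path | str, payload: dict, config: dict | None = None) -> Path:
    """Write a result JSON, embedding the configuration hash."""
    path = Path(path)
    body = dict(payload)
    if config is not None:
        body["config_hash"] = config_hash(config)
    path.write_text(json.dumps(body, indent=1, default=_jsonify, sort_keys=True))
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
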