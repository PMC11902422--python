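"""End-to-end orchestration: simulate -> preprocess/detect -> features ->
select -> evaluate, with one root seed feeding named sub-streams so each
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet, Recording, TrialGroundTruth, CHANNEL_NAMES
from .detection import SampEnParams, detect_trial
from .evaluation import CVConfig, CVResult, crossval, evaluation_report, MODEL_NAMES
from .features import (FEATURE_NAMES, F12B_FEATURES, feature_table,
                       standardize_table)
from .preprocessing import normalize_epochs
from .selection import SelectionConfig, StagedFeatureReducer
from .synthetic import ClassEffects, generate_cohort

logger = logging.getLogger("isoemg")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one (JSON round-trippable) place."""

    seed: int = 0
    fs: float = 1000.0
    n_amateur: int = 5
    n_professional: int = 5
    n_trials: int = 5
    n_cycles: int = 6
    class_effects: ClassEffects = field(default_factory=ClassEffects)
    detector: SampEnParams = field(default_factory=SampEnParams)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    cv_folds: int = 10
    cv_repeats: int = 20
    models: tuple[str, ...] = MODEL_NAMES
    channels: tuple[str, ...] = CHANNEL_NAMES

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("class_effects"), dict):
            d["class_effects"] = ClassEffects(**d["class_effects"])
        if isinstance(d.get("detector"), dict):
            d["detector"] = SampEnParams(**d["detector"])
        if isinstance(d.get("selection"), dict):
            d["selection"] = SelectionConfig(**d["selection"])
        for key in ("models", "channels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))


def simulate_cohort(config: PipelineConfig):
    """Stage 1: generate the synthetic cohort (see :mod:`isoemg.synthetic`)."""
    return generate_cohort(
        n_amateur=config.n_amateur,
        n_professional=config.n_professional,
        class_effects=config.class_effects,
        n_trials=config.n_trials,
        seed=config.seed,
        fs=config.fs,
        n_cycles=config.n_cycles,
    )


def detect_cohort(
    trials: list[tuple[Recording, TrialGroundTruth]],
    params: SampEnParams | None = None,
) -> tuple[EpochSet, dict]:
    """Stage 2: filter, detect and normalize epochs for a list of trials.

    Epoch amplitudes are normalized per (subject, channel) across all of
    that subject's trials.  Returns the normalized epoch set and a log with
    per-channel accepted-epoch counts per subject.
    """
    params = params or SampEnParams()
    per_subject: dict[str, EpochSet] = {}
    log: dict = {"per_trial": [], "counts": {}}
    for rec, _gt in trials:
        eps, tlog = detect_trial(rec, params)
        per_subject.setdefault(rec.subject_id, EpochSet()).extend(eps)
        log["per_trial"].append(
            {
                "subject": rec.subject_id,
                "trial": rec.trial_id,
                "intervals": tlog["intervals"],
            }
        )
    merged = EpochSet()
    for subject, eps in per_subject.items():
        if len(eps) == 0:
            logger.warning("subject %s: no epochs detected", subject)
            continue
        merged.extend(normalize_epochs(eps))
    counts: dict[str, dict[str, int]] = {}
    for ep in merged:
        counts.setdefault(ep.subject_id, {}).setdefault(ep.channel, 0)
        counts[ep.subject_id][ep.channel] += 1
    log["counts"] = counts
    return merged, log


def epoch_counts_per_channel(epoch_set: EpochSet) -> dict[str, int]:
    """Accepted epochs per channel, summed over subjects and trials."""
    out: dict[str, int] = {ch: 0 for ch in CHANNEL_NAMES}
    for ep in epoch_set:
        out[ep.channel] = out.get(ep.channel, 0) + 1
    return out


def extract_features(epoch_set: EpochSet, fs: float) -> pd.DataFrame:
    """Stage 3: 63-value feature vector per epoch, standardized per
    (feature, channel).  Returns the standardized table."""
    table = feature_table(epoch_set, fs)
    if table.empty:
        logger.warning("empty feature table: no epochs to featurize")
        return table
    std_table, _scaler = standardize_table(table)
    return std_table


def evaluate_groups(
    table: pd.DataFrame,
    feature_groups: dict[str, tuple[str, ...]],
    channels: tuple[str, ...],
    models: tuple[str, ...],
    folds: int = 10,
    repeats: int = 20,
    seed: int = 0,
) -> dict[tuple[str, str, str], CVResult]:
    """Stage 5: repeated stratified CV per (channel, feature group, model)."""
    results: dict[tuple[str, str, str], CVResult] = {}
    for ch in channels:
        sub = table[table["channel"] == ch]
        y = (sub["group"] == "professional").to_numpy()
        for grp_name, feats in feature_groups.items():
            X = sub[list(feats)].to_numpy(dtype=float)
            for model in models:
                cfg = CVConfig(
                    folds=folds,
                    repeats=repeats,
                    shuffle_seed=(seed * 1009 + hash((ch, grp_name, model)) % 9973)
                    % (2**31 - 1),
                    model=model,
                )
                results[(ch, grp_name, model)] = crossval(X, y, cfg)
    return results


def run_pipeline(config: PipelineConfig, out_dir: Path | str | None = None) -> dict:
    """Run the full pipeline; optionally write per-stage artifacts.

    Returns a dict with the epoch set, feature table, selection results for
    Methods A and B, the CV report, and stage logs.
    """
    from . import io as iom  # local import to keep module load light

    trials, meta = simulate_cohort(config)
    epoch_set, det_log = detect_cohort(trials, config.detector)
    table = extract_features(epoch_set, config.fs)

    artifacts: dict = {
        "cohort_metadata": meta,
        "epoch_set": epoch_set,
        "detection_log": det_log,
        "feature_table": table,
        "epoch_counts": epoch_counts_per_channel(epoch_set),
    }
    if table.empty:
        logger.warning("pipeline finished with 0 epochs; skipping selection "
                       "and evaluation")
        artifacts["selection"] = None
        artifacts["report"] = evaluation_report({})
        return artifacts

    selections = {}
    for method in ("A", "B"):
        reducer = StagedFeatureReducer(
            method=method,
            icc_threshold=config.selection.icc_threshold,
            alpha=config.selection.alpha,
            min_significant_channels=config.selection.min_significant_channels,
            target_size=config.selection.target_size,
        )
        reducer.fit(table)
        selections[method] = reducer.result_
    artifacts["selection"] = selections

    groups = {
        "F63": FEATURE_NAMES,
        f"F{config.selection.target_size}A": selections["A"].selected,
        f"F{config.selection.target_size}B": selections["B"].selected,
    }
    results = evaluate_groups(
        table,
        groups,
        channels=config.channels,
        models=config.models,
        folds=config.cv_folds,
        repeats=config.cv_repeats,
        seed=config.seed,
    )
    artifacts["cv_results"] = results
    artifacts["report"] = evaluation_report(results)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = config.to_dict()
        iom.write_feature_table(out / "features.tsv", table)
        iom.write_json(out / "detection_log.json", det_log, cfg)
        iom.write_json(
            out / "selection.json",
            {m: r.to_dict() for m, r in selections.items()},
            cfg,
        )
        iom.write_json(out / "report.json", artifacts["report"], cfg)
        (out / "config.json").write_text(config.to_json())
    return artifacts


#: Fallback evaluation feature set when selection cannot run (e.g. a null
#: cohort where no feature separates the groups): the standard compact
#: 12-feature group.
DEFAULT_FEATURE_GROUP = F12B_FEATURES
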