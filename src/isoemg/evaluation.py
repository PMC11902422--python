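"""Repeated stratified 10-fold cross-validated classification and the
comparison statistics used to judge feature groups.

Four classifier families are evaluated per (channel, feature group): linear
discriminant analysis (LDA), a quadratic-kernel SVM ("SVM2"), an RBF-kernel
SVM ("SVMcore") and a subspace-discriminant ensemble (random feature
subspaces of size ceil(d/2), 30 LDA learners, vote by averaged posterior).
Accuracy is the fold-mean of (TP + TN) / (P + N); it is held as a fraction
internally and multiplied by 100 only for display.

Feature-group comparisons use the absolute decibel transform of a
two-sample t-test p-value, dB = |log10 p|; dB <= 1.301 (p >= 0.05) means no
significant difference.  Within one group and channel, differences among the
12 selected features are assessed with a one-way ANOVA followed by Tukey's
HSD when significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

MODEL_NAMES = ("LDA", "SVM2", "SVMcore", "Subspace")

NO_DIFFERENCE_DB = 1.301  # |log10 0.05|


@dataclass
class CVConfig:
    folds: int = 10
    repeats: int = 20
    stratified: bool = True
    shuffle_seed: int = 0
    model: str = "SVM2"

    def __post_init__(self) -> None:
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")
        if self.model not in MODEL_NAMES:
            raise ValueError(f"model must be one of {MODEL_NAMES}")


@dataclass
class CVResult:
    """Per-repeat accuracies with their mean and standard deviation."""

    accuracies: np.ndarray  # one value per repeat (fraction in [0, 1])
    fold_counts: list[dict]  # per-fold {"tp", "tn", "p", "n"} of every repeat
    mean: float
    std: float
    config: dict = field(default_factory=dict)

    def percent(self) -> tuple[float, float]:
        """(mean, std) on the 0-100 display scale."""
        return 100.0 * self.mean, 100.0 * self.std


def make_model(name: str, seed: int = 0, n_features: int | None = None):
    """Instantiate one of the four classifier families with fixed, recorded
    hyperparameters."""
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "SVM2":
        return SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=1.0)
    if name == "SVMcore":
        return SVC(kernel="rbf", gamma="scale", C=1.0)
    if name == "Subspace":
        d = n_features or 2
        return BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=30,
            max_samples=1.0,
            max_features=max(1, math.ceil(d / 2)),
            bootstrap=False,
            bootstrap_features=False,
            random_state=seed,
        )
    raise ValueError(f"unknown model {name!r}")


def crossval(X: np.ndarray, y: np.ndarray, config: CVConfig | None = None) -> CVResult:
    """Repeated stratified K-fold cross-validation of one model.

    Each repeat reshuffles with a seed derived from ``shuffle_seed`` and the
    repeat index, stratifies by class, and averages the per-fold accuracy
    (TP + TN) / (P + N).  Deterministic for fixed data and seed.
    """
    config = config or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need 2 classes, found {len(classes)}")
    if counts.min() < config.folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than "
            f"{config.folds} folds"
        )
    positive = classes[1]

    acc = np.empty(config.repeats)
    fold_counts: list[dict] = []
    for rep in range(config.repeats):
        seed = (config.shuffle_seed * 100_003 + rep) % (2**31 - 1)
        splitter = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=seed
        )
        fold_acc = np.empty(config.folds)
        for k, (tr, te) in enumerate(splitter.split(X, y)):
            model = make_model(config.model, seed=seed, n_features=X.shape[1])
            model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
            truth = y[te]
            tp = int(np.sum((truth == positive) & (pred == positive)))
            tn = int(np.sum((truth != positive) & (pred != positive)))
            pos = int(np.sum(truth == positive))
            neg = int(np.sum(truth != positive))
            fold_acc[k] = (tp + tn) / (pos + neg)
            fold_counts.append(
                {"repeat": rep, "fold": k, "tp": tp, "tn": tn, "p": pos, "n": neg}
            )
        acc[rep] = fold_acc.mean()
    return CVResult(
        accuracies=acc,
        fold_counts=fold_counts,
        mean=float(acc.mean()),
        std=float(acc.std(ddof=1)) if config.repeats > 1 else 0.0,
        config=asdict(config),
    )


def p_to_db(p: float) -> float:
    """Decibel transform of a p-value: dB = |log10 p| (0 at p = 1, 1.301 at
    p = 0.05)."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    return abs(math.log10(p))


@dataclass
class SignificanceResult:
    p_value: float
    db: float
    no_difference: bool


def significance_db(acc_a: np.ndarray, acc_b: np.ndarray) -> SignificanceResult:
    """|log10 p| of a two-sample t-test between two accuracy collections.

    Identical zero-variance collections take the p = 1 path (dB = 0).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 accuracies per collection")
    if np.std(a) == 0 and np.std(b) == 0 and np.allclose(a.mean(), b.mean()):
        p = 1.0
    else:
        p = float(spstats.ttest_ind(a, b, equal_var=True).pvalue)
        if not np.isfinite(p):
            p = 1.0
    db = p_to_db(p) if p > 0 else float("inf")
    return SignificanceResult(p_value=p, db=db, no_difference=db <= NO_DIFFERENCE_DB)


def anova_tukey(
    table: pd.DataFrame, feature_names: list[str], alpha: float = 0.05
) -> dict:
    """One-way ANOVA across feature columns, Tukey HSD post hoc if significant.

    Observations are epochs; groups are the (standardized) features.  The
    Tukey matrix is symmetric with NaN on the diagonal (a feature is not
    compared with itself).
    """
    cols = [table[f].to_numpy(dtype=float) for f in feature_names]
    cols = [c[np.isfinite(c)] for c in cols]
    if any(len(c) < 2 for c in cols):
        raise ValueError("every feature column needs at least 2 finite values")
    if all(np.std(c) == 0 for c in cols):
        raise ValueError("degenerate variance: ANOVA undefined")
    anova = spstats.f_oneway(*cols)
    out = {
        "anova_p": float(anova.pvalue),
        "anova_F": float(anova.statistic),
        "significant": bool(anova.pvalue < alpha),
        "tukey_p": None,
    }
    if out["significant"]:
        tk = spstats.tukey_hsd(*cols)
        m = np.array(tk.pvalue, dtype=float)
        np.fill_diagonal(m, np.nan)
        out["tukey_p"] = pd.DataFrame(m, index=feature_names, columns=feature_names)
    return out


def evaluation_report(results: dict[tuple[str, str, str], CVResult]) -> dict:
    """Aggregate CV results keyed by (channel, feature_group, model).

    Produces per-cell rows plus a (feature group x model) summary whose mean
    and SD pool the per-repeat accuracies across channels (pooling mode
    recorded in the header).  Empty input yields an empty report.
    """
    cells = [
        {
            "channel": ch,
            "feature_group": grp,
            "model": model,
            "mean": res.mean,
            "std": res.std,
            "n_repeats": len(res.accuracies),
        }
        for (ch, grp, model), res in sorted(results.items())
    ]
    summary: dict[str, dict[str, dict[str, float]]] = {}
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    for (ch, grp, model), res in results.items():
        pooled.setdefault((grp, model), []).append(res.accuracies)
    for (grp, model), accs in sorted(pooled.items()):
        allacc = np.concatenate(accs)
        summary.setdefault(grp, {})[model] = {
            "mean": float(allacc.mean()),
            "std": float(allacc.std(ddof=1)) if len(allacc) > 1 else 0.0,
        }
    return {
        "aggregation": "mean/SD over channels x repeats",
        "n_cells": len(cells),
        "cells": cells,
        "summary": summary,
        "warning": "empty report" if not cells else "",
    }
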