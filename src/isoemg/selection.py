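"""Staged feature reduction from consistency (ICC) and group-difference
(two-sample t-test) statistics.

Stage 1 removes features that are not broadly discriminative: a feature
survives only if the two-sample t-test rejects (H = 1) in at least
``min_significant_channels`` of the consulted channels.  Stage 2 removes
redundancy: features are grouped by pairwise one-way intraclass correlation
above a threshold (default 0.8) and only one representative per group — the
feature with the lowest mean p-value over the consulted channels — is kept.
Stage 3 prunes to a fixed target size (default 12) by keeping the features
with the lowest mean p-value.

Two method variants differ only in the consulted channel set: Method A uses
all channels, Method B excludes C6 (a channel whose group differences are
unreliable) from every p-value/H-value condition, so Method B's output is
invariant to arbitrary corruption of C6 statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .features import FEATURE_NAMES

DEFAULT_ICC_THRESHOLD = 0.8
DEFAULT_ALPHA = 0.05


# --------------------------------------------------------------------------
# ICC

def icc_oneway(data: np.ndarray) -> float:
    """One-way random-effects, single-rater ICC of an (n_targets, k_raters)
    table, from the ANOVA mean squares:

        ICC(1) = (MSB - MSW) / (MSB + (k - 1) MSW)

    Can be negative when within-target disagreement exceeds between-target
    variance.
    """
    y = np.asarray(data, dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    grand = y.mean()
    row_means = y.mean(axis=1)
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((y - row_means[:, None]) ** 2) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return float("nan")
    return float((msb - msw) / denom)


def average_across_channels(table: pd.DataFrame) -> pd.DataFrame:
    """Average each epoch's features over the channels that recorded it.

    Epochs are aligned across channels by their rank within (subject,
    trial, channel); the result has one row per epoch slot and the 63
    feature columns.
    """
    t = table.copy()
    t["_slot"] = t.groupby(["subject", "trial", "channel"], observed=True).cumcount()
    avg = (
        t.groupby(["subject", "trial", "_slot"], observed=True)[list(FEATURE_NAMES)]
        .mean()
        .reset_index(drop=True)
    )
    return avg


@dataclass
class ConsistencyMatrix:
    """Pairwise one-way ICC over the 63 features (diagonal = 1)."""

    values: pd.DataFrame  # 63 x 63, feature names on both axes
    threshold: float = DEFAULT_ICC_THRESHOLD

    def groups(self, features: list[str] | None = None) -> list[list[str]]:
        """Greedy consistency groups of the ICC > threshold relation.

        Features are scanned in registry order; each not-yet-grouped feature
        seeds a group and absorbs every later ungrouped feature whose ICC
        with the seed exceeds the threshold.  Greedy leader grouping (rather
        than transitive connected components) keeps groups local: a chain of
        marginal correlations does not merge unrelated families.
        """
        names = [f for f in FEATURE_NAMES if features is None or f in features]
        unassigned = dict.fromkeys(names)
        comps: list[list[str]] = []
        for f in names:
            if f not in unassigned:
                continue
            del unassigned[f]
            comp = [f]
            for g in list(unassigned):
                v = self.values.loc[f, g]
                if np.isfinite(v) and v > self.threshold:
                    comp.append(g)
                    del unassigned[g]
            comps.append(sorted(comp, key=FEATURE_NAMES.index))
        return comps


def icc_matrix(
    table: pd.DataFrame, threshold: float = DEFAULT_ICC_THRESHOLD
) -> ConsistencyMatrix:
    """Pairwise feature-consistency matrix.

    Features are first averaged across channels per epoch, then each
    averaged column is z-scored (one-way ICC compares absolute values, so
    columns must share location and scale for the pairing to be meaningful),
    and the one-way single-rater ICC of every feature pair is computed with
    epochs as targets.  Zero-variance features yield NaN rows/columns.
    """
    avg = average_across_channels(table)
    x = avg.to_numpy(dtype=float)
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1)
    ok = np.isfinite(sd) & (sd > 0)
    z = np.full_like(x, np.nan)
    z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    p = len(FEATURE_NAMES)
    out = np.full((p, p), np.nan)
    for i in range(p):
        if not ok[i]:
            continue
        out[i, i] = 1.0
        for j in range(i + 1, p):
            if not ok[j]:
                continue
            pair = np.column_stack((z[:, i], z[:, j]))
            keep = np.isfinite(pair).all(axis=1)
            if keep.sum() < 2:
                continue
            out[i, j] = out[j, i] = icc_oneway(pair[keep])
    values = pd.DataFrame(out, index=list(FEATURE_NAMES), columns=list(FEATURE_NAMES))
    return ConsistencyMatrix(values=values, threshold=threshold)


# --------------------------------------------------------------------------
# t-test matrix

@dataclass
class TestMatrix:
    """Per-(feature, channel) two-sample t-test results."""

    p: pd.DataFrame  # features x channels
    h: pd.DataFrame  # boolean decisions, H = 1 <=> p < alpha
    alpha: float = DEFAULT_ALPHA


def ttest_matrix(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
) -> TestMatrix:
    """Pooled-variance two-sample t-test of amateur vs professional for
    every feature in every channel (``equal_var=False`` gives Welch)."""
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    channels = sorted(table["channel"].unique())
    p = pd.DataFrame(index=list(FEATURE_NAMES), columns=channels, dtype=float)
    for ch in channels:
        sub = table[table["channel"] == ch]
        a = sub[sub["group"] == groups[0]]
        b = sub[sub["group"] == groups[1]]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"fewer than 2 epochs per group in channel {ch}")
        for name in FEATURE_NAMES:
            xa = a[name].to_numpy(dtype=float)
            xb = b[name].to_numpy(dtype=float)
            xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
            if len(xa) < 2 or len(xb) < 2:
                p.loc[name, ch] = np.nan
                continue
            res = spstats.ttest_ind(xa, xb, equal_var=equal_var)
            pv = float(res.pvalue)
            p.loc[name, ch] = 1.0 if not np.isfinite(pv) else pv
    h = p < alpha
    return TestMatrix(p=p, h=h, alpha=alpha)


# --------------------------------------------------------------------------
# staged reduction

@dataclass
class SelectionConfig:
    """Thresholds of the three reduction stages (all surfaced in the
    result for auditability)."""

    icc_threshold: float = DEFAULT_ICC_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    #: minimum consulted channels with H = 1 for a feature to survive
    #: stage 1; None -> ceil(0.25 * n_consulted)
    min_significant_channels: int | None = None
    target_size: int = 12


@dataclass
class SelectionResult:
    method: str
    excluded_channels: tuple[str, ...]
    consulted_channels: tuple[str, ...]
    z1: tuple[str, ...]
    z2: tuple[str, ...]
    z3: tuple[str, ...]
    stages: dict[str, tuple[str, ...]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def selected(self) -> tuple[str, ...]:
        return self.stages["stage3"]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "excluded_channels": list(self.excluded_channels),
            "consulted_channels": list(self.consulted_channels),
            "Z1": list(self.z1),
            "Z2": list(self.z2),
            "Z3": list(self.z3),
            "stages": {k: list(v) for k, v in self.stages.items()},
            "config": self.config,
        }


def reduce_features(
    method: str,
    tests: TestMatrix,
    icc: ConsistencyMatrix,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Run the three-stage reduction (see module docstring).

    Method "A" consults every channel of the test matrix; method "B"
    excludes C6 from all p/H conditions.
    """
    config = config or SelectionConfig()
    if method not in ("A", "B"):
        raise ValueError("method must be 'A' or 'B'")
    excluded = ("C6",) if method == "B" else ()
    consulted = tuple(c for c in tests.p.columns if c not in excluded)
    if not consulted:
        raise ValueError("no consulted channels left")

    k_min = config.min_significant_channels
    if k_min is None:
        k_min = math.ceil(0.25 * len(consulted))

    h = tests.h[list(consulted)]
    mean_p = tests.p[list(consulted)].mean(axis=1)

    # stage 1: breadth of significance
    stage1 = tuple(f for f in FEATURE_NAMES if int(h.loc[f].sum()) >= k_min)
    z1 = tuple(f for f in FEATURE_NAMES if f not in stage1)
    if not stage1:
        raise ValueError("stage 1 removed every feature; relax "
                         "min_significant_channels")

    # stage 2: one representative per ICC-consistency group
    survivors: list[str] = []
    for comp in icc.groups(features=list(stage1)):
        rep = min(comp, key=lambda f: (mean_p[f], FEATURE_NAMES.index(f)))
        survivors.append(rep)
    stage2 = tuple(sorted(survivors, key=FEATURE_NAMES.index))
    z2 = tuple(f for f in stage1 if f not in stage2)

    # stage 3: prune to the target size by mean p
    if len(stage2) < config.target_size:
        raise ValueError(
            f"stage 2 left {len(stage2)} features, fewer than the stage-3 "
            f"target of {config.target_size}"
        )
    ranked = sorted(stage2, key=lambda f: (mean_p[f], FEATURE_NAMES.index(f)))
    stage3 = tuple(sorted(ranked[: config.target_size], key=FEATURE_NAMES.index))
    z3 = tuple(f for f in stage2 if f not in stage3)

    return SelectionResult(
        method=method,
        excluded_channels=excluded,
        consulted_channels=consulted,
        z1=z1,
        z2=z2,
        z3=z3,
        stages={"stage1": stage1, "stage2": stage2, "stage3": stage3},
        config={**asdict(config), "min_significant_channels_effective": k_min},
    )


class StagedFeatureReducer:
    """scikit-learn style wrapper around the staged reduction.

    ``fit`` expects a standardized feature table (with ``group`` and
    ``channel`` annotation columns); afterwards ``support_`` masks the 63
    registry features, ``result_`` holds the full audit trail and
    ``transform`` restricts a table to the selected features.
    """

    def __init__(
        self,
        method: str = "B",
        icc_threshold: float = DEFAULT_ICC_THRESHOLD,
        alpha: float = DEFAULT_ALPHA,
        min_significant_channels: int | None = None,
        target_size: int = 12,
    ):
        self.method = method
        self.icc_threshold = icc_threshold
        self.alpha = alpha
        self.min_significant_channels = min_significant_channels
        self.target_size = target_size

    def get_params(self, deep: bool = True) -> dict:
        return {
            "method": self.method,
            "icc_threshold": self.icc_threshold,
            "alpha": self.alpha,
            "min_significant_channels": self.min_significant_channels,
            "target_size": self.target_size,
        }

    def set_params(self, **params) -> "StagedFeatureReducer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, table: pd.DataFrame, y=None) -> "StagedFeatureReducer":
        cfg = SelectionConfig(
            icc_threshold=self.icc_threshold,
            alpha=self.alpha,
            min_significant_channels=self.min_significant_channels,
            target_size=self.target_size,
        )
        self.tests_ = ttest_matrix(table, alpha=self.alpha)
        self.icc_ = icc_matrix(table, threshold=self.icc_threshold)
        self.result_ = reduce_features(self.method, self.tests_, self.icc_, cfg)
        self.support_ = np.array(
            [f in self.result_.selected for f in FEATURE_NAMES]
        )
        return self

    def get_support(self) -> np.ndarray:
        return self.support_.copy()

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        keep = [c for c in table.columns if c not in FEATURE_NAMES]
        return table[keep + list(self.result_.selected)]

    def fit_transform(self, table: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(table).transform(table)
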