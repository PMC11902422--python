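"""Sample-entropy event detection for burst-like muscle activity.

Sample entropy, SampEn(m, r, N) = -ln(A/B), measures irregularity: B counts
pairs of length-``m`` templates whose Chebyshev distance is at most ``r``,
A counts the same for length ``m + 1``, self-matches excluded.  Applied in a
sliding window over the rectified/smoothed envelope with a *global*
tolerance r = r_factor * SD(whole trial), SampEn is near zero on the quiet
baseline (every template matches within r) and rises sharply inside a
contraction burst, making the series a robust onset/offset marker that does
not depend on absolute amplitude.

Epoch marking uses an anti-shake rule: a start is committed only after
``start_count`` consecutive windows exceed the start threshold, an end after
``end_count`` consecutive windows fall below the end threshold.  Candidate
epochs are then filtered by minimum length and by peak amplitude relative to
the trial maximum.  Detection runs on each arm's biceps channel only and the
accepted intervals are propagated to the other three channels of that arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import Epoch, EpochSet, Recording, ARM_CHANNELS, BICEPS_CHANNEL
from .preprocessing import bandpass_filter, half_wave_rectify, moving_average


@dataclass
class SampEnParams:
    """Parameters of the sliding-window SampEn detector.

    Defaults follow the standard tuning for 1 kHz dumbbell-curl recordings:
    m=2, r = 0.25*SD of the whole smoothed trial, a 64-sample rectangular
    window advanced in steps of 30 samples, start/end threshold factors
    0.02/0.01 of the series maximum, anti-shake counts 3/2, minimum epoch
    length 1050 samples and a peak-amplitude gate of 0.35 times the trial's
    maximum absolute filtered amplitude.
    """

    m: int = 2
    r_factor: float = 0.25
    window: int = 64
    step: int = 30
    start_factor: float = 0.02
    end_factor: float = 0.01
    start_count: int = 3
    end_count: int = 2
    min_len: int = 1050
    amp_factor: float = 0.35
    #: "relative" thresholds scale start/end factors by max(series);
    #: "absolute" uses them as raw SampEn values.
    threshold_mode: str = "relative"
    #: a candidate spanning at least this fraction of the trial is discarded:
    #: with relative thresholds an activity-free trial (e.g. pure baseline
    #: noise) marks one never-closing epoch over the whole recording, which
    #: is a no-contrast detection, not an event
    max_trial_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError("need 0 < step <= window")
        if self.m >= self.window:
            raise ValueError("template length m must be smaller than the window")
        if self.threshold_mode not in ("relative", "absolute"):
            raise ValueError("threshold_mode must be 'relative' or 'absolute'")


@dataclass
class SampEnSeries:
    """SampEn values at successive window positions."""

    values: np.ndarray
    window_start_samples: np.ndarray
    window: int
    step: int
    r: float = 0.0
    degenerate: np.ndarray = field(default=None)  # True where the cap was used

    def __len__(self) -> int:
        return len(self.values)


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """SampEn(m, r) of one window; degenerate counts return a finite cap.

    Template matching uses the Chebyshev distance and excludes self-matches.
    When no length-(m+1) pair matches (A = 0), or no length-m pair matches
    (B = 0), -ln(A/B) is undefined; the conventional finite ceiling
    -ln(2 / ((N - m - 1)(N - m))) — the smallest nonzero conditional
    probability resolvable from N points — is returned instead so that a
    sliding-window series never contains infinities.
    """
    value, _ = _sampen_with_flag(np.asarray(x, dtype=float), m, r)
    return value


def _sampen_with_flag(x: np.ndarray, m: int, r: float) -> tuple[float, bool]:
    n = len(x)
    if n < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples, got {n}")
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    b = _template_match_count(x, m, n - m, r)
    a = _template_match_count(x, m + 1, n - m, r)
    if a == 0 or b == 0:
        nm = n - m
        return -np.log(2.0 / ((nm - 1) * nm)), True
    return float(-np.log(a / b)), False


def _template_match_count(
    x: np.ndarray, length: int, n_templates: int, r: float
) -> int:
    """Ordered template pairs (i != j) matching within r (Chebyshev).

    Both template lengths m and m + 1 are counted over the same first
    ``n_templates = N - m`` starting positions (the trailing length-m
    template is dropped), the standard convention.
    """
    tpl = np.lib.stride_tricks.sliding_window_view(x, length)[:n_templates]
    if len(tpl) < 2:
        return 0
    d = np.abs(tpl[:, None, :] - tpl[None, :, :]).max(axis=2)
    matches = (d <= r).sum() - len(tpl)  # remove self-matches
    return int(matches)


def sampen_series(x: np.ndarray, params: SampEnParams | None = None) -> SampEnSeries:
    """Sliding-window SampEn of a (smoothed) trial signal.

    The tolerance is computed once from the whole trial,
    r = r_factor * SD(x), so it acts as a global scale reference: windows on
    the quiet baseline have nearly all templates within r and SampEn ~ 0,
    while busy windows score high.
    """
    params = params or SampEnParams()
    x = np.asarray(x, dtype=float)
    if len(x) < params.window:
        raise ValueError(
            f"trial of {len(x)} samples is shorter than one window "
            f"({params.window})"
        )
    r = params.r_factor * float(np.std(x))
    starts = np.arange(0, len(x) - params.window + 1, params.step)
    values = np.empty(len(starts))
    flags = np.zeros(len(starts), dtype=bool)
    if r == 0.0:
        # constant trial: every window is constant, SampEn is 0 by the
        # all-templates-match limit
        values[:] = 0.0
    else:
        for k, s in enumerate(starts):
            values[k], flags[k] = _sampen_with_flag(
                x[s : s + params.window], params.m, r
            )
    return SampEnSeries(
        values=values,
        window_start_samples=starts,
        window=params.window,
        step=params.step,
        r=r,
        degenerate=flags,
    )


def detect_epochs(
    series: SampEnSeries,
    x_filtered: np.ndarray,
    params: SampEnParams | None = None,
) -> list[tuple[int, int]]:
    """Mark activity intervals on a SampEn series and filter them.

    A start is committed at the first window of a run of ``start_count``
    consecutive values above the start threshold; an end at the first window
    of a run of ``end_count`` consecutive values below the end threshold,
    plus the window length (inclusive boundary).  In the default relative
    mode the thresholds are ``start_factor``/``end_factor`` times the series
    maximum.  An unterminated start is closed at the final sample.

    Candidates are then dropped unless their length exceeds ``min_len``
    samples and their peak absolute filtered amplitude exceeds
    ``amp_factor * max|x_filtered|``.
    """
    params = params or SampEnParams()
    x_filtered = np.asarray(x_filtered, dtype=float)
    v = series.values
    if len(v) == 0:
        return []
    if params.threshold_mode == "relative":
        peak = float(np.max(v))
        thr_start = params.start_factor * peak
        thr_end = params.end_factor * peak
    else:
        thr_start = params.start_factor
        thr_end = params.end_factor

    starts_s = series.window_start_samples
    candidates: list[tuple[int, int]] = []
    state_active = False
    start_sample = 0
    run = 0
    run_first = 0
    for k in range(len(v)):
        if not state_active:
            if v[k] > thr_start:
                run = run + 1 if run else 1
                if run == 1:
                    run_first = k
                if run >= params.start_count:
                    state_active = True
                    start_sample = int(starts_s[run_first])
                    run = 0
            else:
                run = 0
        else:
            if v[k] < thr_end:
                run = run + 1 if run else 1
                if run == 1:
                    run_first = k
                if run >= params.end_count:
                    end_sample = int(starts_s[run_first]) + series.window
                    candidates.append((start_sample, min(end_sample, len(x_filtered))))
                    state_active = False
                    run = 0
            else:
                run = 0
    if state_active:
        candidates.append((start_sample, len(x_filtered)))

    amp_gate = params.amp_factor * float(np.max(np.abs(x_filtered))) if len(
        x_filtered
    ) else 0.0
    accepted = []
    for s, e in candidates:
        if e - s <= params.min_len:
            continue
        if e - s >= params.max_trial_fraction * len(x_filtered):
            continue
        if float(np.max(np.abs(x_filtered[s:e]))) <= amp_gate:
            continue
        accepted.append((s, e))
    return accepted


def propagate_epochs(
    intervals: list[tuple[int, int]],
    channels: dict[str, np.ndarray],
    subject_id: str = "",
    group: str = "",
    trial_id: int = 0,
) -> EpochSet:
    """Cut the same sample intervals from every same-arm filtered channel."""
    out = EpochSet()
    for name, x in channels.items():
        x = np.asarray(x, dtype=float)
        for s, e in intervals:
            if not (0 <= s < e <= len(x)):
                raise ValueError(
                    f"interval ({s}, {e}) out of bounds for channel {name} "
                    f"of length {len(x)}"
                )
            out.epochs.append(
                Epoch(
                    samples=x[s:e].copy(),
                    channel=name,
                    start_sample=s,
                    end_sample=e,
                    subject_id=subject_id,
                    group=group,
                    trial_id=trial_id,
                )
            )
    return out


def detect_trial(
    recording: Recording, params: SampEnParams | None = None
) -> tuple[EpochSet, dict]:
    """Full per-trial detection: filter all channels, detect on each arm's
    biceps channel, propagate intervals to the same-arm channels.

    Returns the (unnormalized) epoch set of filtered-signal segments plus a
    log dict with per-arm candidate counts and detected intervals.
    """
    params = params or SampEnParams()
    filtered = {
        name: bandpass_filter(recording.channel(name), recording.fs)
        for name in recording.channel_names
    }
    epoch_set = EpochSet()
    log: dict = {"intervals": {}, "r": {}}
    for arm, members in ARM_CHANNELS.items():
        biceps = BICEPS_CHANNEL[arm]
        smoothed = moving_average(half_wave_rectify(filtered[biceps]), span=5)
        series = sampen_series(smoothed, params)
        intervals = detect_epochs(series, filtered[biceps], params)
        log["intervals"][biceps] = intervals
        log["r"][biceps] = series.r
        arm_signals = {name: filtered[name] for name in members}
        epoch_set.extend(
            propagate_epochs(
                intervals,
                arm_signals,
                subject_id=recording.subject_id,
                group=recording.group,
                trial_id=recording.trial_id,
            )
        )
    return epoch_set, log


def detector_config(params: SampEnParams) -> dict:
    """Serializable view of the detector parameters (for run manifests)."""
    return asdict(params)
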