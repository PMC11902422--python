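"""Synthetic 8-channel dumbbell-curl sEMG generator with ground truth.

Emulates an alternating standing dumbbell-curl protocol sampled at 1 kHz:
six curl cycles per trial, each cycle about 4-5 s (one ~2 s single-arm curl
per arm, left arm first, right arm offset by half a cycle), for a trial of
roughly 30 s.  The left arm drives channels C1, C2, C5, C6 and the right arm
C3, C4, C7, C8; channels of the same arm share burst timing but carry
independent noise realizations with channel-specific amplitude factors.

A burst is Gaussian white noise band-passed around the subject's median
frequency (inside the 20-250 Hz EMG band), shaped by a two-lobe envelope
whose higher first peak and lower second peak imitate the flexion-then-
extension morphology of a curl epoch.  Bursts ride on low-amplitude
band-limited baseline noise; the amplitude scale is the burst's *peak*
amplitude relative to the baseline standard deviation (the two-lobe envelope
and noise crest factor put the burst RMS at roughly peak / 6, so the default
peak scale of 90 corresponds to a burst SNR near 24 dB).  Controlling the
peak rather than the RMS makes the per-subject maximum amplitude — the
divisor used by downstream normalization — essentially deterministic, so
normalized feature distributions carry no incidental subject-level offsets.
Units are arbitrary: normalization removes absolute scale.

Two subject classes (amateur vs professional) differ by configurable class
effects: a burst-amplitude ratio, a median-frequency shift and a
burst-duration ratio.  Identity effects make the classes exchangeable, so
any downstream classifier must perform at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

from .containers import Recording, TrialGroundTruth, CHANNEL_NAMES, ARM_CHANNELS

#: Relative burst amplitude of each channel within its arm (biceps = 1).
CHANNEL_AMPLITUDE_FACTORS = {
    "C1": 1.0, "C2": 0.55, "C5": 0.70, "C6": 0.45,
    "C3": 1.0, "C4": 0.55, "C7": 0.45, "C8": 0.70,
}

EMG_BAND = (20.0, 250.0)


@dataclass
class SubjectProfile:
    """Ground-truth burst parameters of one simulated subject."""

    subject_id: str
    group: str  # "amateur" | "professional"
    burst_amplitude_scale: float = 90.0  # burst peak relative to baseline SD
    burst_duration_s: float = 2.0
    median_freq_hz: float = 100.0
    amplitude_jitter_cv: float = 0.1  # per-burst amplitude jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("amateur", "professional"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.burst_amplitude_scale < 0:
            raise ValueError("burst_amplitude_scale must be >= 0")
        if self.burst_duration_s <= 0:
            raise ValueError("burst_duration_s must be positive")
        if not (EMG_BAND[0] < self.median_freq_hz < EMG_BAND[1]):
            raise ValueError(
                f"median_freq_hz must lie strictly inside {EMG_BAND}, "
                f"got {self.median_freq_hz}"
            )
        if self.amplitude_jitter_cv < 0:
            raise ValueError("amplitude_jitter_cv must be >= 0")


@dataclass
class ClassEffects:
    """Multiplicative/additive differences of professionals vs amateurs."""

    amplitude_ratio: float = 2.0
    median_freq_shift_hz: float = 30.0
    duration_ratio: float = 1.1

    @classmethod
    def identity(cls) -> "ClassEffects":
        """No class difference: both groups drawn from one distribution."""
        return cls(amplitude_ratio=1.0, median_freq_shift_hz=0.0,
                   duration_ratio=1.0)


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        low: float, high: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to (low, high) Hz."""
    pad = int(0.25 * fs)  # absorb filter edge transients
    white = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)[pad : pad + n]
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _burst_envelope(n: int) -> np.ndarray:
    """Two-lobe envelope: a high flexion peak then a lower extension peak."""
    first = np.zeros(n)
    second = np.zeros(n)
    n1 = max(int(0.60 * n), 4)
    n2 = max(n - int(0.50 * n), 4)
    first[:n1] = np.hanning(n1)
    second[n - n2 :] = 0.55 * np.hanning(n2)
    return np.maximum(first, second)


def generate_trial(
    profile: SubjectProfile,
    fs: float = 1000.0,
    n_cycles: int = 6,
    trial_seed: int = 0,
    trial_id: int = 0,
    baseline_sigma: float = 1.0,
) -> tuple[Recording, TrialGroundTruth]:
    """Generate one 8-channel trial and its true burst intervals.

    Cycle lengths are drawn uniformly in [4, 5] s; within each cycle the left
    arm bursts first and the right arm half a cycle later.  Deterministic
    given (profile.seed, trial_seed).
    """
    if fs <= 2 * EMG_BAND[1]:
        raise ValueError(f"fs must exceed {2 * EMG_BAND[1]} Hz, got {fs}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng([max(profile.seed, 0), trial_seed, 2_000_003])

    lead_s = 1.0
    cycle_s = rng.uniform(4.0, 5.0, size=n_cycles)
    cycle_starts_s = lead_s + np.concatenate(([0.0], np.cumsum(cycle_s[:-1])))
    total_s = lead_s + float(cycle_s.sum()) + 1.0
    n = int(round(total_s * fs))

    dur = profile.burst_duration_s
    intervals_per_arm: dict[str, list[tuple[int, int]]] = {"left": [], "right": []}
    for k in range(n_cycles):
        jl = rng.uniform(0.0, 0.2)
        jr = rng.uniform(0.0, 0.2)
        left_start = cycle_starts_s[k] + jl
        right_start = cycle_starts_s[k] + cycle_s[k] / 2.0 + jr
        for arm, start in (("left", left_start), ("right", right_start)):
            s = int(round(start * fs))
            e = min(int(round((start + dur) * fs)), n)
            intervals_per_arm[arm].append((s, e))

    # Per-burst amplitude jitter, shared across an arm's channels so the
    # relative channel factors stay interpretable.  Gains jitter downward
    # from a ceiling of 1 (effort lapses below a repeatable maximum), so the
    # per-subject maximum amplitude — the divisor of the downstream
    # normalization — is essentially deterministic.
    burst_gain = {
        arm: np.exp(-np.abs(rng.normal(0.0, profile.amplitude_jitter_cv,
                                       size=n_cycles)))
        for arm in ("left", "right")
    }

    f0 = profile.median_freq_hz
    low = max(EMG_BAND[0] + 0.5, f0 - 40.0)
    high = min(EMG_BAND[1] - 0.5, f0 + 40.0)

    samples = np.empty((n, len(CHANNEL_NAMES)))
    channel_intervals: dict[str, list[tuple[int, int]]] = {}
    for c, name in enumerate(CHANNEL_NAMES):
        arm = "left" if name in ARM_CHANNELS["left"] else "right"
        x = baseline_sigma * _band_limited_noise(rng, n, fs, *EMG_BAND)
        for k, (s, e) in enumerate(intervals_per_arm[arm]):
            m = e - s
            if m <= 8:
                continue
            burst = _band_limited_noise(rng, m, fs, low, high)
            env = _burst_envelope(m)
            shaped = burst * env
            peak = np.max(np.abs(shaped))
            if peak > 0:
                shaped *= 1.0 / peak  # unit peak: amplitude means peak amplitude
            amp = (
                profile.burst_amplitude_scale
                * CHANNEL_AMPLITUDE_FACTORS[name]
                * burst_gain[arm][k]
                * baseline_sigma
            )
            x[s:e] += amp * shaped
        samples[:, c] = x
        channel_intervals[name] = list(intervals_per_arm[arm])

    rec = Recording(
        samples=samples,
        fs=fs,
        channel_names=CHANNEL_NAMES,
        subject_id=profile.subject_id,
        group=profile.group,
        trial_id=trial_id,
    )
    gt = TrialGroundTruth(
        intervals=channel_intervals,
        sub_threshold=profile.burst_amplitude_scale == 0.0,
    )
    return rec, gt


#: Between-subject variability of the cohort sampler (documented artifact
#: choices, not measured population values): log-normal amplitude spread
#: with sigma 0.15, Gaussian median-frequency spread 5 Hz, Gaussian
#: burst-duration spread 0.05 s.
SUBJECT_JITTER = {
    "amplitude_log_sigma": 0.15,
    "median_freq_sigma_hz": 5.0,
    "duration_sigma_s": 0.05,
}

_BASE_PROFILE = dict(
    burst_amplitude_scale=90.0,
    burst_duration_s=2.0,
    median_freq_hz=100.0,
    amplitude_jitter_cv=0.1,
)


def generate_cohort(
    n_amateur: int = 5,
    n_professional: int = 5,
    class_effects: ClassEffects | None = None,
    n_trials: int = 5,
    seed: int = 0,
    fs: float = 1000.0,
    n_cycles: int = 6,
) -> tuple[list[tuple[Recording, TrialGroundTruth]], dict]:
    """Generate a two-class cohort of trials.

    Professional profiles differ from amateur profiles exactly by
    ``class_effects``; per-subject jitter follows :data:`SUBJECT_JITTER` and
    the drawn profiles are echoed in the returned metadata.  Deterministic
    given ``seed``.

    Returns
    -------
    trials : list of (Recording, TrialGroundTruth), ordered by subject then
        trial.
    metadata : dict with the profiles, jitter distributions and effects used.
    """
    if min(n_amateur, n_professional, n_trials) < 1:
        raise ValueError("all counts must be >= 1")
    effects = class_effects or ClassEffects()
    rng = np.random.default_rng([seed, 77_003])

    # Subject jitter is drawn once per subject *slot* and shared between the
    # groups: professional i is the amateur-i twin with the class effects
    # applied on top.  Professionals therefore differ from amateurs exactly
    # by class_effects, and identity effects make the two groups
    # distributionally indistinguishable (downstream classification must be
    # at chance).
    n_slots = max(n_amateur, n_professional)
    slot_jitter = [
        {
            "amp": float(np.exp(rng.normal(0.0, SUBJECT_JITTER["amplitude_log_sigma"]))),
            "f0": float(rng.normal(0.0, SUBJECT_JITTER["median_freq_sigma_hz"])),
            "dur": float(rng.normal(0.0, SUBJECT_JITTER["duration_sigma_s"])),
        }
        for _ in range(n_slots)
    ]
    profiles: list[SubjectProfile] = []
    for group, count in (("amateur", n_amateur), ("professional", n_professional)):
        for i in range(count):
            j = slot_jitter[i]
            amp = _BASE_PROFILE["burst_amplitude_scale"] * j["amp"]
            f0 = _BASE_PROFILE["median_freq_hz"] + j["f0"]
            dur = _BASE_PROFILE["burst_duration_s"] + j["dur"]
            if group == "professional":
                amp *= effects.amplitude_ratio
                f0 += effects.median_freq_shift_hz
                dur *= effects.duration_ratio
            f0 = float(np.clip(f0, EMG_BAND[0] + 1.0, EMG_BAND[1] - 1.0))
            profiles.append(
                SubjectProfile(
                    subject_id=f"{'A' if group == 'amateur' else 'P'}{i + 1:02d}",
                    group=group,
                    burst_amplitude_scale=float(amp),
                    burst_duration_s=float(max(dur, 1.2)),
                    median_freq_hz=f0,
                    amplitude_jitter_cv=_BASE_PROFILE["amplitude_jitter_cv"],
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )

    trials: list[tuple[Recording, TrialGroundTruth]] = []
    for prof in profiles:
        for t in range(n_trials):
            trials.append(
                generate_trial(prof, fs=fs, n_cycles=n_cycles,
                               trial_seed=t + 1, trial_id=t + 1)
            )
    metadata = {
        "profiles": [asdict(p) for p in profiles],
        "class_effects": asdict(effects),
        "subject_jitter": dict(SUBJECT_JITTER),
        "seed": seed,
        "fs": fs,
        "n_cycles": n_cycles,
        "n_trials": n_trials,
    }
    return trials, metadata
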