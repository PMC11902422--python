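"""Core data containers shared across the pipeline stages.

A trial of multi-channel surface EMG is held in a :class:`Recording`;
detected activity segments become :class:`Epoch` objects collected in an
:class:`EpochSet`.  Feature values live in a plain :class:`pandas.DataFrame`
("feature table") with one row per epoch and one column per feature plus the
annotation columns ``subject``, ``group``, ``channel`` and ``trial``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard channel layout of the 8-electrode dumbbell-curl montage.
#: C1/C3 are the left/right biceps brachii (used for event detection);
#: C2/C4 triceps, C5/C8 brachioradialis, C6/C7 flexor carpi.
CHANNEL_NAMES = ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8")

#: Channels driven by each arm.  Detection runs on the biceps channel of an
#: arm and the resulting intervals are propagated to the other three
#: channels of the same arm.
ARM_CHANNELS = {
    "left": ("C1", "C2", "C5", "C6"),
    "right": ("C3", "C4", "C7", "C8"),
}

#: Biceps (detection) channel per arm.
BICEPS_CHANNEL = {"left": "C1", "right": "C3"}

ANNOTATION_COLUMNS = ("subject", "group", "channel", "trial", "epoch_index")


@dataclass
class Recording:
    """One trial: an ``(n_samples, n_channels)`` signed sample matrix."""

    samples: np.ndarray
    fs: float = 1000.0
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    subject_id: str = ""
    group: str = ""
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_samples, n_channels) array")
        if self.samples.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[1]} columns but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D array."""
        return self.samples[:, self.channel_names.index(name)]


@dataclass
class Epoch:
    """One detected activity segment cut from a filtered channel."""

    samples: np.ndarray
    channel: str
    start_sample: int
    end_sample: int  # exclusive
    subject_id: str = ""
    group: str = ""
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("epoch samples must be 1-D")
        if self.end_sample - self.start_sample != len(self.samples):
            raise ValueError("epoch interval does not match sample count")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class EpochSet:
    """Epochs grouped for downstream feature extraction.

    ``normalization_divisors`` maps ``(subject_id, channel)`` to the
    amplitude the group's samples were divided by; it is empty until
    :func:`isoemg.preprocessing.normalize_epochs` runs.
    """

    epochs: list[Epoch] = field(default_factory=list)
    normalization_divisors: dict[tuple[str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def normalized(self) -> bool:
        return bool(self.normalization_divisors)

    def extend(self, other: "EpochSet") -> None:
        self.epochs.extend(other.epochs)
        self.normalization_divisors.update(other.normalization_divisors)

    def by_group(self) -> dict[tuple[str, str], list[Epoch]]:
        """Epochs keyed by (subject, channel)."""
        out: dict[tuple[str, str], list[Epoch]] = {}
        for ep in self.epochs:
            out.setdefault((ep.subject_id, ep.channel), []).append(ep)
        return out


@dataclass
class TrialGroundTruth:
    """True burst intervals of a synthetic trial.

    ``intervals`` maps channel name to a list of ``(start, end)`` sample
    pairs (end exclusive); ``sub_threshold`` marks trials generated with
    zero burst amplitude whose intervals are listed but carry no activity.
    """

    intervals: dict[str, list[tuple[int, int]]]
    sub_threshold: bool = False

    def __post_init__(self) -> None:
        for ch, ivals in self.intervals.items():
            starts = [s for s, _ in ivals]
            if starts != sorted(starts):
                raise ValueError(f"intervals on {ch} are not sorted")
            for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping intervals on {ch}")
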