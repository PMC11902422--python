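"""Signal conditioning: band-pass filtering, rectification, smoothing and
per-subject amplitude normalization.

The chain mirrors common practice for dynamic-contraction surface EMG:

* a zero-phase 4th-order 20-250 Hz Butterworth band-pass removes baseline
  drift and out-of-band noise (no power-line notch: the band-pass already
  brackets the EMG band and a notch costs usable signal energy);
* half-wave rectification followed by a 5-point moving average produces the
  smoothed envelope used *only* by the event detector — features are always
  computed on the band-passed (not rectified) signal;
* detected epochs are normalized per subject and channel by the maximum
  absolute epoch sample, removing inter-subject and inter-muscle amplitude
  differences (NEMG = EMG_i / max|EMG_all|).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .containers import EpochSet

DEFAULT_BAND = (20.0, 250.0)
DEFAULT_ORDER = 4


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a single channel.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the squared Butterworth magnitude and
    the phase is zero.

    Parameters
    ----------
    x : 1-D signal.
    fs : sampling rate in Hz.
    low, high : pass-band edges in Hz; ``low < high < fs / 2``.
    order : Butterworth order of the one-way filter.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("bandpass_filter expects a 1-D signal")
    if not (0 < low < high < fs / 2):
        raise ValueError(f"need 0 < low < high < fs/2, got {low}, {high}, fs={fs}")
    minlen = 3 * (order + 1)
    if len(x) < minlen:
        raise ValueError(f"signal of {len(x)} samples is shorter than the "
                         f"filter warm-up of {minlen} samples")
    sos = sps.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def half_wave_rectify(x: np.ndarray) -> np.ndarray:
    """Clamp negative samples to zero: ``max(x_i, 0)``."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def moving_average(x: np.ndarray, span: int = 5) -> np.ndarray:
    """Centred moving average with shrinking symmetric end windows.

    The span must be odd.  Interior samples are the mean over ``span``
    neighbours; near the edges the window shrinks symmetrically (1, 3, ...,
    span), so the output has the same length as the input and a constant
    signal is reproduced exactly.
    """
    x = np.asarray(x, dtype=float)
    if span < 1 or span % 2 == 0:
        raise ValueError(f"span must be an odd positive integer, got {span}")
    n = len(x)
    if n == 0 or span == 1:
        return x.copy()
    half = span // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    out = np.empty(n)
    idx = np.arange(n)
    # symmetric shrinking half-width at each position
    h = np.minimum(np.minimum(idx, n - 1 - idx), half)
    lo, hi = idx - h, idx + h + 1
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def normalize_epochs(epoch_set: EpochSet) -> EpochSet:
    """Normalize epoch amplitudes per (subject, channel).

    Every sample of every epoch in a (subject, channel) group is divided by
    the group-wide maximum *absolute* sample value, so normalized samples
    lie in [-1, 1] and the largest-magnitude sample maps to +-1.  The
    divisor is recorded in ``normalization_divisors``.  Idempotent: applying
    twice changes nothing (the second pass divides by 1).

    Raises
    ------
    ValueError
        If a (subject, channel) group contains only zero samples.
    """
    out = EpochSet()
    for (subject, channel), epochs in epoch_set.by_group().items():
        divisor = max(float(np.max(np.abs(ep.samples))) for ep in epochs)
        if divisor == 0.0:
            raise ValueError(
                f"all-zero epoch group for subject={subject!r} channel={channel!r}"
            )
        for ep in epochs:
            scaled = type(ep)(
                samples=ep.samples / divisor,
                channel=ep.channel,
                start_sample=ep.start_sample,
                end_sample=ep.end_sample,
                subject_id=ep.subject_id,
                group=ep.group,
                trial_id=ep.trial_id,
            )
            out.epochs.append(scaled)
        out.normalization_divisors[(subject, channel)] = divisor
    return out
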