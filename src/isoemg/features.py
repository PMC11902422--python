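"""The 63-value epoch feature bank: 41 time-domain features (the 4th-order
AR model contributes four coefficients) and 9 frequency-domain features (the
spectral moments contribute SM0..SM3 and the level-3 wavelet packet
decomposition contributes eight node energies), for 44 + 19 = 63 values per
epoch.

Time-domain features follow the standard surface-EMG catalog (amplitude,
waveform-complexity and difference statistics); frequency-domain features
are derived from one periodogram of the detrended epoch over the positive
frequency bins.  A handful of catalog names (AE, MAS, VARe, VO, LDMA,
LDASDA, FZC) have no single canonical printed formula; the definitions used
here are recorded in the registry and flagged ``interpretation``.

Degenerate inputs produce documented sentinels rather than exceptions where
a feature is undefined mid-pipeline (e.g. LTKEO of a sequence whose
Teager-Kaiser energy sum is non-positive is NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats as spstats
from statsmodels.regression.linear_model import yule_walker

from .containers import Epoch, EpochSet, ANNOTATION_COLUMNS

# --------------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class FeatureInfo:
    name: str
    base: str  # catalog name before multi-value expansion
    domain: str  # "TD" | "FD"
    description: str
    interpretation: bool = False  # True where the catalog name is ambiguous


_TD = [
    FeatureInfo("ASM", "ASM", "TD",
                "abs mean of |x_i|^e, e=0.5 in the middle half else 0.75"),
    FeatureInfo("ASS", "ASS", "TD", "abs sum of sqrt(|x_i|)"),
    FeatureInfo("AR1", "AR", "TD", "1st Yule-Walker AR(4) coefficient"),
    FeatureInfo("AR2", "AR", "TD", "2nd Yule-Walker AR(4) coefficient"),
    FeatureInfo("AR3", "AR", "TD", "3rd Yule-Walker AR(4) coefficient"),
    FeatureInfo("AR4", "AR", "TD", "4th Yule-Walker AR(4) coefficient"),
    FeatureInfo("AAC", "AAC", "TD", "average amplitude change: sum|dx|/N"),
    FeatureInfo("AE", "AE", "TD", "average energy: mean(x^2)", True),
    FeatureInfo("CARD", "CARD", "TD",
                "cardinality: sorted adjacent gaps exceeding the threshold"),
    FeatureInfo("COV", "COV", "TD", "coefficient of variation: SD/|mean|"),
    FeatureInfo("DAMV", "DAMV", "TD", "difference absolute mean value"),
    FeatureInfo("DASDV", "DASDV", "TD", "difference absolute SD value"),
    FeatureInfo("DVARV", "DVARV", "TD", "difference variance value"),
    FeatureInfo("EMAV", "EMAV", "TD", "enhanced MAV with banded exponents"),
    FeatureInfo("EWL", "EWL", "TD", "enhanced wavelength with banded exponents"),
    FeatureInfo("IEMG", "IEMG", "TD", "integrated EMG: sum|x|"),
    FeatureInfo("IQR", "IQR", "TD", "interquartile range"),
    FeatureInfo("KURT", "KURT", "TD", "kurtosis (non-excess)"),
    FeatureInfo("LCOV", "LCOV", "TD", "log coefficient of variation"),
    FeatureInfo("LD", "LD", "TD", "log detector: exp(mean ln|x|)"),
    FeatureInfo("LDMA", "LDMA", "TD", "log of DAMV", True),
    FeatureInfo("LDASDA", "LDASDA", "TD", "log of DASDV", True),
    FeatureInfo("LTKEO", "LTKEO", "TD", "log Teager-Kaiser energy sum"),
    FeatureInfo("MFL", "MFL", "TD", "maximum fractal length: log10 sqrt(sum dx^2)"),
    FeatureInfo("MAS", "MAS", "TD", "mean absolute deviation from the mean", True),
    FeatureInfo("MAV", "MAV", "TD", "mean absolute value"),
    FeatureInfo("MSR", "MSR", "TD", "mean square root: mean sqrt(|x|)"),
    FeatureInfo("MMAV", "MMAV", "TD", "modified MAV, 0.5 weight at the edges"),
    FeatureInfo("MMAV2", "MMAV2", "TD", "modified MAV with linear edge weights"),
    FeatureInfo("MYOP", "MYOP", "TD", "myopulse percentage rate"),
    FeatureInfo("FZC", "FZC", "TD", "zero crossings without amplitude gate", True),
    FeatureInfo("RMS", "RMS", "TD", "root mean square"),
    FeatureInfo("SSI", "SSI", "TD", "simple square integral: sum x^2"),
    FeatureInfo("Skew", "Skew", "TD", "skewness"),
    FeatureInfo("SSC", "SSC", "TD", "slope sign changes above the threshold"),
    FeatureInfo("SD", "SD", "TD", "sample standard deviation"),
    FeatureInfo("TM", "TM", "TD", "absolute 3rd temporal moment |mean x^3|"),
    FeatureInfo("VAR", "VAR", "TD", "sample variance"),
    FeatureInfo("VARe", "VARe", "TD", "EMG variance about zero: sum x^2/(N-1)", True),
    FeatureInfo("VO", "VO", "TD", "v-order, v=2: sqrt(mean x^2)", True),
    FeatureInfo("WL", "WL", "TD", "waveform length: sum|dx|"),
    FeatureInfo("WA", "WA", "TD", "Willison amplitude above the threshold"),
    FeatureInfo("ZC", "ZC", "TD", "zero crossings above the threshold"),
    FeatureInfo("DUR", "DUR", "TD", "epoch duration N/fs in seconds"),
]

_FD = [
    FeatureInfo("MDF", "MDF", "FD", "median frequency of the power spectrum"),
    FeatureInfo("MNF", "MNF", "FD", "mean frequency: sum fP / sum P"),
    FeatureInfo("FR", "FR", "FD", "low-band / high-band power ratio"),
    FeatureInfo("PKF", "PKF", "FD", "peak frequency: argmax of the spectrum"),
    FeatureInfo("PSR", "PSR", "FD", "power spectrum ratio around the peak"),
    FeatureInfo("MNP", "MNP", "FD", "mean spectral power"),
    FeatureInfo("SM0", "SM", "FD", "0th spectral moment (total power)"),
    FeatureInfo("SM1", "SM", "FD", "1st spectral moment"),
    FeatureInfo("SM2", "SM", "FD", "2nd spectral moment"),
    FeatureInfo("SM3", "SM", "FD", "3rd spectral moment"),
    FeatureInfo("VCF", "VCF", "FD", "variance of the central frequency"),
] + [
    FeatureInfo(f"WP{k + 1}", "WP", "FD",
                f"level-3 db1 wavelet packet node ({3},{k}) reconstruction norm")
    for k in range(8)
]

FEATURE_REGISTRY: tuple[FeatureInfo, ...] = tuple(_TD + _FD)
FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURE_REGISTRY)
assert len(FEATURE_NAMES) == 63

#: The compact 12-feature group (nine TD + three FD) and its 16-feature
#: superset used throughout the evaluation stage.  WP5 is the norm of the
#: reconstructed wavelet packet node (3, 4).
F12B_FEATURES = ("ASM", "AR4", "AAC", "DAMV", "LTKEO", "SSI", "SD", "WL",
                 "DUR", "PKF", "SM0", "WP5")
F16B_FEATURES = F12B_FEATURES + ("ASS", "AR2", "CARD", "MNF")

DEFAULT_THRESHOLD = 0.01  # on normalized (unit-peak) amplitude


def registry_json() -> list[dict]:
    """Registry as plain dicts (name, base, domain, description, flags)."""
    return [
        {
            "index": i + 1,
            "name": f.name,
            "base": f.base,
            "domain": f.domain,
            "description": f.description,
            "interpretation": f.interpretation,
        }
        for i, f in enumerate(FEATURE_REGISTRY)
    ]


# --------------------------------------------------------------------------
# time-domain features

def feature_ASM(x: np.ndarray) -> float:
    """Banded-exponent amplitude statistic.

    |x_i| is raised to 0.5 for 0.25 N <= i <= 0.75 N (1-based) and to 0.75
    elsewhere; the powered terms are averaged and the absolute value is
    returned.  Fractional powers act on |x_i| because the band-passed signal
    is signed.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("empty epoch")
    i = np.arange(1, n + 1)
    e = np.where((i >= 0.25 * n) & (i <= 0.75 * n), 0.5, 0.75)
    return float(abs(np.sum(np.abs(x) ** e)) / n)


def feature_ASS(x: np.ndarray) -> float:
    """Absolute sum of square roots of |x_i|."""
    return float(abs(np.sum(np.sqrt(np.abs(x)))))


def feature_LTKEO(x: np.ndarray) -> float:
    """ln of the summed Teager-Kaiser energy, sum(x_i^2 - x_{i-1} x_{i+1}).

    NaN sentinel when the sum is non-positive (e.g. constant sequences give
    exactly zero).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("LTKEO needs at least 3 samples")
    s = float(np.sum(x[1:-1] ** 2 - x[:-2] * x[2:]))
    return float(np.log(s)) if s > 0 else float("nan")


def feature_CARD(x: np.ndarray, threshold: float = DEFAULT_THRESHOLD,
                 order: str = "sorted", rng: np.random.Generator | None = None
                 ) -> float:
    """Cardinality: adjacent-pair gaps above the threshold after reordering.

    The default reorders by sorting, which makes the count the number of
    distinguishable amplitude levels (gaps > threshold between order
    statistics) and keeps the feature deterministic.  ``order="shuffle"``
    applies a literal random permutation instead (requires ``rng``).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("CARD needs at least 2 samples")
    if order == "sorted":
        z = np.sort(x)
    elif order == "shuffle":
        if rng is None:
            raise ValueError("shuffle order requires an rng")
        z = rng.permutation(x)
    else:
        raise ValueError(f"unknown order {order!r}")
    return float(np.sum(np.abs(np.diff(z)) > threshold))


def ar_coefficients(x: np.ndarray, order: int = 4) -> np.ndarray:
    """Yule-Walker AR coefficients a(1..order).

    Sign convention: y(n) = sum_k a(k) y(n - k) + e(n), i.e. a positive
    a(1) means positive lag-1 dependence.  Raises on zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < order + 1:
        raise ValueError(f"need at least {order + 1} samples for AR({order})")
    if np.std(x) == 0:
        raise ValueError("AR model undefined for a zero-variance epoch")
    rho, _ = yule_walker(x, order=order, method="adjusted")
    if not np.isfinite(rho).all():
        raise ValueError("singular autocovariance in AR fit")
    return np.asarray(rho, dtype=float)


def time_domain_features(x: np.ndarray, fs: float,
                         threshold: float = DEFAULT_THRESHOLD,
                         ar_order: int = 4) -> dict[str, float]:
    """All time-domain features of one epoch as a name -> value mapping."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    dx = np.diff(x)
    absx = np.abs(x)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    i = np.arange(1, n + 1)

    damv = float(np.sum(np.abs(dx)) / (n - 1))
    dasdv = float(np.sqrt(np.sum(dx**2) / (n - 1)))
    cov = sd / abs(mean) if mean != 0 else float("nan")

    # banded exponents (1-based index bands, as for ASM)
    p_emav = np.where((i >= 0.2 * n) & (i <= 0.8 * n), 0.75, 0.5)
    w_mmav = np.where((i >= 0.25 * n) & (i <= 0.75 * n), 1.0, 0.5)
    w_mmav2 = np.where(
        (i >= 0.25 * n) & (i <= 0.75 * n),
        1.0,
        np.where(i < 0.25 * n, 4.0 * i / n, 4.0 * (n - i) / n),
    )

    with np.errstate(divide="ignore"):
        log_absx_mean = float(np.mean(np.log(absx))) if n else float("-inf")

    if sd > 0 and n > ar_order:
        ar = ar_coefficients(x, order=ar_order)
    else:
        ar = np.full(ar_order, np.nan)

    sum_dx2 = float(np.sum(dx**2))
    out = {
        "ASM": feature_ASM(x),
        "ASS": feature_ASS(x),
        "AR1": float(ar[0]), "AR2": float(ar[1]),
        "AR3": float(ar[2]), "AR4": float(ar[3]),
        "AAC": float(np.sum(np.abs(dx)) / n),
        "AE": float(np.mean(x**2)),
        "CARD": feature_CARD(x, threshold=threshold),
        "COV": cov,
        "DAMV": damv,
        "DASDV": dasdv,
        "DVARV": float(np.sum(dx**2) / (n - 2)) if n > 2 else float("nan"),
        "EMAV": float(np.sum(absx**p_emav) / n),
        "EWL": float(np.sum(np.abs(dx) ** p_emav[1:])),
        "IEMG": float(np.sum(absx)),
        "IQR": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "KURT": float(spstats.kurtosis(x, fisher=False, bias=True)),
        "LCOV": float(np.log(cov)) if np.isfinite(cov) and cov > 0 else float("nan"),
        "LD": float(np.exp(log_absx_mean)),
        "LDMA": float(np.log(damv)) if damv > 0 else float("nan"),
        "LDASDA": float(np.log(dasdv)) if dasdv > 0 else float("nan"),
        "LTKEO": feature_LTKEO(x),
        "MFL": float(np.log10(np.sqrt(sum_dx2))) if sum_dx2 > 0 else float("nan"),
        "MAS": float(np.mean(np.abs(x - mean))),
        "MAV": float(np.mean(absx)),
        "MSR": float(np.mean(np.sqrt(absx))),
        "MMAV": float(np.sum(w_mmav * absx) / n),
        "MMAV2": float(np.sum(w_mmav2 * absx) / n),
        "MYOP": float(np.mean(absx >= threshold)),
        "FZC": float(np.sum(x[:-1] * x[1:] < 0)),
        "RMS": float(np.sqrt(np.mean(x**2))),
        "SSI": float(np.sum(x**2)),
        "Skew": float(spstats.skew(x, bias=True)),
        "SSC": float(np.sum((dx[:-1] * -dx[1:]) >= threshold)),
        "SD": sd,
        "TM": float(abs(np.mean(x**3))),
        "VAR": float(np.var(x, ddof=1)) if n > 1 else 0.0,
        "VARe": float(np.sum(x**2) / (n - 1)) if n > 1 else float("nan"),
        "VO": float(np.sqrt(np.mean(x**2))),
        "WL": float(np.sum(np.abs(dx))),
        "WA": float(np.sum(np.abs(dx) > threshold)),
        "ZC": float(
            np.sum((x[:-1] * x[1:] < 0) & (np.abs(x[:-1] - x[1:]) >= threshold))
        ),
        "DUR": n / fs,
    }
    return out


# --------------------------------------------------------------------------
# frequency-domain features

def power_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the detrended epoch, DC bin excluded."""
    f, p = sps.periodogram(np.asarray(x, dtype=float), fs=fs, detrend="constant")
    keep = f > 0
    return f[keep], p[keep]


def spectral_features(
    x: np.ndarray,
    fs: float,
    fr_split_hz: float = 135.0,
    fr_band: tuple[float, float] = (20.0, 250.0),
    psr_halfwidth_hz: float = 10.0,
) -> dict[str, float]:
    """Spectral statistics from a single periodogram.

    ``fr_split_hz`` splits the EMG band into the low/high halves used by the
    frequency ratio FR; ``psr_halfwidth_hz`` is the half-width of the band
    around the peak used by the power spectrum ratio PSR.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise ValueError("spectral features need at least 64 samples")
    f, p = power_spectrum(x, fs)
    total = float(np.sum(p))
    if total <= 0:
        raise ValueError("zero-power epoch: spectrum is degenerate")

    csum = np.cumsum(p)
    mdf = float(f[np.searchsorted(csum, 0.5 * total)])
    mnf = float(np.sum(f * p) / total)
    pkf = float(f[np.argmax(p)])
    low = (f >= fr_band[0]) & (f <= fr_split_hz)
    high = (f > fr_split_hz) & (f <= fr_band[1])
    high_power = float(np.sum(p[high]))
    fr = float(np.sum(p[low]) / high_power) if high_power > 0 else float("nan")
    near_peak = np.abs(f - pkf) <= psr_halfwidth_hz
    psr = float(np.sum(p[near_peak]) / total)
    sm = {f"SM{k}": float(np.sum(p * f**k)) for k in range(4)}
    vcf = sm["SM2"] / sm["SM0"] - (sm["SM1"] / sm["SM0"]) ** 2
    return {
        "MDF": mdf, "MNF": mnf, "FR": fr, "PKF": pkf, "PSR": psr,
        "MNP": float(np.mean(p)), **sm, "VCF": float(vcf),
    }


def wavelet_packet_features(
    x: np.ndarray, level: int = 3, wavelet: str = "db1"
) -> np.ndarray:
    """Euclidean norms of the 8 single-node wavelet packet reconstructions.

    The epoch is truncated to a multiple of 2**level so the periodized db1
    packet transform is exactly orthogonal: the squared node norms then sum
    to the squared norm of the (truncated) epoch.  Nodes are in natural
    order, so index 4 (feature WP5) is node (3, 4).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2**level:
        raise ValueError(f"need at least {2 ** level} samples for level {level}")
    n = (len(x) // 2**level) * 2**level
    x = x[:n]
    wp = pywt.WaveletPacket(x, wavelet, mode="periodization", maxlevel=level)
    norms = np.empty(2**level)
    for k, node in enumerate(wp.get_level(level, order="natural")):
        solo = pywt.WaveletPacket(
            np.zeros(n), wavelet, mode="periodization", maxlevel=level
        )
        solo[node.path] = node.data
        rec = solo.reconstruct(update=False)[:n]
        norms[k] = np.linalg.norm(rec)
    return norms


# --------------------------------------------------------------------------
# vector and table assembly

def compute_feature_vector(
    x: np.ndarray,
    fs: float,
    ar_order: int = 4,
    wp_level: int = 3,
    wavelet: str = "db1",
    threshold: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """The 63-value feature vector of one epoch, in registry order."""
    x = np.asarray(x, dtype=float)
    if len(x) < max(2**wp_level, ar_order + 1, 64):
        raise ValueError(
            f"epoch of {len(x)} samples is too short for the feature bank"
        )
    td = time_domain_features(x, fs, threshold=threshold, ar_order=ar_order)
    fd = spectral_features(x, fs)
    wp = wavelet_packet_features(x, level=wp_level, wavelet=wavelet)
    values = [td[f.name] for f in _TD]
    values += [fd[f.name] for f in _FD if f.base != "WP"]
    values += list(wp)
    return np.asarray(values, dtype=float)


def feature_table(epoch_set: EpochSet, fs: float, **kwargs) -> pd.DataFrame:
    """Feature table: one row per epoch, annotation columns + 63 features."""
    rows = []
    for k, ep in enumerate(epoch_set):
        vec = compute_feature_vector(ep.samples, fs, **kwargs)
        rows.append(
            {
                "subject": ep.subject_id,
                "group": ep.group,
                "channel": ep.channel,
                "trial": ep.trial_id,
                "epoch_index": k,
                **dict(zip(FEATURE_NAMES, vec)),
            }
        )
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS) + list(FEATURE_NAMES))
    return df


class ChannelwiseStandardizer:
    """Z-score each feature column per channel, pooled over both groups.

    scikit-learn style: ``fit`` learns per-(feature, channel) means and
    standard deviations from a feature table, ``transform`` applies them and
    ``inverse_transform`` undoes the scaling exactly.  Zero-variance cells
    are flagged and only centred.
    """

    def __init__(self, feature_names: tuple[str, ...] = FEATURE_NAMES):
        self.feature_names = tuple(feature_names)

    def get_params(self, deep: bool = True) -> dict:
        return {"feature_names": self.feature_names}

    def set_params(self, **params) -> "ChannelwiseStandardizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, table: pd.DataFrame, y=None) -> "ChannelwiseStandardizer":
        if len(table) < 2:
            raise ValueError("need at least 2 rows to standardize")
        loc: dict[tuple[str, str], float] = {}
        scale: dict[tuple[str, str], float] = {}
        flagged: list[tuple[str, str]] = []
        for channel, sub in table.groupby("channel", observed=True):
            for name in self.feature_names:
                col = sub[name].to_numpy(dtype=float)
                mu = float(np.nanmean(col))
                sd = float(np.nanstd(col, ddof=1))
                if not np.isfinite(sd) or sd == 0.0:
                    sd = 1.0
                    flagged.append((name, str(channel)))
                loc[(name, str(channel))] = mu
                scale[(name, str(channel))] = sd
        self.location_ = loc
        self.scale_ = scale
        self.flagged_ = tuple(flagged)
        return self

    def _apply(self, table: pd.DataFrame, invert: bool) -> pd.DataFrame:
        out = table.copy()
        for channel, idx in table.groupby("channel", observed=True).groups.items():
            for name in self.feature_names:
                mu = self.location_[(name, str(channel))]
                sd = self.scale_[(name, str(channel))]
                if invert:
                    out.loc[idx, name] = table.loc[idx, name] * sd + mu
                else:
                    out.loc[idx, name] = (table.loc[idx, name] - mu) / sd
        return out

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self._apply(table, invert=False)

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self._apply(table, invert=True)

    def fit_transform(self, table: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(table).transform(table)


def standardize_table(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, ChannelwiseStandardizer]:
    """Z-score a feature table per (feature, channel); returns the scaler."""
    scaler = ChannelwiseStandardizer()
    return scaler.fit_transform(table), scaler
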