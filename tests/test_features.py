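"""The 63-value feature bank against independent direct-summation,
matrix-transform and parameter-recovery oracles."""

import math

import numpy as np
import pytest
from scipy import stats as spstats

import isoemg
from isoemg.features import (FEATURE_NAMES, F12B_FEATURES, F16B_FEATURES,
                             FEATURE_REGISTRY, time_domain_features,
                             power_spectrum)


# ---------------------------------------------------------------------------
# independent oracles (plain-python direct evaluation)

def oracle_asm(x):
    n = len(x)
    total = 0.0
    for i, v in enumerate(x, start=1):
        e = 0.5 if (i >= 0.25 * n and i <= 0.75 * n) else 0.75
        total += abs(v) ** e
    return abs(total) / n


def oracle_ass(x):
    return abs(sum(math.sqrt(abs(v)) for v in x))


def oracle_ltkeo(x):
    s = sum(x[i] ** 2 - x[i - 1] * x[i + 1] for i in range(1, len(x) - 1))
    return math.log(s) if s > 0 else float("nan")


def oracle_card(x, thr=0.01):
    z = sorted(x)
    return sum(1 for a, b in zip(z, z[1:]) if abs(b - a) > thr)


def oracle_haar_packet_norms(x):
    """Node norms of a level-3 Haar packet transform built by explicit
    decimated recursion (orthogonal, so coefficient norm = reconstruction
    norm)."""
    x = np.asarray(x, dtype=float)

    def split(v):
        a = (v[0::2] + v[1::2]) / np.sqrt(2)
        d = (v[0::2] - v[1::2]) / np.sqrt(2)
        return a, d

    nodes = [x]
    for _ in range(3):
        nxt = []
        for v in nodes:
            a, d = split(v)
            nxt.extend([a, d])
        nodes = nxt
    return np.array([np.linalg.norm(v) for v in nodes])


def oracle_yule_walker(x, order=4):
    """Yule-Walker solved from adjusted (denominator n - k) autocovariances
    of the demeaned signal."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    n = len(x)
    r = np.array([np.sum(x[: n - k] * x[k:]) / (n - k) for k in range(order + 1)])
    R = np.array([[r[abs(i - j)] for j in range(order)] for i in range(order)])
    return np.linalg.solve(R, r[1:])


def oracle_spectral(x, fs):
    f, p = power_spectrum(x, fs)
    total = p.sum()
    mnf = float((f * p).sum() / total)
    pkf = float(f[np.argmax(p)])
    sm = [float((p * f**k).sum()) for k in range(4)]
    return {"MNF": mnf, "PKF": pkf, "SM0": sm[0], "SM1": sm[1],
            "SM2": sm[2], "SM3": sm[3]}


def random_epoch(rng, n=None):
    n = n or int(rng.integers(128, 513))
    return rng.standard_normal(n)


# ---------------------------------------------------------------------------

class TestVectorAssembly:
    def test_vector_has_63_values(self, rng):
        vec = isoemg.compute_feature_vector(rng.standard_normal(512), fs=1000)
        assert vec.shape == (63,)
        assert np.isfinite(vec).all()

    def test_registry_counts(self):
        assert len(FEATURE_NAMES) == 63
        td_bases = {f.base for f in FEATURE_REGISTRY if f.domain == "TD"}
        fd_bases = {f.base for f in FEATURE_REGISTRY if f.domain == "FD"}
        assert len(td_bases) == 41
        assert len(fd_bases) == 9
        assert set(F12B_FEATURES) < set(F16B_FEATURES) <= set(FEATURE_NAMES)

    def test_duration_is_n_over_fs(self, rng):
        vec = isoemg.compute_feature_vector(rng.standard_normal(2000), fs=1000)
        assert vec[FEATURE_NAMES.index("DUR")] == pytest.approx(2.0)

    def test_short_epoch_raises(self, rng):
        with pytest.raises(ValueError, match="too short"):
            isoemg.compute_feature_vector(rng.standard_normal(16), fs=1000)

    def test_simple_td_values_on_tiny_epoch(self):
        td = time_domain_features([1.0, 2.0, 3.0], fs=1000)
        assert td["SSI"] == pytest.approx(14.0)
        assert td["WL"] == pytest.approx(2.0)
        assert td["DAMV"] == pytest.approx(1.0)
        assert td["AAC"] == pytest.approx(2.0 / 3.0)


class TestNamedFeatures:
    def test_asm_zero_and_unit_epochs(self):
        assert isoemg.feature_ASM(np.zeros(8)) == 0.0
        assert isoemg.feature_ASM(np.ones(4)) == pytest.approx(1.0)

    def test_asm_exponent_banding(self):
        # direct evaluation with 1-based banded exponents
        x = np.array([4.0, 4.0, 4.0, 4.0])
        assert isoemg.feature_ASM(x) == pytest.approx(oracle_asm(x))
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.standard_normal(int(rng.integers(4, 50)))
            assert isoemg.feature_ASM(y) == pytest.approx(oracle_asm(y),
                                                          abs=1e-12)

    def test_ltkeo_examples(self):
        assert isoemg.feature_LTKEO([1, 2, 3, 2, 1]) == pytest.approx(
            math.log(7.0))
        assert math.isnan(isoemg.feature_LTKEO(np.full(10, 3.0)))
        assert math.isnan(isoemg.feature_LTKEO([1.0, 0.0, 1.0]))

    def test_card_examples(self, rng):
        assert isoemg.feature_CARD(np.full(10, 1.0)) == 0
        perm = rng.permutation([0.0, 1.0, 2.0, 3.0])
        assert isoemg.feature_CARD(perm) == 3
        x = rng.uniform(size=1000)
        assert isoemg.feature_CARD(x) == oracle_card(x)

    def test_card_shuffle_mode_requires_rng(self):
        with pytest.raises(ValueError, match="rng"):
            isoemg.feature_CARD(np.arange(5.0), order="shuffle")


class TestSpectralFeatures:
    def test_pure_tone(self):
        fs = 1000.0
        t = np.arange(4096) / fs
        x = np.sin(2 * np.pi * 100.0 * t)
        out = isoemg.spectral_features(x, fs)
        bin_width = fs / 4096
        assert abs(out["PKF"] - 100.0) <= bin_width
        assert abs(out["MNF"] - 100.0) <= 1.0
        assert abs(out["MDF"] - 100.0) <= 1.0
        assert out["PSR"] > 0.99

    def test_white_noise_mnf_near_quarter_fs(self, rng):
        vals = [isoemg.spectral_features(rng.standard_normal(8192), 1000.0)["MNF"]
                for _ in range(10)]
        assert np.mean(vals) == pytest.approx(250.0, abs=5.0)

    def test_sm0_is_total_power(self, rng):
        x = random_epoch(rng)
        f, p = power_spectrum(x, 1000.0)
        out = isoemg.spectral_features(x, 1000.0)
        assert out["SM0"] == pytest.approx(p.sum(), rel=1e-12)

    def test_zero_power_raises(self):
        with pytest.raises(ValueError, match="degenerate|zero-power"):
            isoemg.spectral_features(np.ones(128), 1000.0)


class TestWaveletPacketFeatures:
    def test_zero_epoch_all_zero(self):
        np.testing.assert_array_equal(
            isoemg.wavelet_packet_features(np.zeros(64)), np.zeros(8)
        )

    def test_orthogonality_energy_preserved(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 64)) * 8
            x = rng.standard_normal(n)
            norms = isoemg.wavelet_packet_features(x)
            assert np.sum(norms**2) == pytest.approx(np.sum(x**2), rel=1e-9)

    def test_matches_explicit_haar_recursion(self, rng):
        ramp = np.arange(64, dtype=float)
        np.testing.assert_allclose(
            isoemg.wavelet_packet_features(ramp),
            oracle_haar_packet_norms(ramp), atol=1e-9,
        )
        x = rng.standard_normal(256)
        np.testing.assert_allclose(
            isoemg.wavelet_packet_features(x),
            oracle_haar_packet_norms(x), atol=1e-9,
        )

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            isoemg.wavelet_packet_features(np.ones(4))


class TestARCoefficients:
    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(5)
        a = isoemg.ar_coefficients(rng.standard_normal(100_000))
        assert np.all(np.abs(a) < 0.02)

    def test_ar1_parameter_recovery(self):
        rng = np.random.default_rng(6)
        n = 100_000
        x = np.empty(n)
        x[0] = 0.0
        e = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = 0.5 * x[t - 1] + e[t]
        a = isoemg.ar_coefficients(x)
        assert a[0] == pytest.approx(0.5, abs=0.02)
        assert np.all(np.abs(a[1:]) < 0.02)

    def test_matches_manual_yule_walker(self, rng):
        for _ in range(5):
            x = random_epoch(rng, 400)
            np.testing.assert_allclose(
                isoemg.ar_coefficients(x), oracle_yule_walker(x), atol=1e-9
            )

    def test_constant_epoch_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            isoemg.ar_coefficients(np.full(100, 2.0))


class TestScalingLaws:
    def test_amplitude_scaling(self, rng):
        x = random_epoch(rng, 256)
        a = 3.7
        v1 = dict(zip(FEATURE_NAMES, isoemg.compute_feature_vector(x, 1000.0)))
        v2 = dict(zip(FEATURE_NAMES, isoemg.compute_feature_vector(a * x, 1000.0)))
        assert v2["SSI"] == pytest.approx(a**2 * v1["SSI"], rel=1e-9)
        for name in ("WL", "AAC", "DAMV", "SD", "MAV", "RMS", "IEMG"):
            assert v2[name] == pytest.approx(a * v1[name], rel=1e-9)
        for name in ("DUR", "FZC", "KURT", "Skew", "MNF", "PKF"):
            assert v2[name] == pytest.approx(v1[name], rel=1e-9)


class TestDirectSummationOracles:
    """Formula-defined features against independent plain-python sums."""

    def test_on_random_epochs(self, rng):
        for _ in range(25):
            x = random_epoch(rng)
            n = len(x)
            td = time_domain_features(x, fs=1000.0)
            assert td["ASM"] == pytest.approx(oracle_asm(x), abs=1e-9)
            assert td["ASS"] == pytest.approx(oracle_ass(x), rel=1e-9)
            assert td["AAC"] == pytest.approx(
                sum(abs(x[i + 1] - x[i]) for i in range(n - 1)) / n, rel=1e-9)
            assert td["DAMV"] == pytest.approx(
                sum(abs(x[i + 1] - x[i]) for i in range(n - 1)) / (n - 1),
                rel=1e-9)
            assert td["LTKEO"] == pytest.approx(oracle_ltkeo(x), rel=1e-9)
            assert td["SSI"] == pytest.approx(sum(v * v for v in x), rel=1e-9)
            assert td["SD"] == pytest.approx(
                math.sqrt(sum((v - np.mean(x)) ** 2 for v in x) / (n - 1)),
                rel=1e-9)
            assert td["WL"] == pytest.approx(
                sum(abs(x[i + 1] - x[i]) for i in range(n - 1)), rel=1e-9)
            assert td["CARD"] == oracle_card(x)
            assert td["DUR"] == pytest.approx(n / 1000.0, rel=1e-12)
            sp = oracle_spectral(x, 1000.0)
            out = isoemg.spectral_features(x, 1000.0)
            for k, v in sp.items():
                assert out[k] == pytest.approx(v, rel=1e-9)


class TestStandardization:
    def test_column_mean_zero_sd_one(self, small_table):
        for ch, sub in small_table.groupby("channel"):
            for name in FEATURE_NAMES:
                col = sub[name].to_numpy()
                assert np.nanmean(col) == pytest.approx(0.0, abs=1e-9)
                assert np.nanstd(col, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_restandardizing_changes_nothing(self, small_table):
        again, _ = isoemg.standardize_table(small_table)
        np.testing.assert_allclose(
            again[list(FEATURE_NAMES)].to_numpy(dtype=float),
            small_table[list(FEATURE_NAMES)].to_numpy(dtype=float),
            atol=1e-9,
        )

    def test_inverse_transform_roundtrip(self, small_epochs):
        eps, _ = small_epochs
        raw = isoemg.feature_table(eps, 1000.0)
        scaler = isoemg.ChannelwiseStandardizer()
        z = scaler.fit_transform(raw)
        back = scaler.inverse_transform(z)
        np.testing.assert_allclose(
            back[list(FEATURE_NAMES)].to_numpy(dtype=float),
            raw[list(FEATURE_NAMES)].to_numpy(dtype=float),
            atol=1e-9, rtol=1e-9,
        )

    def test_zero_variance_column_flagged_and_centred(self):
        import pandas as pd
        rows = []
        rng = np.random.default_rng(1)
        for i in range(10):
            rows.append({"subject": "S", "group": "amateur", "channel": "C1",
                         "trial": 1, "epoch_index": i,
                         **{n: rng.standard_normal() for n in FEATURE_NAMES}})
            rows[-1]["DUR"] = 2.0  # constant column
        t = pd.DataFrame(rows)
        scaler = isoemg.ChannelwiseStandardizer()
        z = scaler.fit_transform(t)
        assert ("DUR", "C1") in scaler.flagged_
        np.testing.assert_allclose(z["DUR"], 0.0, atol=1e-12)
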