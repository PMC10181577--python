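"""Feature bank: oracle agreement, degenerate conventions, scale behaviour."""

import math

import numpy as np
import pytest
from statsmodels.regression.linear_model import burg as sm_burg

import oracles
from ae_jointdx.featurebank import (
    FEATURE_NAMES,
    MFL_FLOOR,
    FeatureParams,
    extract_all,
    extract_complexity_features,
    extract_frequency_features,
    extract_time_features,
    fit_ar4,
)

SMALL = FeatureParams(dfa_box_sizes=tuple(range(10, 101, 10)))


def test_zero_input_gives_zero_time_features():
    out = extract_time_features(np.zeros(4), FeatureParams())
    assert all(v == 0.0 for v in out.values())


def test_alternating_unit_sequence():
    out = extract_time_features(np.array([1.0, -1.0, 1.0, -1.0]), FeatureParams())
    assert out["ZC"] == 3 and out["WL"] == 6 and out["MAV"] == 1 and out["RMS"] == 1


@pytest.mark.parametrize("seed", range(10))
def test_time_features_match_loop_oracle(seed):
    x = np.random.default_rng(seed).standard_normal(500)
    mine = extract_time_features(x, FeatureParams())
    ref = oracles.time_features_loop(list(x), 1e-6)
    for k, v in ref.items():
        assert mine[k] == pytest.approx(v, rel=1e-12, abs=1e-300)


def test_single_tone_peak_and_median_frequency():
    fs, n = 200_000.0, 1000
    f0 = 40 * fs / n  # exact bin
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * f0 * t)
    out = extract_frequency_features(x, fs, FeatureParams(psd_nperseg=n))
    bin_width = fs / n
    assert abs(out["PF"] - f0) <= bin_width
    assert abs(out["MF"] - f0) <= bin_width


def test_two_tone_median_frequency_between_tones(rng):
    fs, n = 100_000.0, 2000
    f1, f2 = 10 * fs / n, 200 * fs / n
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t)
    # single full-length segment so the explicit written-out estimator applies
    out = extract_frequency_features(x, fs, FeatureParams(psd_nperseg=n))
    assert f1 <= out["MF"] <= f2
    mf, pf = oracles.median_peak_frequency(x, fs)
    assert out["MF"] == pytest.approx(mf, rel=1e-12)
    assert out["PF"] == pytest.approx(pf, rel=1e-12)


def test_echo_cepstrum_peak_at_delay(rng):
    n, tau = 1024, 100
    s = rng.standard_normal(n)
    x = s + 0.5 * np.roll(s, tau)
    mag = np.abs(np.fft.fft(x))
    ceps = np.fft.ifft(np.log(mag)).real
    assert np.argmax(ceps[1 : n // 2 + 1]) + 1 == tau
    out = extract_frequency_features(x, 1.0, FeatureParams(psd_nperseg=n))
    assert out["Ceps"] == pytest.approx(oracles.max_real_cepstrum(x), rel=1e-12)


def test_degenerate_constant_window():
    x = np.full(300, 2.5)
    out = extract_complexity_features(x, SMALL)
    assert out["SampEn"] == 0.0
    assert out["MFL"] == MFL_FLOOR
    ar = fit_ar4(x, FeatureParams())
    assert all(v == 0.0 for v in ar.values())


def test_higuchi_known_dimensions():
    line = np.arange(1000, dtype=float)
    assert 0.95 <= extract_complexity_features(line, SMALL)["HFD"] <= 1.05
    noise = np.random.default_rng(3).standard_normal(5000)
    assert 1.9 <= oracles.higuchi_loop(noise, 10) <= 2.05
    assert extract_complexity_features(noise, FeatureParams())["HFD"] == pytest.approx(
        oracles.higuchi_loop(noise, 10), rel=1e-10
    )


def test_dfa_known_exponents_small():
    from ae_jointdx.featurebank import _dfa

    boxes = np.asarray(tuple(range(30, 301, 10)))
    alphas_w, alphas_b = [], []
    for s in range(10):
        w = np.random.default_rng(s).standard_normal(20_000)
        alphas_w.append(_dfa(w, boxes))
        alphas_b.append(_dfa(np.cumsum(w), boxes))
    assert abs(np.mean(alphas_w) - 0.5) < 0.05
    assert abs(np.mean(alphas_b) - 1.5) < 0.1


@pytest.mark.parametrize("seed", range(5))
def test_complexity_features_match_oracles(seed):
    x = np.random.default_rng(seed).standard_normal(400)
    out = extract_complexity_features(x, SMALL)
    assert out["SampEn"] == pytest.approx(oracles.sampen_cdist(x), abs=1e-12)
    assert out["HFD"] == pytest.approx(oracles.higuchi_loop(x, 10), rel=1e-12)
    assert out["DFA"] == pytest.approx(
        oracles.dfa_loop(x, range(10, 101, 10)), rel=1e-12
    )
    assert out["MFL"] == pytest.approx(
        math.log10(math.sqrt(np.sum(np.diff(x) ** 2))), rel=1e-12
    )


def test_burg_matches_reference_recursion_and_statsmodels(rng):
    x = np.random.default_rng(11).standard_normal(64)
    mine = np.array(list(fit_ar4(x, FeatureParams()).values()))
    np.testing.assert_allclose(mine, oracles.burg_loop(x, 4), atol=1e-10)
    sm_coeffs, _ = sm_burg(x, order=4, demean=True)
    np.testing.assert_allclose(mine, sm_coeffs, atol=1e-8)


def test_ar_process_coefficient_recovery():
    rng = np.random.default_rng(21)
    n = 10_000
    x = np.zeros(n)
    eps = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = 0.7 * x[t - 1] + eps[t]
    assert abs(fit_ar4(x, FeatureParams())["AR1"] - 0.7) < 0.05
    white = rng.standard_normal(n)
    assert all(abs(v) < 0.05 for v in fit_ar4(white, FeatureParams()).values())


def test_scale_behaviour_under_amplitude_scaling(rng):
    x = rng.standard_normal(600)
    c = 3.7
    p = FeatureParams(threshold=0.0, dfa_box_sizes=tuple(range(10, 101, 10)))
    a = extract_all(x, 1000.0, p)
    b = extract_all(c * x, 1000.0, p)
    for name in ("MAV", "RMS", "WL"):
        assert b[name] == pytest.approx(c * a[name], rel=1e-9)
    assert b["MFL"] == pytest.approx(a["MFL"] + math.log10(c), rel=1e-9)
    for name in ("ZC", "SSC", "NP", "HFD", "DFA", "SampEn"):
        assert b[name] == pytest.approx(a[name], rel=1e-9)


def test_extract_all_schema_and_determinism(rng):
    x = rng.standard_normal(1500)
    a = extract_all(x, 200_000.0, FeatureParams())
    b = extract_all(x, 200_000.0, FeatureParams())
    assert tuple(a) == FEATURE_NAMES and len(a) == 19
    assert all(np.isfinite(v) for v in a.values())
    assert a == b


def test_preconditions_raise():
    with pytest.raises(ValueError):
        extract_time_features(np.zeros(2), FeatureParams())
    with pytest.raises(ValueError):
        extract_frequency_features(np.zeros(4), 1000.0, FeatureParams())
    with pytest.raises(ValueError):
        extract_complexity_features(np.zeros(100), FeatureParams())  # box > len/2
    with pytest.raises(ValueError):
        fit_ar4(np.zeros(5), FeatureParams())
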