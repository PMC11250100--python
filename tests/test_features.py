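"""Feature bank: closed forms, brute-force oracles, invariants."""

import numpy as np
import pytest

import oracles
from epochsift.epoch_io import Epoch
from epochsift.features import (
    BANDS,
    DERIV_WINDOWS_MS,
    FEATURE_NAMES,
    MANIFEST_VERSION,
    Spectrum,
    amplitude_change,
    amplitude_variance,
    band_power,
    derivative_sum,
    extract_all,
    fd_kurtosis,
    fd_series,
    haar_details,
    haar_kurtosis,
    higuchi_fd,
    katz_fd,
    load_manifest,
    mean_local_skewness,
    periodogram,
    power_below_0p5hz,
    spectral_fit,
    temporal_kurtosis,
)

from conftest import random_epochs

FS = 2000.0


def ep(x, fs=FS, offset=None):
    x = np.asarray(x, float)
    if offset is None:
        offset = min(0.5, len(x) / fs)
    return Epoch(samples=x, fs=fs, event_offset=offset)


def test_manifest_matches_code():
    man = load_manifest()
    assert man["version"] == MANIFEST_VERSION
    assert tuple(man["features"]) == FEATURE_NAMES
    assert len(FEATURE_NAMES) == 31


# ---------------------------------------------------------------------------
# closed forms

def test_amplitude_change_ramp():
    # 1 µV/ms ramp sampled at 0.5 ms: any 100-sample window spans 49.5 µV
    t = np.arange(3000) / FS
    assert amplitude_change(ep(1000 * t)) == pytest.approx(49.5)


def test_amplitude_change_constant_zero():
    assert amplitude_change(ep(np.full(3000, 3.3))) == 0.0


def test_sine_kurtosis_closed_form():
    t = np.arange(3000) / FS
    x = 40 * np.sin(2 * np.pi * 10 * t)  # 15 full periods
    assert temporal_kurtosis(ep(x)) == pytest.approx(1.5, abs=0.01)


def test_gaussian_kurtosis_near_three(rng):
    x = rng.standard_normal(200_000)
    assert temporal_kurtosis(ep(x, offset=0.5)) == pytest.approx(3.0, abs=0.2)


def test_amplitude_variance_two_level_zero():
    x = np.tile([5.0, -5.0], 1500)
    assert amplitude_variance(ep(x)) == 0.0


def test_derivative_sum_sign_flip_invariant(rng):
    x = rng.standard_normal(3000)
    for w_ms in DERIV_WINDOWS_MS:
        a = derivative_sum(ep(x), w_ms / 1000)
        b = derivative_sum(ep(-x), w_ms / 1000)
        assert a == pytest.approx(b, rel=1e-12)


# ---------------------------------------------------------------------------
# brute-force oracles

@pytest.fixture(scope="module")
def oracle_epochs():
    return random_epochs(6, seed=42)


def test_amplitude_change_vs_bruteforce(oracle_epochs):
    for e in oracle_epochs:
        w = int(round(0.05 * e.fs))
        assert amplitude_change(e) == pytest.approx(
            oracles.amplitude_change_bf(e.samples, w), rel=1e-9
        )


def test_mean_local_skew_vs_bruteforce(oracle_epochs):
    for e in oracle_epochs:
        w = int(round(0.015 * e.fs))
        assert mean_local_skewness(e) == pytest.approx(
            oracles.mean_local_skew_bf(e.samples, w), rel=1e-9
        )


def test_kurtosis_vs_moment_formula(oracle_epochs):
    for e in oracle_epochs:
        assert temporal_kurtosis(e) == pytest.approx(
            oracles.kurtosis_bf(e.samples), rel=1e-9
        )


def test_amplitude_variance_vs_bruteforce(oracle_epochs):
    for e in oracle_epochs:
        assert amplitude_variance(e) == pytest.approx(
            oracles.amplitude_variance_bf(e.samples), rel=1e-9
        )


@pytest.mark.parametrize("w_ms", DERIV_WINDOWS_MS)
def test_derivative_sum_vs_bruteforce(oracle_epochs, w_ms):
    e = oracle_epochs[0]
    w = int(round(w_ms / 1000 * e.fs))
    assert derivative_sum(e, w_ms / 1000) == pytest.approx(
        oracles.derivative_sum_bf(e.samples, w), rel=1e-9
    )


def test_band_power_vs_bruteforce(oracle_epochs):
    e = oracle_epochs[1]
    spec = periodogram(e)
    for lo, hi in BANDS.values():
        assert band_power(spec, (lo, hi)) == pytest.approx(
            oracles.band_power_bf(spec.freqs, spec.power, lo, hi), rel=1e-9
        )


def test_spectral_fit_vs_closed_form_regression(oracle_epochs):
    e = oracle_epochs[2]
    spec = periodogram(e)
    for band in BANDS.values():
        lam, c, err = spectral_fit(spec, band)
        lam_o, c_o, err_o = oracles.spectral_fit_bf(spec.freqs, spec.power, *band)
        assert lam == pytest.approx(lam_o, rel=1e-8)
        assert err == pytest.approx(err_o, rel=1e-8)


def test_fd_estimators_vs_bruteforce(oracle_epochs):
    e = oracle_epochs[3]
    wins = [e.samples[s : s + 200] for s in range(0, 3000 - 199, 100)]
    for w in wins[:5]:
        assert katz_fd(w) == pytest.approx(oracles.katz_bf(w), rel=1e-9)
        assert higuchi_fd(w) == pytest.approx(oracles.higuchi_bf(w), rel=1e-9)


def test_fd_kurtosis_is_kurtosis_of_series(oracle_epochs):
    e = oracle_epochs[4]
    for method in ("higuchi", "katz"):
        series = fd_series(e, method)
        assert fd_kurtosis(e, method) == pytest.approx(
            oracles.kurtosis_bf(series), rel=1e-9
        )


def test_haar_details_vs_manual_pyramid(oracle_epochs):
    e = oracle_epochs[5]
    ours = np.sort(haar_details(e.samples))
    manual = np.sort(oracles.haar_details_bf(e.samples))
    np.testing.assert_allclose(ours, manual, rtol=1e-9, atol=1e-12)


def test_haar_level1_details_direct_formula():
    x = np.arange(16.0) ** 2
    d1 = haar_details(x)[:8]
    expect = (x[::2] - x[1::2]) / np.sqrt(2)
    np.testing.assert_allclose(np.sort(np.abs(d1)), np.sort(np.abs(expect)), rtol=1e-12)


# ---------------------------------------------------------------------------
# spectra

def test_parseval_identity(oracle_epochs):
    for e in oracle_epochs:
        spec = periodogram(e)
        total = spec.power.sum() * spec.df
        assert total == pytest.approx(np.mean(e.samples**2), rel=1e-9)


def test_pure_sine_power_in_alpha():
    t = np.arange(3000) / FS
    a = 25.0
    x = a * np.sin(2 * np.pi * 10 * t)
    spec = periodogram(ep(x))
    total = spec.power.sum() * spec.df
    assert total == pytest.approx(a**2 / 2, rel=1e-9)
    alpha = band_power(spec, BANDS["alpha"])
    assert alpha > 0.95 * total
    assert power_below_0p5hz(spec) < 0.01 * total


def test_low_frequency_line_power():
    # a 0.3 Hz line on a long epoch lands almost entirely below 0.5 Hz
    fs, dur = 200.0, 60.0
    t = np.arange(int(fs * dur)) / fs
    a = 10.0
    x = a * np.sin(2 * np.pi * 0.3 * t)
    spec = periodogram(Epoch(samples=x, fs=fs, event_offset=0.5))
    assert power_below_0p5hz(spec) == pytest.approx(a**2 / 2, rel=0.05)


def test_spectral_fit_exact_power_law():
    f = np.linspace(0.5, 100, 400)
    spec = Spectrum(freqs=f, power=f**-2.0)
    lam, c, err = spectral_fit(spec, (1.0, 80.0))
    assert lam == pytest.approx(-2.0, abs=1e-10)
    assert err == pytest.approx(0.0, abs=1e-10)


def test_spectral_fit_planted_residual():
    f = np.geomspace(1, 64, 7)
    resid = np.array([0.1, -0.1, 0.1, -0.1, 0.1, -0.1, 0.0])
    resid -= resid.mean()  # orthogonalise to the intercept
    logf = np.log10(f)
    # orthogonalise to the slope direction too, then the fit recovers it
    logf_c = logf - logf.mean()
    resid -= logf_c * (resid @ logf_c) / (logf_c @ logf_c)
    power = 10 ** (-1.5 * logf + 0.3 + resid)
    spec = Spectrum(freqs=f, power=power)
    lam, c, err = spectral_fit(spec, (0.5, 100))
    assert lam == pytest.approx(-1.5, abs=1e-9)
    assert err == pytest.approx(np.sqrt(np.mean(resid**2)), rel=1e-9)


def test_spectral_fit_too_few_bins_convention():
    spec = Spectrum(freqs=np.array([1.0, 2.0, 3.0]), power=np.ones(3))
    assert spectral_fit(spec, (1.0, 2.5)) == (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# fractal dimension closed forms

def test_katz_straight_line_is_one():
    assert katz_fd(np.linspace(0, 5, 200)) == pytest.approx(1.0, abs=1e-12)


def test_higuchi_white_noise_near_two(rng):
    fds = [higuchi_fd(rng.standard_normal(200)) for _ in range(50)]
    assert np.mean(fds) == pytest.approx(2.0, abs=0.15)


def test_haar_spike_heavy_tailed():
    x = np.zeros(3000)
    x[1500] = 100.0
    assert haar_kurtosis(ep(x)) > 3.0


# ---------------------------------------------------------------------------
# invariants

def test_scale_invariance_and_scaling_laws(oracle_epochs):
    e = oracle_epochs[0]
    c = 7.3
    e2 = e.with_samples(c * e.samples)
    for fn in (mean_local_skewness, temporal_kurtosis, haar_kurtosis):
        assert fn(e2) == pytest.approx(fn(e), rel=1e-9)
    for method in ("higuchi", "katz"):
        # FD of a scaled window differs slightly (Katz mixes time and
        # amplitude units) but Higuchi's log-log slope is exactly invariant
        if method == "higuchi":
            assert fd_kurtosis(e2, method) == pytest.approx(
                fd_kurtosis(e, method), rel=1e-9
            )
    spec, spec2 = periodogram(e), periodogram(e2)
    for band in BANDS.values():
        assert spectral_fit(spec2, band)[0] == pytest.approx(
            spectral_fit(spec, band)[0], rel=1e-9
        )
    assert amplitude_change(e2) == pytest.approx(c * amplitude_change(e), rel=1e-9)
    assert amplitude_variance(e2) == pytest.approx(
        c**4 * amplitude_variance(e), rel=1e-9
    )


def test_constant_epoch_degenerate_conventions():
    fv = extract_all(ep(np.full(3000, 2.0)))
    assert all(np.isfinite(v) for v in fv.values())
    for name in ("mean_local_skew_15ms", "temporal_kurtosis", "amplitude_variance",
                 "haar_kurtosis", "fd_kurtosis_higuchi", "fd_kurtosis_katz",
                 "amplitude_change_50ms", "deriv_sum_50ms", "power_below_0p5hz"):
        assert fv[name] == 0.0


def test_extract_all_deterministic_and_ordered(clean_epoch):
    a = extract_all(clean_epoch)
    b = extract_all(clean_epoch)
    assert a == b
    assert tuple(a.keys()) == FEATURE_NAMES


def test_artefact_moves_many_features(gen_spec):
    from epochsift.synthetic import gen_clean_epoch, inject_artefact

    rng = np.random.default_rng(5)
    clean = gen_clean_epoch(gen_spec, rng)
    art = inject_artefact(clean, "movement_burst", rng)
    fa, fb = extract_all(clean), extract_all(art)
    moved = [
        k for k in FEATURE_NAMES
        if abs(fb[k] - fa[k]) > 0.1 * max(abs(fa[k]), 1e-12)
    ]
    assert len(moved) >= 5
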