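"""Feature estimators against closed-form and simulation oracles."""

import numpy as np
import pandas as pd
import pytest

from nleeg import (
    ConditionFragment,
    FeatureParams,
    envelope,
    envelope_cv,
    envelope_mean_frequency,
    extract_all,
    gen_colored_noise,
    gen_fbm,
    higuchi_fd,
    hjorth_complexity,
    hjorth_mobility,
    psd_unit_bins,
)
from nleeg.exceptions import (
    DegenerateEnvelopeWarning,
    DegenerateInputError,
    ParameterError,
)
from nleeg.features import FEATURES, PSD_BIN_NAMES
from nleeg.preprocessing import WIDEBAND, bandpass
from nleeg.simulate import _band_noise
from tests.conftest import FS, am_signal, sine


# ---------------------------------------------------------------------------
# Higuchi fractal dimension
# ---------------------------------------------------------------------------

def test_fd_linear_ramp_exact():
    """A straight line has curve length L(k) ~ 1/k exactly, so FD = 1."""
    assert higuchi_fd(np.arange(1000.0), k_max=8) == pytest.approx(1.0, abs=1e-6)


def test_fd_white_noise_asymptote():
    """Uncorrelated noise fills the plane: FD -> 2."""
    fds = [higuchi_fd(np.random.default_rng(s).standard_normal(10000), 8)
           for s in range(50)]
    assert 1.95 <= np.mean(fds) <= 2.05


@pytest.mark.parametrize("hurst", [0.2, 0.5, 0.8])
def test_fd_fbm_recovery(hurst):
    """For fractional Brownian motion FD = 2 - H (exact-covariance oracle)."""
    fds = [higuchi_fd(gen_fbm(5000, hurst, s), 8) for s in range(50)]
    assert np.mean(fds) == pytest.approx(2.0 - hurst, abs=0.1)


def test_fd_monotone_in_hurst():
    hs = [0.2, 0.35, 0.5, 0.65, 0.8]
    means = [np.mean([higuchi_fd(gen_fbm(5000, h, s), 8) for s in range(50)])
             for h in hs]
    assert all(a > b for a, b in zip(means, means[1:]))


def test_fd_degenerate_and_parameter_errors():
    with pytest.raises(DegenerateInputError):
        higuchi_fd(np.ones(1000), 8)
    with pytest.raises(ParameterError):
        higuchi_fd(np.arange(1000.0), 1)
    with pytest.raises(ParameterError):
        higuchi_fd(np.arange(20.0), 8)


# ---------------------------------------------------------------------------
# Hjorth parameters
# ---------------------------------------------------------------------------

def test_hjorth_sine_closed_forms():
    """First-difference mobility of a sinusoid is 2 sin(pi f / fs);
    its complexity is 1 (a pure tone has zero bandwidth)."""
    x = sine(10.0, 10.0)
    assert hjorth_mobility(x) == pytest.approx(2 * np.sin(np.pi * 10 / FS),
                                               rel=0.01)
    assert hjorth_complexity(x) == pytest.approx(1.0, rel=0.01)


def test_hjorth_white_noise_closed_forms():
    """var(dx) = 2 sigma^2 and var(d2x) = 6 sigma^2 for i.i.d. noise."""
    x = np.random.default_rng(7).standard_normal(100000)
    assert hjorth_mobility(x) == pytest.approx(np.sqrt(2), rel=0.02)
    assert hjorth_complexity(x) == pytest.approx(np.sqrt(1.5), rel=0.02)


def test_hjorth_zero_variance():
    with pytest.raises(DegenerateInputError):
        hjorth_mobility(np.ones(100))
    with pytest.raises(DegenerateInputError):
        hjorth_complexity(np.arange(100.0))  # first difference constant


def test_hjorth_spectral_moment_equivalence():
    """Time-domain Hjorth parameters match the periodogram spectral-moment
    forms sqrt(m2/m0) and sqrt(m4 m0)/m2 within 1% on 100 random
    band-limited signals (Parseval)."""
    n = 5000
    freqs = np.fft.rfftfreq(n, 1 / FS)
    sel = (freqs >= 2) & (freqs <= 20)
    omega = 2 * np.pi * freqs / FS
    for s in range(100):
        rng = np.random.default_rng(s)
        spec = np.zeros(n // 2 + 1, complex)
        spec[sel] = (rng.uniform(0.2, 1, sel.sum())
                     * np.exp(1j * rng.uniform(0, 2 * np.pi, sel.sum())))
        x = np.fft.irfft(spec, n)
        p = np.abs(np.fft.rfft(x - x.mean())) ** 2
        m0, m2, m4 = p.sum(), (omega ** 2 * p).sum(), (omega ** 4 * p).sum()
        assert hjorth_mobility(x) == pytest.approx(np.sqrt(m2 / m0), rel=0.01)
        assert hjorth_complexity(x) == pytest.approx(np.sqrt(m4 * m0) / m2,
                                                     rel=0.01)


# ---------------------------------------------------------------------------
# Envelope metrics
# ---------------------------------------------------------------------------

def test_envelope_constant_carrier():
    env = envelope(sine(10.0, 20.0), FS)
    assert np.abs(env - 1.0).max() < 0.02


def test_envelope_am_recovery():
    """Analytic-signal envelope of a narrowband AM signal recovers the
    modulator."""
    x = am_signal(depth=0.5)
    env = envelope(x, FS)
    t = np.arange(int(20 * FS)) / FS
    modulator = 1 + 0.5 * np.cos(2 * np.pi * 2.0 * t)
    trim = int(0.5 * FS)
    expected = modulator[trim:-trim]
    rms_err = np.sqrt(np.mean((env - expected) ** 2)) / expected.mean()
    assert rms_err < 0.03


def test_envelope_zero_signal():
    with pytest.raises(DegenerateInputError):
        envelope(np.zeros(1000), FS)


def test_emf_single_modulator():
    env = envelope(am_signal(0.5, mod_hz=2.0), FS)
    assert envelope_mean_frequency(env, FS) == pytest.approx(2.0, abs=0.2)


def test_emf_two_equal_modulators():
    """Centroid of equal spectral lines at 1 and 3 Hz is 2 Hz."""
    t = np.arange(int(20 * FS)) / FS
    x = (1 + 0.25 * np.cos(2 * np.pi * 1 * t)
         + 0.25 * np.cos(2 * np.pi * 3 * t)) * np.sin(2 * np.pi * 10 * t)
    env = envelope(x, FS)
    assert envelope_mean_frequency(env, FS) == pytest.approx(2.0, abs=0.2)


def test_emf_constant_envelope_degenerate():
    env = envelope(sine(10.0, 20.0), FS)
    with pytest.warns(DegenerateEnvelopeWarning):
        assert envelope_mean_frequency(env, FS) == 0.0


def test_emf_peak_mode():
    env = envelope(am_signal(0.5, mod_hz=2.0), FS)
    assert envelope_mean_frequency(env, FS, mode="peak") == pytest.approx(
        2.0, abs=0.2)


def test_rat_constant_envelope():
    assert envelope_cv(envelope(sine(10.0, 20.0), FS)) < 0.02


@pytest.mark.parametrize("depth", [0.5, 0.8])
def test_rat_am_depth(depth):
    """CV of 1 + m cos(wt) is m / sqrt(2)."""
    env = envelope(am_signal(depth), FS)
    assert envelope_cv(env) == pytest.approx(depth / np.sqrt(2), rel=0.05)


def test_rat_degenerate():
    with pytest.raises(DegenerateInputError):
        envelope_cv(np.zeros(100))


# ---------------------------------------------------------------------------
# PSD unit bins
# ---------------------------------------------------------------------------

def test_psd_sine_power_and_localization():
    """A unit sine carries A^2/2 = 0.5 uV^2, concentrated in its bin."""
    bins = psd_unit_bins(sine(10.5, 60.0), FS)
    total = bins.power.sum()
    assert total == pytest.approx(0.5, rel=0.05)
    assert bins.power[8] / total >= 0.95          # the 10-11 Hz bin


def test_psd_white_noise_flat():
    powers = np.mean([psd_unit_bins(
        np.random.default_rng(s).standard_normal(int(60 * FS)), FS).power
        for s in range(20)], axis=0)
    assert powers.max() / powers.min() < 1.2


def test_psd_parseval():
    """Bin sum over 2-20 Hz recovers the variance of a band-limited signal."""
    rng = np.random.default_rng(3)
    x = _band_noise(int(60 * FS), FS, 3.0, 18.0, rng) * 12.0
    bins = psd_unit_bins(x, FS)
    assert bins.power.sum() == pytest.approx(np.var(x), rel=0.05)


def test_psd_too_short():
    with pytest.raises(ParameterError):
        psd_unit_bins(np.zeros(100), FS)


# ---------------------------------------------------------------------------
# Invariances and sign structure
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("scale", [1e-3, 0.5, 1.0, 7.3, 1e3])
def test_amplitude_scale_invariance(scale):
    """FD, Hjorth, EMF and RAT are invariant under positive rescaling."""
    rng = np.random.default_rng(11)
    x = bandpass(rng.standard_normal(5000) * 10, FS, WIDEBAND)
    env = envelope(x, FS)
    env_s = envelope(scale * x, FS)
    assert higuchi_fd(scale * x, 8) == pytest.approx(higuchi_fd(x, 8), rel=1e-6)
    assert hjorth_mobility(scale * x) == pytest.approx(hjorth_mobility(x),
                                                       rel=1e-6)
    assert hjorth_complexity(scale * x) == pytest.approx(hjorth_complexity(x),
                                                         rel=1e-6)
    assert envelope_mean_frequency(env_s, FS) == pytest.approx(
        envelope_mean_frequency(env, FS), rel=1e-6)
    assert envelope_cv(env_s) == pytest.approx(envelope_cv(env), rel=1e-6)


def test_sign_structure_slow_and_fast_power():
    """Adding slow (2-6 Hz) power to a fixed-alpha signal lowers EMF and the
    Hjorth parameters and raises RAT; adding fast (15-19 Hz) power raises
    EMF."""
    rng = np.random.default_rng(5)
    n = int(40 * FS)
    # alpha-dominated base: added power acts through cross-beating with the
    # alpha carrier (the regime of alpha-rich resting EEG)
    base = gen_colored_noise(n, FS, 1.0, rng) * 5 + 15 * sine(10.5, 40.0)

    def metrics(x):
        wb = bandpass(x, FS, WIDEBAND)
        env = envelope(wb, FS)
        return {
            "EMF": envelope_mean_frequency(env, FS),
            "RAT": envelope_cv(env),
            "mob": hjorth_mobility(wb),
            "cplx": hjorth_complexity(wb),
        }

    ref = metrics(base)
    slow = metrics(base + _band_noise(n, FS, 2.0, 6.0, rng) * 20)
    fast = metrics(base + _band_noise(n, FS, 15.0, 19.0, rng) * 4)
    assert slow["EMF"] < ref["EMF"]
    assert slow["mob"] < ref["mob"]
    assert slow["RAT"] > ref["RAT"]
    assert fast["EMF"] > ref["EMF"]


# ---------------------------------------------------------------------------
# extract_all orchestration
# ---------------------------------------------------------------------------

def _fragment(rng, n_channels=19, n_epochs=2, dur_s=8.0):
    from nleeg.io import PAPER_CHANNELS
    epochs = [rng.standard_normal((n_channels, int(dur_s * FS))) * 15
              for _ in range(n_epochs)]
    return ConditionFragment(condition="laughter", epochs=epochs, fs=FS,
                             subject_id="s01", group="control",
                             channel_labels=PAPER_CHANNELS[:n_channels])


def test_extract_all_row_counts():
    feats, psd = extract_all(_fragment(np.random.default_rng(0)))
    assert len(feats) == 19 * 6
    assert len(psd) == 19
    assert set(feats["feature"]) == set(FEATURES)
    assert all(c in psd.columns for c in PSD_BIN_NAMES)


def test_extract_all_duplicate_epochs_idempotent():
    rng = np.random.default_rng(1)
    frag = _fragment(rng, n_channels=2, n_epochs=1)
    twice = ConditionFragment("laughter", frag.epochs * 2, FS, "s01",
                              "control", frag.channel_labels)
    f1, p1 = extract_all(frag)
    f2, p2 = extract_all(twice)
    pd.testing.assert_frame_equal(f1, f2)
    pd.testing.assert_frame_equal(p1, p2)


def test_extract_all_epoch_order_invariant():
    rng = np.random.default_rng(2)
    frag = _fragment(rng, n_channels=2, n_epochs=3)
    rev = ConditionFragment("laughter", frag.epochs[::-1], FS, "s01",
                            "control", frag.channel_labels)
    f1, _ = extract_all(frag)
    f2, _ = extract_all(rev)
    pd.testing.assert_frame_equal(f1, f2)


def test_extract_all_rejects_everything_warns():
    rng = np.random.default_rng(3)
    frag = _fragment(rng, n_channels=2, n_epochs=2)
    params = FeatureParams(artifact_threshold_uv=0.001)
    with pytest.warns(UserWarning, match="rejected"):
        feats, psd = extract_all(frag, params)
    assert feats.empty and psd.empty
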