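"""Nonlinear/time-domain EEG features and unit-bin power spectral density.

Six features are computed per channel and condition:

``FD``
    Higuchi fractal dimension of the 2-20 Hz band-limited signal. For
    k = 1..k_max the mean normalized curve length L(k) is computed over the
    k sub-series offsets; FD is minus the slope of the least-squares fit of
    ln L(k) on ln k. FD is 1 for smooth curves and approaches 2 for
    uncorrelated noise; for fractional Brownian motion FD = 2 - H.
``HjorthMobility`` / ``HjorthComplexity``
    mobility = sqrt(var(y') / var(y)); complexity = mobility(y') /
    mobility(y), with the derivative taken as the unscaled first difference
    (per-sample convention). Mobility is a time-domain proxy for mean
    frequency; complexity equals 1 for a pure sinusoid and grows with
    bandwidth. Computed on the wideband (1.6-30 Hz) signal.
``EMF`` / ``EMFA``
    Mean frequency of the amplitude envelope (Hilbert-transform magnitude)
    of the wideband / alpha-band (8-13 Hz) signal: the amplitude-spectrum
    centroid of the mean-removed envelope over (0, f_cap] Hz. Indexes how
    fast a rhythm waxes and wanes ((de)synchronization dynamics).
``RAT``
    Coefficient of variation (std/mean) of the wideband envelope -
    envelope amplitude instability. For an AM signal of modulation depth m
    this is m/sqrt(2); for a stationary Gaussian process the envelope is
    Rayleigh and RAT ~ 0.52.

PSD is a Welch estimate integrated over unit-width bins 2-3, 3-4, ...,
19-20 Hz, normalized so the integral over all frequencies equals the
signal variance (microvolts squared per bin).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import DegenerateEnvelopeWarning, DegenerateInputError, ParameterError
from .io import ConditionFragment
from .preprocessing import (
    ALPHA_BAND,
    DEFAULT_ARTIFACT_THRESHOLD_UV,
    FD_BAND,
    WIDEBAND,
    BandSpec,
    bandpass,
    reject_artifacts,
)

logger = logging.getLogger(__name__)

FEATURES = ["FD", "EMF", "EMFA", "RAT", "HjorthMobility", "HjorthComplexity"]

#: Unit-width PSD bin edges: [2,3), [3,4), ..., [19,20) Hz.
PSD_BIN_EDGES = np.arange(2, 21, dtype=float)
PSD_BIN_NAMES = [f"psd_{lo:.0f}_{lo + 1:.0f}" for lo in PSD_BIN_EDGES[:-1]]


@dataclass(frozen=True)
class FeatureParams:
    """Tunable feature-extraction parameters (defaults used throughout)."""

    k_max: int = 8                 # Higuchi curve-length lags
    emf_cap_hz: float = 12.0       # envelope-frequency centroid cap
    emf_mode: str = "centroid"     # centroid | peak
    trim_s: float = 0.5            # envelope edge guard per side
    artifact_threshold_uv: float = DEFAULT_ARTIFACT_THRESHOLD_UV
    filter_mode: str = "zero_phase"
    psd_window_s: float = 4.0      # Welch segment length
    wideband: BandSpec = WIDEBAND
    fd_band: BandSpec = FD_BAND
    alpha_band: BandSpec = ALPHA_BAND


@dataclass
class PsdBins:
    """Band power integrated over the 18 unit-width bins."""

    power: np.ndarray              # (18,) microvolts^2
    edges: np.ndarray = field(default_factory=lambda: PSD_BIN_EDGES.copy())
    channel: str = ""
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.edges) - 1,):
            raise ParameterError("PsdBins power must have one value per bin")
        if (self.power < 0).any():
            raise ParameterError("bin powers must be non-negative")


# ---------------------------------------------------------------------------
# Higuchi fractal dimension
# ---------------------------------------------------------------------------

def higuchi_fd(x: np.ndarray, k_max: int = 8) -> float:
    """Higuchi fractal dimension of a 1-D series."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if k_max < 2:
        raise ParameterError("k_max must be >= 2")
    if n < 10 * k_max:
        raise ParameterError(f"need >= {10 * k_max} samples for k_max={k_max}, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant signal has no curve-length scaling")

    log_k = np.empty(k_max)
    log_l = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            sub = x[m::k]
            n_m = sub.size - 1
            if n_m < 1:
                continue
            dist = np.abs(np.diff(sub)).sum()
            # normalization maps the sub-series span back to n-1 samples
            lengths.append(dist * (n - 1) / (n_m * k) / k)
        log_k[k - 1] = np.log(k)
        log_l[k - 1] = np.log(np.mean(lengths))
    slope = np.polyfit(log_k, log_l, 1)[0]
    return float(-slope)


# ---------------------------------------------------------------------------
# Hjorth parameters
# ---------------------------------------------------------------------------

def hjorth_mobility(x: np.ndarray) -> float:
    """sqrt(var(first difference) / var(signal))."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ParameterError("need >= 3 samples")
    v0 = np.var(x)
    if v0 <= 0:
        raise DegenerateInputError("zero-variance signal")
    return float(np.sqrt(np.var(np.diff(x)) / v0))


def hjorth_complexity(x: np.ndarray) -> float:
    """mobility(first difference) / mobility(signal); 1 for a pure sinusoid."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ParameterError("need >= 4 samples")
    d = np.diff(x)
    if np.var(d) <= 0:
        raise DegenerateInputError("zero-variance first difference")
    return float(hjorth_mobility(d) / hjorth_mobility(x))


# ---------------------------------------------------------------------------
# Envelope metrics
# ---------------------------------------------------------------------------

def envelope(x: np.ndarray, fs: float, trim_s: float = 0.5) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic (Hilbert) signal.

    ``trim_s`` seconds are dropped from each end to guard against the
    transform's edge transients before any downstream statistic.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ParameterError("need >= 64 samples for a stable envelope")
    if not np.any(x):
        raise DegenerateInputError("all-zero signal has no envelope")
    env = np.abs(sps.hilbert(x))
    trim = int(round(trim_s * fs))
    if trim:
        if x.size - 2 * trim < 8:
            raise ParameterError("series too short for the requested edge trim")
        env = env[trim:-trim]
    return env


def envelope_mean_frequency(env: np.ndarray, fs: float, f_cap_hz: float = 12.0,
                            mode: str = "centroid",
                            degenerate_rel_std: float = 0.02) -> float:
    """Mean frequency (Hz) of envelope fluctuations.

    Amplitude-spectrum centroid of the mean-removed envelope over
    (0, f_cap_hz]; ``mode="peak"`` reports the peak frequency instead. A
    near-constant envelope (relative std below ``degenerate_rel_std``) has
    no oscillatory energy: 0.0 is returned with a
    :class:`DegenerateEnvelopeWarning`.
    """
    env = np.asarray(env, dtype=float)
    if env.size < 2 * fs:
        raise ParameterError("need >= 2 s of envelope samples")
    mean = env.mean()
    if mean <= 0 or env.std() <= degenerate_rel_std * mean:
        warnings.warn("envelope is (near-)constant; mean frequency reported as 0",
                      DegenerateEnvelopeWarning)
        return 0.0
    amp = np.abs(np.fft.rfft(env - mean))
    freqs = np.fft.rfftfreq(env.size, d=1.0 / fs)
    sel = (freqs > 0) & (freqs <= f_cap_hz)
    if mode == "centroid":
        return float((freqs[sel] * amp[sel]).sum() / amp[sel].sum())
    if mode == "peak":
        return float(freqs[sel][np.argmax(amp[sel])])
    raise ParameterError(f"unknown EMF mode {mode!r}")


def envelope_cv(env: np.ndarray) -> float:
    """Coefficient of variation std/mean of an (already trimmed) envelope."""
    env = np.asarray(env, dtype=float)
    mean = env.mean()
    if mean <= 0 or not np.isfinite(mean):
        raise DegenerateInputError("envelope mean must be positive")
    return float(env.std() / mean)


# ---------------------------------------------------------------------------
# Power spectral density in unit bins
# ---------------------------------------------------------------------------

def psd_unit_bins(x: np.ndarray, fs: float, window_s: float = 4.0,
                  **meta) -> PsdBins:
    """Welch PSD integrated over [b, b+1) Hz for b = 2..19.

    Hann windows of ``window_s`` seconds with 50% overlap, density scaling;
    bins are Riemann sums of the density over the half-open interval, so
    the sum over all frequencies recovers the signal variance (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * fs:
        raise ParameterError("need >= 2 s of signal for the PSD")
    nperseg = min(int(round(window_s * fs)), x.size)
    freqs, pxx = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, detrend="constant",
                           scaling="density")
    df = freqs[1] - freqs[0]
    power = np.empty(len(PSD_BIN_EDGES) - 1)
    for i, lo in enumerate(PSD_BIN_EDGES[:-1]):
        sel = (freqs >= lo) & (freqs < lo + 1)
        power[i] = pxx[sel].sum() * df
    return PsdBins(power=power, **meta)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def extract_all(fragment: ConditionFragment,
                params: FeatureParams = FeatureParams()
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute all six features and the unit-bin PSD for one fragment.

    Each epoch is wideband filtered, screened by peak-amplitude artifact
    rejection, and processed independently; per-channel values are then
    averaged across surviving epochs (computing per epoch avoids the phase
    discontinuities concatenation would introduce into the Hilbert and FFT
    steps). Returns (long-format feature rows, per-channel PSD rows).
    """
    fs = fragment.fs
    labels = fragment.channel_labels or [
        f"ch{i}" for i in range(fragment.epochs[0].shape[0])
    ]
    n_ch = len(labels)
    feat_acc: dict[str, list[np.ndarray]] = {f: [] for f in FEATURES}
    psd_acc: list[np.ndarray] = []

    for idx, epoch in enumerate(fragment.epochs):
        wb = bandpass(epoch, fs, params.wideband, mode=params.filter_mode)
        if not reject_artifacts(wb, params.artifact_threshold_uv):
            logger.info("extract_all: epoch %d of %r rejected (peak amplitude)",
                        idx, fragment.condition)
            continue
        fd_sig = bandpass(epoch, fs, params.fd_band, mode=params.filter_mode)
        al_sig = bandpass(epoch, fs, params.alpha_band, mode=params.filter_mode)

        vals = {f: np.empty(n_ch) for f in FEATURES}
        psd = np.empty((n_ch, len(PSD_BIN_NAMES)))
        for c in range(n_ch):
            vals["FD"][c] = higuchi_fd(fd_sig[c], k_max=params.k_max)
            vals["HjorthMobility"][c] = hjorth_mobility(wb[c])
            vals["HjorthComplexity"][c] = hjorth_complexity(wb[c])
            env_w = envelope(wb[c], fs, trim_s=params.trim_s)
            vals["EMF"][c] = envelope_mean_frequency(
                env_w, fs, f_cap_hz=params.emf_cap_hz, mode=params.emf_mode)
            vals["RAT"][c] = envelope_cv(env_w)
            env_a = envelope(al_sig[c], fs, trim_s=params.trim_s)
            vals["EMFA"][c] = envelope_mean_frequency(
                env_a, fs, f_cap_hz=params.emf_cap_hz, mode=params.emf_mode)
            psd[c] = psd_unit_bins(wb[c], fs, window_s=params.psd_window_s).power
        for f in FEATURES:
            feat_acc[f].append(vals[f])
        psd_acc.append(psd)

    if not psd_acc:
        warnings.warn(
            f"all epochs of condition {fragment.condition!r} rejected; "
            "returning empty tables")
        return (pd.DataFrame(columns=["subject", "group", "condition",
                                      "channel", "feature", "value"]),
                pd.DataFrame(columns=["subject", "group", "condition",
                                      "channel", *PSD_BIN_NAMES]))

    feat_rows = []
    for f in FEATURES:
        mean_vals = np.mean(feat_acc[f], axis=0)
        for c, lab in enumerate(labels):
            feat_rows.append({
                "subject": fragment.subject_id, "group": fragment.group,
                "condition": fragment.condition, "channel": lab,
                "feature": f, "value": mean_vals[c],
            })
    psd_mean = np.mean(psd_acc, axis=0)
    psd_rows = [
        {"subject": fragment.subject_id, "group": fragment.group,
         "condition": fragment.condition, "channel": lab,
         **dict(zip(PSD_BIN_NAMES, psd_mean[c]))}
        for c, lab in enumerate(labels)
    ]
    return pd.DataFrame(feat_rows), pd.DataFrame(psd_rows)
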