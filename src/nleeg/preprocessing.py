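"""Band-limited filtering and amplitude-threshold artifact rejection.

Three Butterworth bands are used throughout the pipeline:

* wideband 1.6-30 Hz (the acquisition band; Hjorth parameters, wideband
  envelope),
* 2-20 Hz (fractal-dimension band),
* alpha 8-13 Hz (alpha-band envelope).

The nominal order is 12 and filtering is zero-phase by default: a
forward-backward pass of an order-6 design, so the magnitude response has
the full order-12 roll-off while the phase response is identically zero.
Zero-phase filtering matters here because the downstream feature
estimators (fractal dimension, Hjorth derivatives) are sensitive to
waveform shape. A causal mode (single forward pass of the full-order
design) is available for comparison. Filters run as cascaded second-order
sections for numerical stability at high order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ParameterError

#: Default peak-amplitude rejection threshold, microvolts.
DEFAULT_ARTIFACT_THRESHOLD_UV = 100.0


@dataclass(frozen=True)
class BandSpec:
    """A band-pass specification: edges in Hz and nominal filter order."""

    low_hz: float
    high_hz: float
    order: int = 12
    purpose: str = "wideband"  # wideband | fd_band | alpha

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ParameterError(f"invalid band edges {self.low_hz}-{self.high_hz} Hz")
        if self.high_hz >= fs / 2:
            raise ParameterError(
                f"band edge {self.high_hz} Hz at or above Nyquist ({fs / 2} Hz)"
            )
        if self.order < 2:
            raise ParameterError("filter order must be >= 2")


WIDEBAND = BandSpec(1.6, 30.0, purpose="wideband")
FD_BAND = BandSpec(2.0, 20.0, purpose="fd_band")
ALPHA_BAND = BandSpec(8.0, 13.0, purpose="alpha")


def design_bandpass(band: BandSpec, fs: float, mode: str = "zero_phase") -> np.ndarray:
    """Second-order sections for a Butterworth band-pass.

    In zero-phase mode the design order is half the nominal order, because
    the forward-backward application squares the magnitude response.
    """
    band.validate(fs)
    if mode == "zero_phase":
        if band.order % 2:
            raise ParameterError("zero-phase mode requires an even nominal order")
        order = band.order // 2
    elif mode == "causal":
        order = band.order
    else:
        raise ParameterError(f"unknown filter mode {mode!r}")
    return sps.butter(order, [band.low_hz, band.high_hz], btype="bandpass",
                      fs=fs, output="sos")


def bandpass(x: np.ndarray, fs: float, band: BandSpec,
             mode: str = "zero_phase") -> np.ndarray:
    """Band-pass filter a single-channel series (same length out).

    Accepts a 1-D series or a channels x samples matrix (filtered along the
    last axis). Zero-phase by default; see module docstring.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 3 * band.order:
        raise ParameterError(
            f"series of {x.shape[-1]} samples too short for order-{band.order} filter"
        )
    sos = design_bandpass(band, fs, mode=mode)
    if mode == "zero_phase":
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def reject_artifacts(epoch: np.ndarray, threshold_uv: float = DEFAULT_ARTIFACT_THRESHOLD_UV) -> bool:
    """Decide whether an epoch survives peak-amplitude rejection.

    Returns True (kept) iff no channel's peak absolute amplitude exceeds
    ``threshold_uv``. A stand-in for manual artifact screening: simple,
    deterministic, and logged by the caller.
    """
    if not threshold_uv > 0:
        raise ParameterError("artifact threshold must be positive")
    return bool(np.abs(epoch).max() <= threshold_uv)
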