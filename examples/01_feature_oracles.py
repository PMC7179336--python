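"""Closed-form sanity checks for the five nonlinear features.

Builds analytic signals whose feature values are known exactly and prints
the estimate next to the theory. Run: python examples/01_feature_oracles.py
"""

import numpy as np

from nleeg import (
    envelope,
    envelope_cv,
    envelope_mean_frequency,
    gen_fbm,
    higuchi_fd,
    hjorth_complexity,
    hjorth_mobility,
    psd_unit_bins,
)

FS = 250.0
t = np.arange(int(20 * FS)) / FS

print("Higuchi fractal dimension")
print(f"  straight line      : {higuchi_fd(np.arange(1000.0), 8):.6f}  (theory 1.0)")
w = np.random.default_rng(0).standard_normal(10000)
print(f"  white noise        : {higuchi_fd(w, 8):.3f}  (theory ~2.0)")
fbm = gen_fbm(5000, 0.5, seed=1)
print(f"  fBm, Hurst 0.5     : {higuchi_fd(fbm, 8):.3f}  (theory 2 - H = 1.5)")

print("\nHjorth parameters")
x = np.sin(2 * np.pi * 10 * t)
print(f"  sine mobility      : {hjorth_mobility(x):.4f}  "
      f"(theory 2 sin(pi f/fs) = {2 * np.sin(np.pi * 10 / FS):.4f})")
print(f"  sine complexity    : {hjorth_complexity(x):.4f}  (theory 1.0)")
print(f"  white mobility     : {hjorth_mobility(w):.4f}  (theory sqrt(2) = 1.4142)")
print(f"  white complexity   : {hjorth_complexity(w):.4f}  (theory sqrt(1.5) = 1.2247)")

print("\nEnvelope metrics (AM signal, depth 0.5, 2 Hz modulator)")
am = (1 + 0.5 * np.cos(2 * np.pi * 2 * t)) * np.sin(2 * np.pi * 10 * t)
env = envelope(am, FS)            # |analytic signal|, 0.5 s edge trim
print(f"  envelope CV (RAT)  : {envelope_cv(env):.4f}  "
      f"(theory m/sqrt(2) = {0.5 / np.sqrt(2):.4f})")
print(f"  envelope mean freq : {envelope_mean_frequency(env, FS):.3f} Hz  (theory 2.0)")

print("\nUnit-bin PSD (unit 10.5 Hz sine, 60 s)")
bins = psd_unit_bins(np.sin(2 * np.pi * 10.5 * np.arange(int(60 * FS)) / FS), FS)
print(f"  total 2-20 Hz power: {bins.power.sum():.4f} uV^2  (theory A^2/2 = 0.5)")
print(f"  share in 10-11 bin : {100 * bins.power[8] / bins.power.sum():.1f} %")
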