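"""Synthetic EEG cohort generation.

The signal model is deliberately phenomenological: each channel is
1/f^exponent colored Gaussian noise, plus extra band-limited noise
realizing group-specific band-power elevations, plus a shared
amplitude-modulated alpha oscillation weighted toward posterior
electrodes. This reproduces the statistical structure the analysis
pipeline assumes -- group-specific resting spectra, stimulus-locked band
shifts, and subject-level latent traits that couple spectral composition
to subjective ratings -- without attempting biophysical realism.

Group resting profiles mirror the clinical contrasts the pipeline is
designed to detect: a "coma" profile with strongly elevated 2-7 Hz power
and almost no alpha, a "stroke" profile with elevated 5-9 Hz power and
weakened alpha, a "control" profile dominated by a posterior 10-13 Hz
rhythm, a "schizophrenia" profile with mildly elevated fast (15-19 Hz)
power and faster alpha amplitude modulation, and an "mTBI" profile
identical to control (no resting feature separates the two).

Every generator takes a mandatory seed; identical specs (including the
seed) produce byte-identical output. Per-subject and per-channel streams
are split off a single :class:`numpy.random.SeedSequence` so adding a
subject never perturbs another subject's data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import windows as sps_windows

from .exceptions import ParameterError, ValidationError
from .io import (
    PAPER_CHANNELS,
    REST_CONDITIONS,
    STIMULI,
    EventTable,
    Recording,
)
from .preprocessing import BandSpec, bandpass

#: Relative alpha-oscillation weight per electrode (posterior dominance).
ALPHA_TOPOGRAPHY = {
    "O1": 1.0, "O2": 1.0, "P3": 0.85, "Pz": 0.85, "P4": 0.85,
    "T5": 0.6, "T6": 0.6, "C3": 0.55, "Cz": 0.55, "C4": 0.55,
    "T3": 0.35, "T4": 0.35, "F3": 0.25, "Fz": 0.25, "F4": 0.25,
    "F7": 0.2, "F8": 0.2, "Fp1": 0.15, "Fp2": 0.15,
}

#: Std-dev (in log-gain units) of the per-subject latent traits that scale
#: slow (2-7 Hz) and fast (15-19 Hz) band power in every group. These
#: latents create the cross-subject spectral variability that drives the
#: PSD-feature and rating-feature correlations. The two latents are
#: negatively correlated (one "diffuse slowing" axis: slow power up goes
#: with fast power down), as in clinical EEG.
LATENT_SIGMA = 0.5
LATENT_RHO = -0.5


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ParameterError("a seed is mandatory; unseeded generation is not allowed")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------

def gen_colored_noise(n: int, fs: float, exponent: float, seed) -> np.ndarray:
    """Unit-variance Gaussian noise with power ~ 1/f^exponent above 1 Hz.

    Spectral shaping is done in the frequency domain on white Gaussian
    noise; below 1 Hz the spectrum is held flat to keep the variance
    finite.
    """
    if n < 256:
        raise ParameterError("need n >= 256 samples")
    rng = _rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.maximum(f, 1.0) ** (-exponent / 2.0)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n)
    return x / x.std()


def gen_fbm(n: int, hurst: float, seed) -> np.ndarray:
    """Fractional Brownian motion by exact circulant embedding.

    Generates fractional Gaussian noise with the exact covariance
    r(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2 via Davies-Harte circulant
    embedding (valid for all H in (0,1)), then cumulates. Serves as the
    ground truth for fractal-dimension estimators: FD(fBm) = 2 - H.
    """
    if not 0 < hurst < 1:
        raise ParameterError(f"Hurst exponent must be in (0,1), got {hurst}")
    if n < 2:
        raise ParameterError("need n >= 2")
    rng = _rng(seed)
    m = int(n)
    k = np.arange(m + 1, dtype=float)
    r = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
               + np.abs(k - 1) ** (2 * hurst))
    circ = np.concatenate([r, r[-2:0:-1]])          # length 2m
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-8 * lam.max():
        raise ParameterError("circulant embedding produced negative eigenvalues")
    lam = np.clip(lam, 0.0, None)

    v = rng.standard_normal(2)
    a = rng.standard_normal(m - 1)
    b = rng.standard_normal(m - 1)
    w = np.empty(2 * m, dtype=complex)
    w[0] = np.sqrt(lam[0]) * v[0]
    w[m] = np.sqrt(lam[m]) * v[1]
    w[1:m] = np.sqrt(lam[1:m] / 2.0) * (a + 1j * b)
    w[m + 1:] = np.conj(w[1:m][::-1])
    fgn = np.fft.fft(w).real[:m] / np.sqrt(2 * m)
    return np.cumsum(fgn)


def _band_noise(n: int, fs: float, low_hz: float, high_hz: float,
                rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise, unit variance."""
    x = bandpass(rng.standard_normal(n), fs, BandSpec(low_hz, high_hz, order=8))
    return x / x.std()


def _band_variance(x: np.ndarray, fs: float, low_hz: float, high_hz: float) -> float:
    return float(np.var(bandpass(x, fs, BandSpec(low_hz, high_hz, order=8))))


def _apply_band_gain(sig: np.ndarray, base: np.ndarray, fs: float,
                     low_hz: float, high_hz: float, gain: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Scale the power of ``base``'s in-band content within ``sig`` by ``gain``.

    Elevations (gain > 1) add independent band-limited noise scaled to
    (gain - 1) times the base's in-band variance; attenuations (gain < 1)
    subtract the appropriate fraction of the base's own band-filtered
    component.
    """
    if gain == 1.0:
        return sig
    if gain > 1.0:
        extra = _band_noise(len(base), fs, low_hz, high_hz, rng)
        extra *= np.sqrt((gain - 1.0) * _band_variance(base, fs, low_hz, high_hz))
        return sig + extra
    component = bandpass(base, fs, BandSpec(low_hz, high_hz, order=8))
    return sig - (1.0 - np.sqrt(gain)) * component


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralProfile:
    """Resting spectral signature of a group.

    ``band_boosts`` multiply the base noise power inside a band by
    ``gain`` (>= 1; elevations only -- contrasts in the opposite
    direction are realized by elevating the complementary band).
    ``alpha_amp`` is the alpha-oscillation amplitude in microvolts at a
    topography weight of 1 (occipital sites).
    """

    exponent: float = 1.0
    band_boosts: tuple[tuple[float, float, float], ...] = ()
    alpha_freq_hz: float = 10.5
    alpha_mod_freq_hz: float = 1.0
    alpha_depth: float = 0.5
    alpha_amp_uv: float = 12.0
    base_rms_uv: float = 10.0

    def validate(self) -> None:
        if self.exponent < 0:
            raise ValidationError("1/f exponent must be >= 0")
        for lo, hi, gain in self.band_boosts:
            if not 0 < lo < hi:
                raise ValidationError(f"bad boost band {lo}-{hi}")
            if gain < 1:
                raise ValidationError("band boost gains must be >= 1")
        if not 0 <= self.alpha_depth <= 1:
            raise ValidationError("alpha modulation depth must be in [0,1]")


#: Group resting profiles. Boost gains are relative to the subject's own
#: base-noise power inside the band, so the slow rhythms of the "coma" and
#: "stroke" profiles are strongly dominant: a steep 1/f tail plus a large
#: narrowband boost yields the nearly monomorphic slow activity of those
#: states (low Hjorth complexity/mobility, low envelope mean frequency,
#: Rayleigh-like envelope hence high envelope CV), while the control
#: profile is dominated by its amplitude-modulated posterior alpha rhythm.
GROUP_PROFILES: dict[str, SpectralProfile] = {
    "control": SpectralProfile(),
    "mTBI": SpectralProfile(),
    "schizophrenia": SpectralProfile(
        band_boosts=((15.0, 19.0, 2.5),),
        alpha_mod_freq_hz=2.0, alpha_depth=0.6, alpha_amp_uv=9.5),
    "stroke": SpectralProfile(
        exponent=1.5, band_boosts=((5.0, 9.5, 50.0),),
        alpha_freq_hz=9.4, alpha_mod_freq_hz=0.8, alpha_depth=0.4,
        alpha_amp_uv=5.0, base_rms_uv=6.0),
    "coma": SpectralProfile(
        exponent=2.5, band_boosts=((2.0, 5.0, 100.0),),
        alpha_mod_freq_hz=0.6, alpha_depth=0.3, alpha_amp_uv=1.0,
        base_rms_uv=2.5),
}


@dataclass(frozen=True)
class SubjectDesign:
    """Session layout: rest blocks plus randomized stimulus presentations.

    The default mirrors the study design: 2 min eyes-closed rest, each of
    the seven 30-s stimuli presented 8 times in random order with
    0.7-2.0 s gaps, and 2 min eyes-open rest at the end.
    """

    stimuli: tuple[str, ...] = tuple(STIMULI)
    n_epochs: int = 8
    epoch_s: float = 30.0
    rest_s: float = 120.0
    include_rest_open: bool = True
    gap_range_s: tuple[float, float] = (0.7, 2.0)
    fs: float = 250.0
    channels: tuple[str, ...] = tuple(PAPER_CHANNELS)


@dataclass(frozen=True)
class Effect:
    """A stimulus-locked band-power elevation for one group/condition."""

    group: str
    condition: str
    low_hz: float
    high_hz: float
    gain: float

    def validate(self) -> None:
        if self.gain < 1:
            raise ValidationError("effect gains must be >= 1")


#: Default stimulus-locked effects: a fast-band (15-19 Hz) elevation raises
#: FD and EMF; a slow-band (2-7 Hz) elevation lowers FD, EMF and the Hjorth
#: parameters and raises RAT.
DEFAULT_EFFECTS: tuple[Effect, ...] = (
    Effect("control", "crying", 15.0, 19.0, 3.0),        # FD up vs rest
    Effect("mTBI", "coughing", 2.0, 7.0, 2.5),           # FD/Hjorth down
    Effect("mTBI", "vomiting", 2.0, 7.0, 2.5),
    Effect("coma", "barking", 2.0, 7.0, 2.5),            # Hjorth down
    Effect("schizophrenia", "birdsong", 15.0, 19.0, 2.5),  # EMF up
)


@dataclass(frozen=True)
class RatingCoupling:
    """Linear coupling of a rating scale to a subject latent trait.

    ``latent`` is one of "slow", "fast", "slowing" (standardized
    z_slow - z_fast) or "fastness" (its negation); ``weight`` is the
    latent loading in [-1, 1] (the rest of the rating variance is
    subject + stimulus noise).
    """

    scale: str
    latent: str
    weight: float


#: Rating scales: (low, high, baseline mean).
RATING_SCALES = {
    "pleasantness": (-5.0, 5.0, 0.0),
    "arousal": (0.0, 10.0, 5.0),
    "fear": (0.0, 10.0, 3.0),
    "empathy": (0.0, 10.0, 4.0),
    "irritation": (0.0, 10.0, 4.0),
}

#: Per-stimulus pleasantness offsets (other scales share one baseline).
PLEASANTNESS_OFFSET = {
    "laughter": 3.0, "birdsong": 2.0, "barking": -1.0, "crying": -2.0,
    "coughing": -2.0, "vomiting": -3.0, "scratching": -3.0,
}

#: Default couplings: subjects with diffusely slowed EEG (low Hjorth
#: mobility/complexity) report more irritation; subjects with faster EEG
#: (high fractal dimension) report more empathy and arousal.
DEFAULT_COUPLINGS: tuple[RatingCoupling, ...] = (
    RatingCoupling("irritation", "slowing", 0.6),
    RatingCoupling("empathy", "fastness", 0.6),
    RatingCoupling("arousal", "fastness", 0.5),
)


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_subjects: int
    profile: SpectralProfile

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError(f"group {self.name!r} needs >= 2 subjects")
        self.profile.validate()


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort (seed mandatory)."""

    groups: tuple[GroupSpec, ...]
    seed: int
    design: SubjectDesign = SubjectDesign()
    effects: tuple[Effect, ...] = DEFAULT_EFFECTS
    couplings: tuple[RatingCoupling, ...] = DEFAULT_COUPLINGS
    latent_sigma: float = LATENT_SIGMA

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("CohortSpec.seed is mandatory")
        if not self.groups:
            raise ValidationError("cohort needs at least one group")
        for g in self.groups:
            g.validate()
        for e in self.effects:
            e.validate()


def default_cohort_spec(n_subjects: int = 15, seed: int = 0,
                        design: SubjectDesign | None = None,
                        groups: tuple[str, ...] | None = None) -> CohortSpec:
    """Convenience: one GroupSpec per named group with default profiles."""
    names = groups if groups is not None else tuple(GROUP_PROFILES)
    return CohortSpec(
        groups=tuple(GroupSpec(g, n_subjects, GROUP_PROFILES[g]) for g in names),
        seed=seed,
        design=design if design is not None else SubjectDesign(),
    )


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------

def _layout_events(design: SubjectDesign, rng: np.random.Generator) -> EventTable:
    rows = []
    t = 0.0
    gap = lambda: float(rng.uniform(*design.gap_range_s))  # noqa: E731
    if design.rest_s > 0:
        rows.append(("rest_closed", t, design.rest_s))
        t += design.rest_s + gap()
    order = np.repeat(np.arange(len(design.stimuli)), design.n_epochs)
    rng.shuffle(order)
    for idx in order:
        rows.append((design.stimuli[idx], t, design.epoch_s))
        t += design.epoch_s + gap()
    if design.include_rest_open and design.rest_s > 0:
        rows.append(("rest_open", t, design.rest_s))
        t += design.rest_s
    df = pd.DataFrame(
        [{"onset_s": on, "duration_s": dur, "label": lab} for lab, on, dur in rows]
    )
    vocab = list(design.stimuli) + REST_CONDITIONS
    return EventTable(df, vocabulary=vocab)


@dataclass
class SubjectLatents:
    """Per-subject latent traits recorded for coupling diagnostics."""

    z_slow: float
    z_fast: float

    @property
    def slowing(self) -> float:
        """Standardized diffuse-slowing score (slow power up, fast down)."""
        return (self.z_slow - self.z_fast) / np.sqrt(2.0 - 2.0 * LATENT_RHO)


def gen_subject(profile: SpectralProfile, design: SubjectDesign, seed,
                subject_id: str = "s01", group: str = "unknown",
                effects: tuple[Effect, ...] = (),
                latent_sigma: float = LATENT_SIGMA,
                ) -> tuple[Recording, EventTable, SubjectLatents]:
    """Generate one subject's recording and event table.

    Subject-level variability: the profile's exponent, boost gains, alpha
    amplitude/depth/frequency are jittered, and two latent traits z_slow /
    z_fast scale 2-7 Hz and 15-19 Hz power by exp(latent_sigma * z) in
    every subject regardless of group.
    """
    profile.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    seq = ss.spawn(3 + len(design.channels))
    rng_layout, rng_subject, rng_shared = (np.random.default_rng(s) for s in seq[:3])

    events = _layout_events(design, rng_layout)
    last = events.table.iloc[-1]
    fs = design.fs
    n = int(np.ceil((last.onset_s + last.duration_s + 1.0) * fs))
    t = np.arange(n) / fs

    # subject-level jitter and latent traits (one diffuse-slowing axis)
    z_slow, eps = rng_subject.standard_normal(2)
    z_fast = LATENT_RHO * z_slow + np.sqrt(1 - LATENT_RHO ** 2) * eps
    exponent = max(0.0, profile.exponent + 0.05 * rng_subject.standard_normal())
    alpha_amp = profile.alpha_amp_uv * float(
        np.exp(0.12 * rng_subject.standard_normal()))
    alpha_freq = profile.alpha_freq_hz + 0.3 * rng_subject.standard_normal()
    depth = float(np.clip(
        profile.alpha_depth + 0.08 * rng_subject.standard_normal(), 0.0, 1.0))
    boosts = [
        (lo, hi, 1.0 + (gain - 1.0) * float(np.exp(0.2 * rng_subject.standard_normal())))
        for lo, hi, gain in profile.band_boosts
    ]
    boosts.append((3.0, 8.0, float(np.exp(latent_sigma * z_slow))))
    boosts.append((15.0, 19.0, float(np.exp(latent_sigma * z_fast))))

    # shared alpha oscillation: AM carrier, modulator is narrowband noise
    mf = profile.alpha_mod_freq_hz
    mod = _band_noise(n, fs, max(0.3, 0.5 * mf), 1.6 * mf, rng_shared)
    mod = np.clip(mod / 2.5, -1.0, 1.0)
    phase = rng_shared.uniform(0, 2 * np.pi)
    alpha_wave = (1.0 + depth * mod) * np.sin(2 * np.pi * alpha_freq * t + phase)

    # per-event effect windows for this group
    active = [e for e in effects if e.group == group]
    win_rows = events.table

    data = np.empty((len(design.channels), n))
    for c, label in enumerate(design.channels):
        rng_ch = np.random.default_rng(seq[3 + c])
        base = gen_colored_noise(n, fs, exponent, rng_ch) * profile.base_rms_uv
        sig = base.copy()
        for lo, hi, gain in boosts:
            sig = _apply_band_gain(sig, base, fs, lo, hi, gain, rng_ch)
        sig += alpha_amp * ALPHA_TOPOGRAPHY.get(label, 0.3) * alpha_wave
        for eff in active:
            sel = win_rows[win_rows["label"] == eff.condition]
            for row in sel.itertuples(index=False):
                a = int(np.round(row.onset_s * fs))
                b = a + int(np.round(row.duration_s * fs))
                w = b - a
                extra = _band_noise(w, fs, eff.low_hz, eff.high_hz, rng_ch)
                extra *= np.sqrt(
                    (eff.gain - 1.0)
                    * _band_variance(base[a:b], fs, eff.low_hz, eff.high_hz))
                sig[a:b] += extra * sps_windows.tukey(w, alpha=min(0.2, 2 * fs / w))
        data[c] = sig

    rec = Recording(data=data, fs=fs, channel_labels=list(design.channels),
                    subject_id=subject_id, group=group)
    return rec, events, SubjectLatents(z_slow=float(z_slow), z_fast=float(z_fast))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    recording: Recording
    events: EventTable
    latents: SubjectLatents


@dataclass
class Cohort:
    subjects: list[SubjectData]
    ratings: pd.DataFrame          # subject, group, stimulus, scale, value
    latents: pd.DataFrame          # subject, group, z_slow, z_fast


def _gen_ratings(subjects: list[SubjectData], stimuli: tuple[str, ...],
                 couplings: tuple[RatingCoupling, ...],
                 rng: np.random.Generator) -> pd.DataFrame:
    """Ratings as truncated Gaussians coupled to subject latents.

    Comatose subjects give no ratings. Subject-level rating tendency is
    weight * z_latent + sqrt(1 - weight^2) * eta (unit variance), scaled
    by 2 rating points; per-stimulus noise has sd 0.5.
    """
    rows = []
    for sd in subjects:
        if sd.recording.group == "coma":
            continue
        latent = {"slow": sd.latents.z_slow, "fast": sd.latents.z_fast,
                  "slowing": sd.latents.slowing,
                  "fastness": -sd.latents.slowing}
        coupling = {c.scale: c for c in couplings}
        for scale, (lo, hi, base) in RATING_SCALES.items():
            c = coupling.get(scale)
            if c is None:
                tendency = rng.standard_normal()
            else:
                tendency = (c.weight * latent[c.latent]
                            + np.sqrt(1 - c.weight ** 2) * rng.standard_normal())
            for stim in stimuli:
                mu = base + (PLEASANTNESS_OFFSET.get(stim, 0.0)
                             if scale == "pleasantness" else 0.0)
                val = mu + 2.0 * tendency + 0.5 * rng.standard_normal()
                rows.append({
                    "subject": sd.recording.subject_id,
                    "group": sd.recording.group,
                    "stimulus": stim, "scale": scale,
                    "value": float(np.clip(val, lo, hi)),
                })
    return pd.DataFrame(rows, columns=["subject", "group", "stimulus",
                                       "scale", "value"])


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate all subjects of a cohort plus the ratings table."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    n_total = sum(g.n_subjects for g in spec.groups)
    seqs = root.spawn(n_total + 1)
    ratings_rng = np.random.default_rng(seqs[-1])

    subjects: list[SubjectData] = []
    i = 0
    for g in spec.groups:
        for j in range(g.n_subjects):
            sid = f"{g.name}_{j + 1:02d}"
            rec, ev, lat = gen_subject(
                g.profile, spec.design, seqs[i], subject_id=sid, group=g.name,
                effects=spec.effects, latent_sigma=spec.latent_sigma)
            subjects.append(SubjectData(rec, ev, lat))
            i += 1

    ratings = _gen_ratings(subjects, spec.design.stimuli, spec.couplings,
                           ratings_rng)
    latents = pd.DataFrame([
        {"subject": s.recording.subject_id, "group": s.recording.group,
         "z_slow": s.latents.z_slow, "z_fast": s.latents.z_fast}
        for s in subjects
    ])
    return Cohort(subjects=subjects, ratings=ratings, latents=latents)
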