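"""Run configuration: YAML loading, validation, and hashing.

A :class:`RunConfig` collects every tunable of the pipeline (band edges,
filter order, Higuchi k_max, envelope-frequency cap and mode, edge trim,
artifact threshold, statistics parameters, seed). Output directories
always receive a manifest carrying the config hash so runs are
reproducible and comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml

from .exceptions import ValidationError
from .features import FeatureParams
from .preprocessing import BandSpec
from .simulate import (
    DEFAULT_COUPLINGS,
    DEFAULT_EFFECTS,
    GROUP_PROFILES,
    LATENT_SIGMA,
    CohortSpec,
    Effect,
    GroupSpec,
    RatingCoupling,
    SpectralProfile,
    SubjectDesign,
)


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    r_display: float = 0.35
    pooling: str = "channel_mean"
    rest_condition: str = "rest_closed"

    def validate(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValidationError(f"stats.alpha must be in (0,1], got {self.alpha}")
        if self.r_display < 0:
            raise ValidationError("stats.r_display must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    features: FeatureParams = FeatureParams()
    stats: StatsParams = StatsParams()
    seed: int = 0

    def validate(self) -> None:
        self.stats.validate()
        for band in (self.features.wideband, self.features.fd_band,
                     self.features.alpha_band):
            if not 0 < band.low_hz < band.high_hz:
                raise ValidationError(f"invalid band {band}")
        if self.features.k_max < 2:
            raise ValidationError("features.k_max must be >= 2")
        if self.features.trim_s < 0:
            raise ValidationError("features.trim_s must be >= 0")
        if not self.features.artifact_threshold_uv > 0:
            raise ValidationError("features.artifact_threshold_uv must be > 0")

    def to_dict(self) -> dict:
        """Serialize in the same schema the YAML loader accepts."""
        f = self.features
        return {
            "features": {
                "k_max": f.k_max, "emf_cap_hz": f.emf_cap_hz,
                "emf_mode": f.emf_mode, "trim_s": f.trim_s,
                "artifact_threshold_uv": f.artifact_threshold_uv,
                "filter_mode": f.filter_mode, "psd_window_s": f.psd_window_s,
            },
            "bands": {
                "wideband": [f.wideband.low_hz, f.wideband.high_hz],
                "fd": [f.fd_band.low_hz, f.fd_band.high_hz],
                "alpha": [f.alpha_band.low_hz, f.alpha_band.high_hz],
            },
            "stats": asdict(self.stats),
            "seed": self.seed,
        }

    def hash(self) -> str:
        """Stable hash of the full parameter set."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _band_from(obj, default: BandSpec) -> BandSpec:
    if obj is None:
        return default
    if isinstance(obj, (list, tuple)):
        return BandSpec(float(obj[0]), float(obj[1]), order=default.order,
                        purpose=default.purpose)
    return BandSpec(float(obj["low_hz"]), float(obj["high_hz"]),
                    order=int(obj.get("order", default.order)),
                    purpose=default.purpose)


def run_config_from_yaml(path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys raise with their path."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    defaults = RunConfig()
    known = {"features", "stats", "seed", "bands"}
    extra = set(doc) - known
    if extra:
        raise ValidationError(f"unknown config keys: {sorted(extra)}")
    fdoc = dict(doc.get("features") or {})
    bands = dict(doc.get("bands") or {})
    fp = FeatureParams(
        k_max=int(fdoc.pop("k_max", defaults.features.k_max)),
        emf_cap_hz=float(fdoc.pop("emf_cap_hz", defaults.features.emf_cap_hz)),
        emf_mode=str(fdoc.pop("emf_mode", defaults.features.emf_mode)),
        trim_s=float(fdoc.pop("trim_s", defaults.features.trim_s)),
        artifact_threshold_uv=float(
            fdoc.pop("artifact_threshold_uv",
                     defaults.features.artifact_threshold_uv)),
        filter_mode=str(fdoc.pop("filter_mode", defaults.features.filter_mode)),
        psd_window_s=float(fdoc.pop("psd_window_s", defaults.features.psd_window_s)),
        wideband=_band_from(bands.get("wideband"), defaults.features.wideband),
        fd_band=_band_from(bands.get("fd"), defaults.features.fd_band),
        alpha_band=_band_from(bands.get("alpha"), defaults.features.alpha_band),
    )
    if fdoc:
        raise ValidationError(f"unknown keys under features: {sorted(fdoc)}")
    sdoc = dict(doc.get("stats") or {})
    sp = StatsParams(
        alpha=float(sdoc.pop("alpha", defaults.stats.alpha)),
        r_display=float(sdoc.pop("r_display", defaults.stats.r_display)),
        pooling=str(sdoc.pop("pooling", defaults.stats.pooling)),
        rest_condition=str(sdoc.pop("rest_condition",
                                    defaults.stats.rest_condition)),
    )
    if sdoc:
        raise ValidationError(f"unknown keys under stats: {sorted(sdoc)}")
    cfg = RunConfig(features=fp, stats=sp, seed=int(doc.get("seed", 0)))
    cfg.validate()
    return cfg


def run_config_to_yaml(path, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Cohort spec YAML
# ---------------------------------------------------------------------------

def _profile_from(doc: dict) -> SpectralProfile:
    base = GROUP_PROFILES.get(doc.get("like", ""), SpectralProfile())
    kwargs = {}
    for key in ("exponent", "alpha_freq_hz", "alpha_mod_freq_hz",
                "alpha_depth", "alpha_amp_uv", "base_rms_uv"):
        kwargs[key] = float(doc.get(key, getattr(base, key)))
    boosts = doc.get("band_boosts")
    kwargs["band_boosts"] = (tuple(tuple(map(float, b)) for b in boosts)
                             if boosts is not None else base.band_boosts)
    return SpectralProfile(**kwargs)


def cohort_spec_from_yaml(path) -> CohortSpec:
    """Load a CohortSpec from YAML.

    Minimal form::

        seed: 7
        groups:
          - {name: control, n_subjects: 15}
          - {name: coma, n_subjects: 15, profile: {like: coma, exponent: 1.4}}
        design: {n_epochs: 2, epoch_s: 10, rest_s: 40}
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if "seed" not in doc:
        raise ValidationError("cohort spec: 'seed' is mandatory")
    if not doc.get("groups"):
        raise ValidationError("cohort spec: 'groups' must list at least one group")
    groups = []
    for i, g in enumerate(doc["groups"]):
        if "name" not in g or "n_subjects" not in g:
            raise ValidationError(f"cohort spec: groups[{i}] needs name and n_subjects")
        prof_doc = g.get("profile")
        if prof_doc is None:
            if g["name"] not in GROUP_PROFILES:
                raise ValidationError(
                    f"cohort spec: groups[{i}].name {g['name']!r} has no default "
                    "profile; supply one")
            profile = GROUP_PROFILES[g["name"]]
        else:
            profile = _profile_from(prof_doc)
        groups.append(GroupSpec(g["name"], int(g["n_subjects"]), profile))
    ddoc = dict(doc.get("design") or {})
    defaults = SubjectDesign()
    design = SubjectDesign(
        stimuli=tuple(ddoc.get("stimuli", defaults.stimuli)),
        n_epochs=int(ddoc.get("n_epochs", defaults.n_epochs)),
        epoch_s=float(ddoc.get("epoch_s", defaults.epoch_s)),
        rest_s=float(ddoc.get("rest_s", defaults.rest_s)),
        include_rest_open=bool(ddoc.get("include_rest_open",
                                        defaults.include_rest_open)),
        gap_range_s=tuple(ddoc.get("gap_range_s", defaults.gap_range_s)),
        fs=float(ddoc.get("fs", defaults.fs)),
        channels=tuple(ddoc.get("channels", defaults.channels)),
    )
    effects = tuple(
        Effect(e["group"], e["condition"], float(e["low_hz"]),
               float(e["high_hz"]), float(e["gain"]))
        for e in doc.get("effects", [])
    ) if "effects" in doc else DEFAULT_EFFECTS
    couplings = tuple(
        RatingCoupling(c["scale"], c["latent"], float(c["weight"]))
        for c in doc.get("couplings", [])
    ) if "couplings" in doc else DEFAULT_COUPLINGS
    spec = CohortSpec(groups=tuple(groups), seed=int(doc["seed"]), design=design,
                      effects=effects, couplings=couplings,
                      latent_sigma=float(doc.get("latent_sigma", LATENT_SIGMA)))
    spec.validate()
    return spec
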