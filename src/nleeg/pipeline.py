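"""End-to-end orchestration: simulate -> extract -> stats.

Library-level entry points used by the CLI, the examples and the tests.
Each on-disk stage writes a ``manifest.json`` with the package version,
the config hash and SHA-256 checksums of its outputs, so identical
seeds/configs are verifiably byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .features import PSD_BIN_NAMES, extract_all
from .io import (
    EventTable,
    Recording,
    read_edf,
    read_events,
    segment,
    write_edf,
    write_events,
    write_feature_table,
    write_ratings_table,
)
from .simulate import Cohort, CohortSpec, gen_cohort
from .stats import (
    group_anova_rest,
    psd_feature_correlations,
    rating_feature_correlations,
)

PSD_COLUMNS = ["subject", "group", "condition", "channel", *PSD_BIN_NAMES]


def extract_recording(recording: Recording, events: EventTable,
                      config: RunConfig = RunConfig()
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment one recording and extract features + PSD for every condition."""
    feats, psds = [], []
    for frag in segment(recording, events):
        f, p = extract_all(frag, config.features)
        if len(f):
            feats.append(f)
            psds.append(p)
    return (pd.concat(feats, ignore_index=True) if feats else pd.DataFrame(),
            pd.concat(psds, ignore_index=True) if psds else pd.DataFrame())


def extract_cohort(cohort: Cohort, config: RunConfig = RunConfig()
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature and PSD tables for a whole in-memory cohort."""
    feats, psds = [], []
    for sd in cohort.subjects:
        f, p = extract_recording(sd.recording, sd.events, config)
        if len(f):
            feats.append(f)
            psds.append(p)
    return (pd.concat(feats, ignore_index=True),
            pd.concat(psds, ignore_index=True))


# ---------------------------------------------------------------------------
# Disk-based stages (used by the CLI)
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, config_hash: str, files: list[Path]) -> Path:
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash,
        "checksums": {f.name: _sha256(f) for f in sorted(files)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def simulate_to_dir(spec: CohortSpec, out_dir) -> Path:
    """Generate a cohort and write EDF recordings, events, and ratings."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = gen_cohort(spec)
    files = []
    for sd in cohort.subjects:
        sid = sd.recording.subject_id
        edf = out / f"{sid}.edf"
        ev = out / f"{sid}_events.tsv"
        write_edf(edf, sd.recording)
        write_events(ev, sd.events)
        files += [edf, ev]
    ratings_path = out / "ratings.tsv"
    write_ratings_table(ratings_path, cohort.ratings)
    files.append(ratings_path)
    groups_path = out / "subjects.tsv"
    cohort.latents[["subject", "group"]].to_csv(groups_path, sep="\t", index=False)
    files.append(groups_path)
    spec_hash = hashlib.sha256(repr(spec).encode()).hexdigest()[:16]
    return _write_manifest(out, spec_hash, files)


def extract_from_dir(in_dir, out_dir, config: RunConfig = RunConfig()) -> Path:
    """Read every EDF + events pair in a directory and write feature tables."""
    src = Path(in_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = {}
    subjects_tsv = src / "subjects.tsv"
    if subjects_tsv.exists():
        gdf = pd.read_csv(subjects_tsv, sep="\t")
        groups = dict(zip(gdf["subject"], gdf["group"]))
    feats, psds = [], []
    edfs = sorted(src.glob("*.edf"))
    if not edfs:
        raise FileNotFoundError(f"no EDF recordings under {src}")
    for edf in edfs:
        rec = read_edf(edf)
        rec.subject_id = edf.stem
        rec.group = groups.get(edf.stem, "unknown")
        events = read_events(edf.with_name(f"{edf.stem}_events.tsv"))
        f, p = extract_recording(rec, events, config)
        feats.append(f)
        psds.append(p)
    features = pd.concat(feats, ignore_index=True)
    psd = pd.concat(psds, ignore_index=True)
    fpath, ppath = out / "features.tsv", out / "psd.tsv"
    write_feature_table(fpath, features)
    psd[PSD_COLUMNS].to_csv(ppath, sep="\t", index=False)
    return _write_manifest(out, config.hash(), [fpath, ppath])


def stats_from_tables(features: pd.DataFrame, psd: pd.DataFrame,
                      ratings: pd.DataFrame | None, out_dir,
                      config: RunConfig = RunConfig()) -> Path:
    """Run the statistical stage and write TSV + JSON reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    report = group_anova_rest(features, alpha=config.stats.alpha,
                              condition=config.stats.rest_condition)
    anova_path = out / "anova_rest.tsv"
    flat = report.drop(columns=["group_means", "tukey"])
    flat.to_csv(anova_path, sep="\t", index=False)
    (out / "anova_rest.json").write_text(report.to_json(orient="records"))
    files += [anova_path, out / "anova_rest.json"]

    cmap = psd_feature_correlations(features, psd,
                                    r_display=config.stats.r_display,
                                    alpha=config.stats.alpha,
                                    pooling=config.stats.pooling)
    for name, df in (("psd_feature_r", cmap.r), ("psd_feature_p", cmap.p),
                     ("psd_feature_mask", cmap.mask)):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t")
        files.append(path)

    if ratings is not None and len(ratings):
        rf = rating_feature_correlations(ratings, features,
                                         alpha=config.stats.alpha,
                                         r_display=config.stats.r_display)
        path = out / "rating_feature_r.tsv"
        rf.to_csv(path, sep="\t", index=False)
        files.append(path)

    return _write_manifest(out, config.hash(), files)
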