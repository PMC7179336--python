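"""Group contrasts, stimulation-vs-rest contrasts, and correlation maps.

The statistical stage mirrors a classic clinical-EEG analysis:

* between-group contrasts of resting-state features: one-way ANOVA per
  (feature, channel) with Bonferroni correction across the 19-channel
  family within each feature, Tukey HSD post-hoc on significant omnibus
  tests;
* within-group stimulation-vs-rest contrasts: paired t-test per channel
  (Wilcoxon signed-rank fallback for n < 8), with the sign convention
  "+" = higher in rest, "-" = lower in rest;
* Pearson correlation maps between unit-bin PSD and the nonlinear
  features, masked at p < 0.05 and |r| > 0.35 (display threshold);
* Pearson correlations between subjective ratings and features within
  group/condition strata (groups without ratings are skipped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .exceptions import PairingError, ValidationError
from .features import FEATURES, PSD_BIN_NAMES
from .io import PAPER_CHANNELS

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_R_DISPLAY = 0.35


def bonferroni(p_raw: float, m: int) -> float:
    """min(1, m * p): family-wise adjustment for m tests."""
    return float(min(1.0, m * p_raw))


def channel_list_string(significant: list[str],
                        all_channels: list[str] = PAPER_CHANNELS) -> str:
    """Render a channel set the way clinical reports do ("all except ...")."""
    sig = [c for c in all_channels if c in significant]
    if len(sig) == len(all_channels):
        return "all"
    if len(sig) > len(all_channels) / 2:
        missing = [c for c in all_channels if c not in sig]
        return "all except " + ", ".join(missing)
    return ", ".join(sig) if sig else "none"


# ---------------------------------------------------------------------------
# Between-group resting contrasts
# ---------------------------------------------------------------------------

def group_anova_rest(features: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                     condition: str = "rest_closed") -> pd.DataFrame:
    """One-way between-group ANOVA per (feature, channel) at rest.

    ``features`` is the long-format table (subject, group, condition,
    channel, feature, value) with one value per subject per cell. The
    Bonferroni family is the set of channels tested within each feature.
    Rows carry F, degrees of freedom, raw and adjusted p, the per-group
    means, and Tukey HSD pairwise p-values when the omnibus test survives
    adjustment.
    """
    sub = features[features["condition"] == condition]
    if sub.empty:
        raise ValidationError(f"no rows for condition {condition!r}")
    rows = []
    for feat, feat_df in sub.groupby("feature", sort=False):
        channels = list(dict.fromkeys(feat_df["channel"]))
        m = len(channels)
        for chan in channels:
            cell = feat_df[feat_df["channel"] == chan]
            groups = {g: d["value"].to_numpy() for g, d in cell.groupby("group")}
            names = sorted(groups)
            samples = [groups[g] for g in names]
            if len(samples) < 2 or any(len(s) < 2 for s in samples):
                logger.info("group_anova_rest: skipping %s/%s (empty/small cell)",
                            feat, chan)
                continue
            n_total = sum(len(s) for s in samples)
            fstat, p_raw = sst.f_oneway(*samples)
            if not np.isfinite(fstat):      # identical groups: zero between-SS
                fstat, p_raw = 0.0, 1.0
            p_adj = bonferroni(p_raw, m)
            significant = p_adj <= alpha
            posthoc = []
            if significant:
                res = sst.tukey_hsd(*samples)
                for i in range(len(names)):
                    for j in range(i + 1, len(names)):
                        posthoc.append({
                            "pair": (names[i], names[j]),
                            "p": float(res.pvalue[i, j]),
                        })
            rows.append({
                "feature": feat, "channel": chan,
                "F": float(fstat),
                "df_between": len(samples) - 1,
                "df_within": n_total - len(samples),
                "p_raw": float(p_raw), "p_adjusted": p_adj,
                "significant": bool(significant),
                "group_means": {g: float(groups[g].mean()) for g in names},
                "tukey": posthoc,
            })
    return pd.DataFrame(rows)


def significant_channels(report: pd.DataFrame, feature: str) -> list[str]:
    sel = report[(report["feature"] == feature) & report["significant"]]
    return list(sel["channel"])


# ---------------------------------------------------------------------------
# Stimulation vs rest
# ---------------------------------------------------------------------------

def stim_vs_rest(features: pd.DataFrame, group: str, condition: str,
                 rest_condition: str = "rest_closed",
                 alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Paired within-group contrast of a stimulus condition against rest.

    Values must be paired by subject. Uses a paired t-test (Wilcoxon
    signed-rank for n < 8). Signs follow the reporting convention:
    "+" when the feature is higher in rest, "-" when lower in rest.
    """
    sub = features[features["group"] == group]
    rows = []
    for feat, feat_df in sub.groupby("feature", sort=False):
        channels = list(dict.fromkeys(feat_df["channel"]))
        m = len(channels)
        for chan in channels:
            cell = feat_df[feat_df["channel"] == chan]
            rest = cell[cell["condition"] == rest_condition].set_index("subject")["value"]
            stim = cell[cell["condition"] == condition].set_index("subject")["value"]
            if set(rest.index) != set(stim.index) or rest.empty:
                raise PairingError(
                    f"unpaired subject sets for {feat}/{chan} "
                    f"({condition} vs {rest_condition})")
            stim = stim.reindex(rest.index)
            diff = (rest - stim).to_numpy()
            n = diff.size
            if np.allclose(diff, 0):
                stat, p_raw, test = 0.0, 1.0, "t"
            elif n < 8:
                stat, p_raw = sst.wilcoxon(diff)
                test = "wilcoxon"
            else:
                stat, p_raw = sst.ttest_rel(rest.to_numpy(), stim.to_numpy())
                test = "t"
            p_adj = bonferroni(float(p_raw), m)
            rows.append({
                "feature": feat, "channel": chan, "n": n, "test": test,
                "statistic": float(stat), "p_raw": float(p_raw),
                "p_adjusted": p_adj, "significant": bool(p_adj <= alpha),
                "sign": "+" if diff.mean() > 0 else "-",
                "mean_rest": float(rest.mean()), "mean_stim": float(stim.mean()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation maps
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMap:
    """Pearson r grid with a significance/display mask.

    ``r`` and ``p`` are (row variable x column variable) DataFrames;
    ``mask`` is True where p < alpha AND |r| > r_display. Entries whose r
    is undefined (constant column) are NaN with mask False.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    r_display: float = DEFAULT_R_DISPLAY

    def to_long(self) -> pd.DataFrame:
        out = (self.r.stack().rename("r").to_frame()
               .join(self.p.stack().rename("p"))
               .join(self.mask.stack().rename("significant")))
        out.index.names = ["row", "column"]
        return out.reset_index()


def _pearson_grid(x: pd.DataFrame, y: pd.DataFrame, alpha: float,
                  r_display: float) -> CorrelationMap:
    r = pd.DataFrame(index=x.columns, columns=y.columns, dtype=float)
    p = r.copy()
    for xc in x.columns:
        for yc in y.columns:
            xv, yv = x[xc].to_numpy(), y[yc].to_numpy()
            if np.std(xv) == 0 or np.std(yv) == 0 or len(xv) < 3:
                r.loc[xc, yc] = np.nan
                p.loc[xc, yc] = np.nan
                continue
            res = sst.pearsonr(xv, yv)
            r.loc[xc, yc] = res.statistic
            p.loc[xc, yc] = res.pvalue
    mask = (p < alpha) & (r.abs() > r_display)
    mask = mask.fillna(False).astype(bool)
    return CorrelationMap(r=r, p=p, mask=mask, alpha=alpha, r_display=r_display)


def psd_feature_correlations(features: pd.DataFrame, psd: pd.DataFrame,
                             r_display: float = DEFAULT_R_DISPLAY,
                             alpha: float = DEFAULT_ALPHA,
                             pooling: str = "channel_mean") -> CorrelationMap:
    """Pearson correlations between unit-bin PSD and features.

    Observation unit: a (subject, condition) cell with values averaged
    over channels (``pooling="channel_mean"``, the default) or every
    (subject, condition, channel) triple (``pooling="per_channel"``).
    Returns a CorrelationMap with PSD bins as rows and features as
    columns.
    """
    if pooling == "channel_mean":
        keys = ["subject", "condition"]
    elif pooling == "per_channel":
        keys = ["subject", "condition", "channel"]
    else:
        raise ValidationError(f"unknown pooling {pooling!r}")
    feat_wide = (features.pivot_table(index=keys, columns="feature",
                                      values="value", aggfunc="mean")
                 .reindex(columns=[f for f in FEATURES
                                   if f in set(features["feature"])]))
    psd_wide = psd.groupby(keys)[[c for c in PSD_BIN_NAMES if c in psd.columns]].mean()
    joined = feat_wide.join(psd_wide, how="inner").dropna()
    if len(joined) < 3:
        raise ValidationError("need >= 3 matched observations for correlations")
    return _pearson_grid(joined[psd_wide.columns], joined[feat_wide.columns],
                         alpha, r_display)


def rating_feature_correlations(ratings: pd.DataFrame, features: pd.DataFrame,
                                alpha: float = DEFAULT_ALPHA,
                                r_display: float = DEFAULT_R_DISPLAY,
                                ) -> pd.DataFrame:
    """Pearson r between rating scales and features, per group x stimulus.

    Observations are subjects; feature values are channel-averaged within
    the stimulus condition. Groups present in the features but absent from
    the ratings (comatose patients give no ratings) are skipped with a log
    entry. Returns a long DataFrame (group, condition, scale, feature, n,
    r, p, significant).
    """
    rows = []
    rated_groups = set(ratings["group"]) if len(ratings) else set()
    for grp in dict.fromkeys(features["group"]):
        if grp not in rated_groups:
            logger.info("rating_feature_correlations: group %r has no ratings; "
                        "skipped", grp)
            continue
        f_grp = features[features["group"] == grp]
        r_grp = ratings[ratings["group"] == grp]
        for stim in dict.fromkeys(r_grp["stimulus"]):
            f_cell = f_grp[f_grp["condition"] == stim]
            if f_cell.empty:
                continue
            feat_by_subj = f_cell.pivot_table(index="subject", columns="feature",
                                              values="value", aggfunc="mean")
            r_cell = r_grp[r_grp["stimulus"] == stim].pivot_table(
                index="subject", columns="scale", values="value")
            joined = feat_by_subj.join(r_cell, how="inner").dropna()
            if len(joined) < 3:
                continue
            for scale in r_cell.columns:
                for feat in feat_by_subj.columns:
                    xv = joined[scale].to_numpy()
                    yv = joined[feat].to_numpy()
                    if np.std(xv) == 0 or np.std(yv) == 0:
                        continue
                    res = sst.pearsonr(xv, yv)
                    rows.append({
                        "group": grp, "condition": stim, "scale": scale,
                        "feature": feat, "n": len(joined),
                        "r": float(res.statistic), "p": float(res.pvalue),
                        "significant": bool(res.pvalue < alpha
                                            and abs(res.statistic) > r_display),
                    })
    return pd.DataFrame(rows, columns=["group", "condition", "scale", "feature",
                                       "n", "r", "p", "significant"])


# ---------------------------------------------------------------------------
# Calibration utilities
# ---------------------------------------------------------------------------

def null_anova_fwer(n_reps: int = 1000, n_groups: int = 5, n_subjects: int = 8,
                    n_channels: int = 19, alpha: float = DEFAULT_ALPHA,
                    seed: int = 0) -> float:
    """Family-wise type-I error of the Bonferroni-corrected channel family.

    Simulates ``n_reps`` null cohorts (i.i.d. standard-normal feature
    values, no group differences), runs the per-channel one-way ANOVA
    family through :func:`group_anova_rest`, and reports the fraction of
    repetitions with at least one adjusted rejection. Should not exceed
    alpha (plus Monte-Carlo error).
    """
    rng = np.random.default_rng(seed)
    channels = PAPER_CHANNELS[:n_channels]
    hits = 0
    base = pd.DataFrame({
        "subject": np.repeat([f"g{g}s{s}" for g in range(n_groups)
                              for s in range(n_subjects)], n_channels),
        "group": np.repeat([f"g{g}" for g in range(n_groups)],
                           n_subjects * n_channels),
        "condition": "rest_closed",
        "channel": np.tile(channels, n_groups * n_subjects),
        "feature": "F0",
    })
    for _ in range(n_reps):
        base["value"] = rng.standard_normal(len(base))
        report = group_anova_rest(base, alpha=alpha)
        hits += bool(report["significant"].any())
    return hits / n_reps
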