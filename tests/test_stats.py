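"""Statistical stage: ANOVA oracle, contrasts, correlation maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nleeg.exceptions import PairingError, ValidationError
from nleeg.stats import (
    bonferroni,
    channel_list_string,
    group_anova_rest,
    psd_feature_correlations,
    rating_feature_correlations,
    significant_channels,
    stim_vs_rest,
)
from nleeg.features import PSD_BIN_NAMES
from nleeg.io import PAPER_CHANNELS


def brute_force_f(groups):
    """One-way ANOVA F from explicit sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def feature_table(groups: dict[str, np.ndarray], channel="Cz",
                  feature="FD", condition="rest_closed") -> pd.DataFrame:
    rows = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append({"subject": f"{g}{i}", "group": g,
                         "condition": condition, "channel": channel,
                         "feature": feature, "value": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Between-group ANOVA
# ---------------------------------------------------------------------------

def test_anova_matches_brute_force_sums_of_squares():
    """F statistic equals the explicit sums-of-squares computation to 1e-9
    relative on random small instances."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        k = rng.integers(2, 6)
        groups = {f"g{j}": rng.standard_normal(rng.integers(3, 11)) + 0.3 * j
                  for j in range(k)}
        report = group_anova_rest(feature_table(groups))
        expect = brute_force_f([np.asarray(v) for v in groups.values()])
        assert report["F"].iloc[0] == pytest.approx(expect, rel=1e-9)


def test_anova_identical_groups_null():
    vals = np.random.default_rng(1).standard_normal(10)
    report = group_anova_rest(feature_table({"a": vals, "b": vals}))
    assert report["F"].iloc[0] == pytest.approx(0.0, abs=1e-20)
    assert report["p_raw"].iloc[0] == pytest.approx(1.0)


def test_anova_degrees_of_freedom_and_posthoc():
    rng = np.random.default_rng(2)
    groups = {g: rng.standard_normal(8) + mu
              for g, mu in [("a", 0.0), ("b", 2.0), ("c", 4.0)]}
    report = group_anova_rest(feature_table(groups))
    row = report.iloc[0]
    assert (row["df_between"], row["df_within"]) == (2, 21)
    assert row["significant"]
    pairs = {frozenset(p["pair"]) for p in row["tukey"]}
    assert pairs == {frozenset({"a", "b"}), frozenset({"a", "c"}),
                     frozenset({"b", "c"})}


def test_anova_bonferroni_family_is_channels():
    """With 2 channels, adjusted p doubles (per-feature channel family)."""
    rng = np.random.default_rng(3)
    rows = []
    for chan in ("Cz", "Pz"):
        rows.append(feature_table(
            {"a": rng.standard_normal(6), "b": rng.standard_normal(6)},
            channel=chan))
    report = group_anova_rest(pd.concat(rows, ignore_index=True))
    for _, r in report.iterrows():
        assert r["p_adjusted"] == pytest.approx(min(1.0, 2 * r["p_raw"]))


def test_anova_missing_condition():
    with pytest.raises(ValidationError):
        group_anova_rest(feature_table({"a": np.arange(4.0)},
                                       condition="laughter"))


@given(p=st.floats(0, 1), m=st.integers(1, 100))
def test_bonferroni_monotone_and_capped(p, m):
    assert bonferroni(p, m) == min(1.0, m * p)
    assert bonferroni(p, m + 1) >= bonferroni(p, m)


def test_channel_list_string_reporting():
    assert channel_list_string(list(PAPER_CHANNELS)) == "all"
    most = [c for c in PAPER_CHANNELS if c not in ("F7", "C3")]
    assert channel_list_string(most) == "all except F7, C3"
    assert channel_list_string([]) == "none"
    assert channel_list_string(["Cz", "Pz"]) == "Cz, Pz"


# ---------------------------------------------------------------------------
# Stimulation vs rest
# ---------------------------------------------------------------------------

def _paired_table(rest_vals, stim_vals, group="control", channel="Cz"):
    rows = []
    for cond, vals in (("rest_closed", rest_vals), ("crying", stim_vals)):
        for i, v in enumerate(vals):
            rows.append({"subject": f"s{i}", "group": group,
                         "condition": cond, "channel": channel,
                         "feature": "FD", "value": float(v)})
    return pd.DataFrame(rows)


def test_stim_vs_rest_forced_direction():
    rest = np.random.default_rng(4).standard_normal(12)
    report = stim_vs_rest(_paired_table(rest, rest + 1.0), "control", "crying")
    row = report.iloc[0]
    assert row["significant"] and row["sign"] == "-" and row["test"] == "t"


def test_stim_vs_rest_identical_conditions():
    rest = np.random.default_rng(5).standard_normal(12)
    report = stim_vs_rest(_paired_table(rest, rest), "control", "crying")
    row = report.iloc[0]
    assert row["statistic"] == 0.0 and row["p_raw"] == 1.0


def test_stim_vs_rest_wilcoxon_fallback_small_n():
    rest = np.random.default_rng(6).standard_normal(6)
    report = stim_vs_rest(_paired_table(rest, rest + 2.0), "control", "crying")
    assert report.iloc[0]["test"] == "wilcoxon"


def test_stim_vs_rest_unpaired_subjects():
    df = _paired_table(np.arange(5.0), np.arange(5.0))
    df = df.drop(df[(df.condition == "crying") & (df.subject == "s0")].index)
    with pytest.raises(PairingError):
        stim_vs_rest(df, "control", "crying")


# ---------------------------------------------------------------------------
# Correlation maps
# ---------------------------------------------------------------------------

def _matched_tables(n=40, seed=0):
    rng = np.random.default_rng(seed)
    subjects = [f"s{i}" for i in range(n)]
    feat = pd.DataFrame({
        "subject": subjects, "group": "control", "condition": "rest_closed",
        "channel": "Cz", "feature": "FD",
        "value": rng.standard_normal(n),
    })
    psd = pd.DataFrame({"subject": subjects, "group": "control",
                        "condition": "rest_closed", "channel": "Cz"})
    for c in PSD_BIN_NAMES:
        psd[c] = rng.standard_normal(n)
    return feat, psd


def test_psd_correlation_perfect_match():
    feat, psd = _matched_tables()
    psd["psd_5_6"] = feat["value"].to_numpy()
    cmap = psd_feature_correlations(feat, psd)
    assert cmap.r.loc["psd_5_6", "FD"] == pytest.approx(1.0)
    assert bool(cmap.mask.loc["psd_5_6", "FD"])


def test_psd_correlation_null_rarely_masked():
    """Independent columns at n=100: |r| > 0.35 with p < .05 is rare."""
    feat, psd = _matched_tables(n=100, seed=7)
    cmap = psd_feature_correlations(feat, psd)
    assert cmap.r.abs().max().max() < 0.5
    assert int(cmap.mask.to_numpy().sum()) <= 1


def test_psd_correlation_constant_column_flagged():
    feat, psd = _matched_tables()
    psd["psd_2_3"] = 1.0
    cmap = psd_feature_correlations(feat, psd)
    assert np.isnan(cmap.r.loc["psd_2_3", "FD"])
    assert not bool(cmap.mask.loc["psd_2_3", "FD"])


@given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
def test_pearson_affine_invariance(a, b):
    feat, psd = _matched_tables(seed=8)
    c1 = psd_feature_correlations(feat, psd)
    feat2 = feat.assign(value=a * feat["value"] + b)
    c2 = psd_feature_correlations(feat2, psd)
    np.testing.assert_allclose(c1.r.to_numpy(dtype=float),
                               c2.r.to_numpy(dtype=float), atol=1e-9)


def test_psd_correlation_pooling_modes_differ_in_n(rest_tables):
    feats, psd = rest_tables
    cm_mean = psd_feature_correlations(feats, psd, pooling="channel_mean")
    cm_chan = psd_feature_correlations(feats, psd, pooling="per_channel")
    assert cm_mean.r.shape == cm_chan.r.shape == (18, 6)
    with pytest.raises(ValidationError):
        psd_feature_correlations(feats, psd, pooling="banana")


# ---------------------------------------------------------------------------
# Rating correlations
# ---------------------------------------------------------------------------

def _ratings_for(feat: pd.DataFrame, values: np.ndarray,
                 scale="irritation", stimulus="barking") -> pd.DataFrame:
    subjects = feat["subject"].unique()
    return pd.DataFrame({"subject": subjects, "group": "control",
                         "stimulus": stimulus, "scale": scale,
                         "value": values})


def test_rating_correlation_identity():
    rng = np.random.default_rng(9)
    vals = rng.standard_normal(20)
    feat = pd.DataFrame({
        "subject": [f"s{i}" for i in range(20)], "group": "control",
        "condition": "barking", "channel": "Cz", "feature": "FD",
        "value": vals,
    })
    ratings = _ratings_for(feat, vals)
    out = rating_feature_correlations(ratings, feat)
    row = out[(out.scale == "irritation") & (out.feature == "FD")].iloc[0]
    assert row["r"] == pytest.approx(1.0)
    assert row["significant"]


def test_rating_correlation_group_without_ratings_skipped(caplog):
    feat = pd.DataFrame({
        "subject": ["c1", "c2", "c3"], "group": "coma",
        "condition": "barking", "channel": "Cz", "feature": "FD",
        "value": [1.0, 2.0, 3.0],
    })
    ratings = pd.DataFrame(columns=["subject", "group", "stimulus",
                                    "scale", "value"])
    import logging
    with caplog.at_level(logging.INFO, logger="nleeg.stats"):
        out = rating_feature_correlations(ratings, feat)
    assert out.empty
    assert any("skipped" in m for m in caplog.messages)


def test_rating_coupling_recovery_replicates():
    """At latent coupling 0.6 the negative irritation-mobility correlation
    is recovered with |r| >= 0.3 in >= 80% of 200 replicate draws (n=30)."""
    hits = 0
    root = np.random.SeedSequence(123)
    for seq in root.spawn(200):
        rng = np.random.default_rng(seq)
        z = rng.standard_normal(30)
        mobility = -z + 0.3 * rng.standard_normal(30)   # feature tracks latent
        irritation = 0.6 * z + np.sqrt(1 - 0.36) * rng.standard_normal(30)
        feat = pd.DataFrame({
            "subject": [f"s{i}" for i in range(30)], "group": "control",
            "condition": "barking", "channel": "Cz",
            "feature": "HjorthMobility", "value": mobility,
        })
        ratings = _ratings_for(feat, irritation)
        out = rating_feature_correlations(ratings, feat)
        r = out.iloc[0]["r"]
        if r < -0.3:
            hits += 1
    assert hits >= 160


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def test_significant_channels_listing():
    rng = np.random.default_rng(10)
    rows = []
    for chan, shift in (("Cz", 3.0), ("Pz", 0.0)):
        rows.append(feature_table(
            {"a": rng.standard_normal(10),
             "b": rng.standard_normal(10) + shift}, channel=chan))
    report = group_anova_rest(pd.concat(rows, ignore_index=True))
    assert significant_channels(report, "FD") == ["Cz"]
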