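"""Between-group resting contrasts with Bonferroni + Tukey reporting.

Simulates a resting cohort (8 subjects per group), runs the per-channel
one-way ANOVA family for each feature, and prints the per-feature list of
significant channels in the conventional clinical style ("all except ...").

Run: python examples/03_group_statistics.py
"""

from nleeg import SubjectDesign, default_cohort_spec, gen_cohort
from nleeg.pipeline import extract_cohort
from nleeg.stats import channel_list_string, group_anova_rest, significant_channels

design = SubjectDesign(stimuli=(), n_epochs=0, epoch_s=30.0, rest_s=40.0,
                       include_rest_open=False)
spec = default_cohort_spec(n_subjects=8, seed=3, design=design)
features, _ = extract_cohort(gen_cohort(spec))

report = group_anova_rest(features, alpha=0.05)
print("group effect at rest, Bonferroni over the 19-channel family:\n")
for feature in report["feature"].unique():
    sig = significant_channels(report, feature)
    sub = report[report["feature"] == feature]
    fmax = sub["F"].max()
    print(f"  {feature:17s} F(4, {int(sub['df_within'].iloc[0])}) up to "
          f"{fmax:6.1f}  significant: {channel_list_string(sig)}")

row = report[(report["feature"] == "EMF") & report["significant"]].iloc[0]
print(f"\nTukey post-hoc for EMF at {row['channel']}:")
for pair in row["tukey"]:
    a, b = pair["pair"]
    print(f"  {a:13s} vs {b:13s} p = {pair['p']:.4f}")
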