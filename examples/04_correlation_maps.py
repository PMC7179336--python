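"""PSD-feature and rating-feature correlation maps.

Reproduces the two correlation analyses on synthetic data: the grid of
Pearson correlations between 1-Hz PSD bins and the nonlinear features
(masked at p < 0.05 and |r| > 0.35), and the coupling between subjective
irritation ratings and Hjorth mobility across subjects.

Run: python examples/04_correlation_maps.py
"""

from nleeg import SubjectDesign, default_cohort_spec, gen_cohort
from nleeg.pipeline import extract_cohort
from nleeg.stats import psd_feature_correlations, rating_feature_correlations

design = SubjectDesign(stimuli=("barking",), n_epochs=2, epoch_s=15.0,
                       rest_s=30.0, include_rest_open=False)
spec = default_cohort_spec(n_subjects=8, seed=5, design=design)
cohort = gen_cohort(spec)
features, psd = extract_cohort(cohort)

cmap = psd_feature_correlations(features, psd)
print("Pearson r between PSD bins and features "
      "(observations: subject x condition cells, channel-averaged):")
print(cmap.r.round(2).to_string())
print(f"\ncells passing p < {cmap.alpha} and |r| > {cmap.r_display}: "
      f"{int(cmap.mask.to_numpy().sum())} of {cmap.mask.size}")
print("negative r in the slow bins for FD/EMF/Hjorth and positive for RAT "
      "is the expected slowing signature.")

rf = rating_feature_correlations(cohort.ratings, features)
irr = rf[(rf["scale"] == "irritation") & (rf["feature"] == "HjorthMobility")]
print("\nirritation vs Hjorth mobility (per group, 'barking' condition):")
print(irr[["group", "n", "r", "p", "significant"]].round(3).to_string(index=False))
print("subjects with diffusely slowed EEG (low mobility) report more "
      "irritation, so r should be negative.")
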