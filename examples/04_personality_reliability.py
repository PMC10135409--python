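"""Score questionnaire traits and quantify interrater reliability.

Trait scores average the reliable keyed items (reversing negative
items) within rater, then across raters.  Reliability of the mean score
is ICC(3,k): the share of between-male variance in the k-rater mean.
"""

from pantrank.personality import score_traits, trait_reliabilities
from pantrank.simulate import SimConfig, simulate_study

bundle, truth = simulate_study(SimConfig(seed=1))

scores = score_traits(bundle.ratings)
print(f"trait scores for {len(scores)} males (1-7 scale):")
print(scores.round(2).head().to_string())

r = scores["dominance"].corr(scores["conscientiousness"])
print(f"\nDominance-Conscientiousness correlation: {r:.3f} "
      "(configured trait-level value: -0.6)")

rel = trait_reliabilities(bundle.ratings)
print("\ninterrater reliability of mean ratings, ICC(3,k):")
print(rel[["icc_mean_raters", "k_effective"]].round(3).to_string())
print("values near 0.4-0.5 mean roughly half the variance in mean "
      "scores reflects stable differences between males")
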