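"""Generate a synthetic chimpanzee community and inspect its tables.

The simulator creates a roster of males with staggered hierarchy entries
and deaths, a pant-grunt interaction stream from a true Elo process,
questionnaire ratings driven by a latent quality factor, and siring
events with known ground-truth coefficients.
"""

from pantrank.data_model import filter_adult_interactions, save_study_tables
from pantrank.simulate import SimConfig, simulate_study

bundle, truth = simulate_study(SimConfig(seed=1, n_males=20, study_years=25))

print(f"males in roster:        {len(bundle.roster)}")
print(f"pant-grunt events:      {len(bundle.interactions)}")
adult = filter_adult_interactions(bundle.interactions, bundle.roster)
print(f"  both participants 12+: {len(adult)}")
print(f"questionnaire rows:     {len(bundle.ratings)}")
print(f"siring events:          {len(bundle.paternity)}")
print(f"relatedness dyads:      {len(bundle.relatedness)}")
print(f"true update constant k: {truth.k}")
print("true entry scores (first 5):")
print(truth.entry_scores.head().round(1).to_string())

# the bundle round-trips through plain CSV files
paths = save_study_tables(bundle, "scratch/example_bundle")
print("tables written to:", ", ".join(str(p) for p in paths.values()))
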