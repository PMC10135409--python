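"""Extract rank-trajectory components and validate them against traits.

Each male's lifetime rank curve is reduced to six components (entry
score, rise slope, peak, best ordinal, top tenure, decline slope), each
with its own eligibility rule, and regressed on z-scored personality
traits by ordinary least squares.
"""

import warnings

from pantrank.data_model import filter_adult_interactions
from pantrank.elo import daily_scores, fit_ml_elo
from pantrank.personality import score_traits
from pantrank.simulate import SimConfig, simulate_study
from pantrank.trajectories import COMPONENTS, extract_components, validate_component

warnings.simplefilter("ignore")

bundle, _ = simulate_study(SimConfig(seed=1, n_males=20, study_years=25))
adult = filter_adult_interactions(bundle.interactions, bundle.roster)
daily = daily_scores(fit_ml_elo(adult, bundle.roster).params, adult,
                     bundle.roster)

comp = extract_components(daily, bundle.roster).set_index("male_id")
print("eligible males per component:")
for c in COMPONENTS:
    print(f"  {c:18s} {int(comp[f'{c}_eligible'].sum()):3d}")

traits = score_traits(bundle.ratings)
print("\nbivariate validation: component ~ z(Dominance)")
for c in ["entry_cardinal", "rise_slope", "peak_cardinal"]:
    vals = comp[c].where(comp[f"{c}_eligible"])
    try:
        res = validate_component(vals, traits["dominance"])
    except ValueError:
        continue
    print(f"  {c:15s} beta={res.beta:+.4f}  "
          f"95% CI [{res.ci_low:+.4f}, {res.ci_high:+.4f}]  n={res.n}")
print("a positive slope means higher-Dominance males score higher on "
      "that trajectory component")
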