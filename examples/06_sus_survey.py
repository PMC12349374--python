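"""Score and aggregate the bundled SUS usability survey.

The package ships the original device evaluation's 15-respondent survey
(final scores plus visual-condition metadata).  Scores band into
Unacceptable (<= 50), Marginal (51-68) and Acceptable (69-100).
"""

from oculomaze import aggregate_sus, sus_category, sus_score
from oculomaze.io import bundled_usability_scores
from oculomaze.usability import SUSResponse

# Scoring a raw questionnaire: odd items positive, even items negative.
resp = SUSResponse((4, 2, 5, 1, 4, 2, 5, 2, 4, 1))
print(f"example questionnaire -> score {sus_score(resp)} "
      f"({sus_category(sus_score(resp))})")

records = bundled_usability_scores()
agg = aggregate_sus(records)
print(f"\ncohort n={agg['n']}: mean={agg['mean']:.2f}, "
      f"sample std={agg['sample_std']:.2f}")
print(f"categories: {agg['counts']}")
print(f"acceptance rate: {agg['acceptance_rate_pct']}% "
      f"(marginal {agg['marginal_rate_pct']}%)")
for r in records:
    if "Amblyopia" in (r.visual_condition or ""):
        print(f"  amblyopic respondent {r.id}: score {r.score} "
              f"({sus_category(r.score)})")
# A mean in the mid-70s is 'good' usability; all three amblyopic
# respondents rate the device Acceptable.
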