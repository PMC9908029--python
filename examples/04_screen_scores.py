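"""Score a small drug screen: differentiating / dedifferentiating scores,
hit calls, the combination score, and cross-culture intersection.

The differentiating score rewards shifting cells into committed +
differentiated states while depleting cycling progenitors; the
dedifferentiating score tracks MuSC-like enrichment (a 1.5-fold enrichment
is a dedifferentiating hit).
"""

import myostate as ms

# hand-held compositions (percent scale) to show the arithmetic
control = {"pct_quiescent_musc": 10, "pct_cycling_musc": 10,
           "pct_cycling_progenitor": 40, "pct_committed": 20,
           "pct_differentiated": 5}
treated = {"pct_quiescent_musc": 10, "pct_cycling_musc": 10,
           "pct_cycling_progenitor": 10, "pct_committed": 30,
           "pct_differentiated": 20}
s = ms.differentiating_score(treated, control)
print(f"differentiating score: {s:.0f}  "
      "(bracket treated minus bracket control; positive = differentiation)")
print("differentiating hit:",
      ms.is_differentiating_hit(treated, control))
print("MuSC fold change:", ms.musc_fold_change(treated, control))

# combination screen: average over the four library doses minus the
# 50 nM backbone score
combo = ms.combined_differentiating_score(
    {10.0: 10.0, 1.0: 20.0, 0.1: 30.0, 0.01: 40.0}, backbone_score=15.0
)
print(f"combined differentiating score: {combo:.0f}  "
      "(mean of four doses minus backbone alone)")

# intersect hits of two cultures, ranked by the mean score
import pandas as pd

culture_a = pd.DataFrame({"compound": ["tram", "cobi", "erda"],
                          "s_diff": [60.0, 40.0, 30.0],
                          "is_diff_hit": [True, True, True]})
culture_b = pd.DataFrame({"compound": ["tram", "erda", "pona"],
                          "s_diff": [50.0, 35.0, 20.0],
                          "is_diff_hit": [True, True, True]})
shared = ms.rank_and_intersect(culture_a, culture_b)
print("\nshared differentiating hits across cultures:")
print(shared.to_string(index=False))
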