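"""Novelty, diversity, similarity, and condition-matching metrics.

Runs the sample-quality metrics on small hand-made sets so the numbers
are easy to verify: normalized edit distance (NED) against a training
set, pairwise NED within a generated batch, Needleman-Wunsch percent
identity, and the ±10% condition-matching rule.
"""

import numpy as np

from pepmorph import condition_match, ned, novelty_report, nw_percent_identity
from pepmorph.evalgen import ConditionQuery, diversity_report

training = ["ACDFK", "KKWWY", "IVLFI", "GGSGG"]
generated = ["ACDFK", "ACDWK", "PMNQR"]

report = novelty_report(generated, training)
print(f"novelty vs {len(training)} training peptides:")
print(f"  exact matches: {report['exact_match_fraction']:.0%}")
print(f"  nearest-neighbour NED per sample: "
      f"{np.round(report['nn_ned'], 3).tolist()} (median {report['nn_ned_median']:.3f})")

div = diversity_report({"condition-1": generated})
entry = div["per_condition"]["condition-1"]
print(f"diversity within the batch: pairwise NED "
      f"{entry['pairwise_ned_mean']:.3f} ± {entry['pairwise_ned_std']:.3f}")

print(f"NW percent identity ACDFK vs ACDWK: "
      f"{nw_percent_identity('ACDFK', 'ACDWK'):.0f}%")
print(f"NED is a metric on [0,1]: ned('AC','A') = {ned('AC', 'A')}")
print()

# condition matching: binary slots exact, continuous within ±10%
query = ConditionQuery(np.array([5.0, 2.0, 1.0, 0.0, 0.0, 0.0]),
                       np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0]))
for ap_pred in (2.15, 2.3):
    predicted = np.array([5.0, ap_pred, 1.0, np.nan, np.nan, np.nan])
    result = condition_match(predicted, query)
    verdict = "match" if result["all"] else "no match"
    print(f"target (length 5, AP 2.0, assembled), predicted AP {ap_pred}: {verdict}")
print("2.15 sits inside the ±10% window around 2.0; 2.3 falls outside, and a")
print("single failing slot fails the aggregate match.")
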