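"""Classify duplicate-gene retention mechanisms on simulated profiles.

Builds a synthetic three-genome expression dataset with planted fates,
derives the divergence cutoff E_div from single-copy ortholog distances,
classifies every duplicate triple, and compares the calls against the
planted truth.
"""

import numpy as np

from dupevol import fate, simulate

cfg = simulate.FateSimConfig(seed=42, n_per_fate=60)
ancestor, focal, pairs, truth = simulate.simulate_fate_dataset(cfg)

single_copy = fate.single_copy_distances(pairs, ancestor, focal)
e_div = fate.select_ediv(single_copy)  # 0.90 quantile of E(S1,S2)
print(f"E_div (q=0.90 of {len(single_copy)} single-copy distances): {e_div:.3f}")

calls = fate.classify_triples(pairs, ancestor, focal, e_div)
table = fate.fate_by_dup_type(calls, pairs)
print("\nFate counts by duplication type:")
print(table.loc[list(fate.FATES_COARSE)])

pred = {c.triple_id: c.fate for c in calls}
recovery = np.mean([pred[t] == f for t, f in zip(truth.triple_id, truth.fate)])
print(f"\nPlanted-fate recovery: {100 * recovery:.1f}% of {len(truth)} triples")
print(
    "Conserved copies sit within E_div of the ancestor; a neofunctionalized\n"
    "copy exceeds it alone; subfunctionalized copies exceed it individually\n"
    "but their combined profile does not; specialized triples exceed it in\n"
    "every comparison."
)
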