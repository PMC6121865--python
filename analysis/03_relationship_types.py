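"""Classify within-colony polyp pairs against simulated-mating nulls.

For each retained colony: pairwise genotype-mismatch distances, a
neighbor-joining tree, outcrossing and selfing nulls of simulated
within-colony reproduction, and Type I/II/III calls (below / within /
above the range the colony's allele pool can generate).  Scores the
calls against the generator's ground truth and tests whether possessing
Type II comparisons predicts possessing Type III (Fisher's exact test).
"""

import numpy as np
import pandas as pd

from _common import COLONY_FILTER, RESULTS, SEED, load_study, write
from polypkin.distances import nj_tree, pairwise_distances
from polypkin.genotype_io import colony_passes_retention, filter_colony_panel
from polypkin.mating import classification_null, classify_pairs, colony_type_summary, simulate_offspring

gm, truth_pairs, _ = load_study()
truth = {
    (r.sample_a, r.sample_b): r.expected_type for r in truth_pairs.itertuples()
}

(RESULTS / "trees").mkdir(parents=True, exist_ok=True)
seed_rng = np.random.default_rng(SEED + 1)
all_calls, null_rows = [], []
calls_by_colony = {}
for colony in gm.colonies():
    panel = filter_colony_panel(gm, colony, COLONY_FILTER)
    if not colony_passes_retention(panel, COLONY_FILTER)[0]:
        continue
    s = int(seed_rng.integers(2**30))
    null = classification_null(panel, n_offspring=1000, seed=s)
    selfing = simulate_offspring(panel, "selfing", 1000, seed=s + 2)
    calls = classify_pairs(pairwise_distances(panel), null)
    calls.insert(0, "colony", colony)
    calls_by_colony[colony] = calls
    all_calls.append(calls)
    for n in (null, selfing):
        v, c = np.unique(n.distances, return_counts=True)
        null_rows += [
            {"colony": colony, "mode": n.mode, "d": int(x), "count": int(k)}
            for x, k in zip(v, c)
        ]
    (RESULTS / "trees" / f"{colony}.nwk").write_text(
        nj_tree(calls, panel.sample_ids) + "\n"
    )

calls = pd.concat(all_calls, ignore_index=True)
calls["expected_type"] = [
    truth[tuple(sorted((a, b)))] for a, b in zip(calls["sample_a"], calls["sample_b"])
]
write(calls, "03_relationship_calls.tsv")
write(pd.DataFrame(null_rows), "03_null_distributions.tsv")

acc = (
    calls.assign(hit=calls["type"] == calls["expected_type"])
    .groupby("expected_type")["hit"]
    .agg(["mean", "size"])
)
print("Type-call accuracy vs ground truth:")
print(acc.rename(columns={"mean": "accuracy", "size": "n_pairs"}).to_string())

presence, fisher = colony_type_summary(calls_by_colony)
write(presence, "03_colony_type_presence.tsv")
print("\nPer-colony type presence:")
print(presence.to_string(index=False))
print(f"\nFisher's exact test, Type II presence vs Type III presence: "
      f"p = {fisher['p_value']:.4f} (degenerate={fisher['degenerate']})")
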