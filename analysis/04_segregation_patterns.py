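"""Classify each within-colony SNP's segregation pattern.

Per SNP: clonal noise (one configuration one error step off consensus),
Mendelian segregation of lineage alleles, or foreign alleles — with
alternate homozygotes (both-allele mismatches) as the fusion signal.
Breaks down sites polymorphic inside the main clonal lineage into
singleton errors / repeated one-step configurations (somatic mutation) /
unexplained, and runs the allelic-dropout read-depth diagnostic.
"""

import json

import numpy as np
import pandas as pd

from _common import COLONY_FILTER, RESULTS, SEED, load_study, write
from polypkin.distances import pairwise_distances
from polypkin.genotype_io import colony_passes_retention, filter_colony_panel
from polypkin.mating import classification_null, classify_pairs
from polypkin.segregation import classify_colony, dropout_diagnostic, typeI_breakdown

gm, _, truth_labels = load_study()
settlers = truth_labels[truth_labels["label"] == "unrelated"].groupby("colony").size()

rows, breakdown = [], {"singleton": 0, "repeated_one_step": 0, "unexplained": 0}
diagnostics = {}
rng = np.random.default_rng(SEED + 2)
for colony in gm.colonies():
    panel = filter_colony_panel(gm, colony, COLONY_FILTER)
    if not colony_passes_retention(panel, COLONY_FILTER)[0]:
        continue
    calls = classify_pairs(
        pairwise_distances(panel),
        classification_null(panel, 1000, seed=int(rng.integers(2**30))),
    )
    classes, lineage = classify_colony(panel, calls)
    rows.append(classes)
    bd = typeI_breakdown(panel, lineage)
    for k in breakdown:
        breakdown[k] += bd["counts"][k]
    diagnostics[colony] = dropout_diagnostic(panel, classes)

classes = pd.concat(rows, ignore_index=True)
write(classes, "04_snp_classifications.tsv")
(RESULTS / "04_dropout_diagnostics.json").write_text(
    json.dumps(diagnostics, indent=1, default=str)
)

print("SNP class counts per colony:")
print(classes.groupby(["colony", "snp_class"]).size().unstack(fill_value=0).to_string())
print("\nAlternate-homozygote (fusion-signal) sites vs settlers present:")
alt = classes[classes["foreign_detail"] == "both_alleles"].groupby("colony").size()
for colony in sorted(classes["colony"].unique()):
    print(f"  {colony}: {int(alt.get(colony, 0)):3d} sites, "
          f"{int(settlers.get(colony, 0))} settlers in truth")

total = sum(breakdown.values())
print("\nSites polymorphic within the main clonal lineage "
      f"(n={total}): " + ", ".join(
          f"{k} {100 * v / total:.1f}%" for k, v in breakdown.items()))
for colony, rep in diagnostics.items():
    if rep.get("testable"):
        w = rep["welch"]
        print(f"dropout check {colony}: t={w['t']:.2f} (df={w['df']:.1f}) "
              f"p={w['p_value']:.3f}; MWU p={rep['mannwhitney']['p_value']:.3f}")
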