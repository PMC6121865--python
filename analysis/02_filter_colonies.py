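"""Apply colony-level SNP retention filters and report what survives.

Per colony: mask calls below 8 reads, keep sites genotyped in every
polyp and still polymorphic within the colony, then retain colonies with
more than four polyps and at least 100 SNPs.
"""

import pandas as pd

from _common import COLONY_FILTER, load_study, write
from polypkin.genotype_io import colony_passes_retention, filter_colony_panel

gm, _, _ = load_study()
rows = []
for colony in gm.colonies():
    panel = filter_colony_panel(gm, colony, COLONY_FILTER)
    ok, reason = colony_passes_retention(panel, COLONY_FILTER)
    rows.append(
        {
            "colony": colony,
            "n_polyps": panel.n_samples,
            "n_snps": panel.n_sites,
            "retained": ok,
            "reason": reason or "",
            **panel.meta["filter_report"],
        }
    )
table = pd.DataFrame(rows)
path = write(table, "02_colony_retention.tsv")
print(table.to_string(index=False))
n_kept = int(table["retained"].sum())
print(f"\n{n_kept}/{len(table)} colonies retained; note that even pure-clone "
      "colonies carry SNPs (the founder's heterozygous sites are polymorphic)")
print(f"wrote {path}")
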