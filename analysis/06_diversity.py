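"""Population-level diversity and between-colony differentiation.

Per collecting location: SNP counts, percent polymorphic sites (over all
assayed sites, variant and invariant), nucleotide diversity pi, F_IS,
the within- vs between-colony distance distributions, and pairwise
Weir & Cockerham F_ST between colonies.
"""

from _common import RESULTS, load_study, write
from polypkin.distances import within_between_distributions
from polypkin.diversity import diversity_table, pairwise_fst

gm, _, _ = load_study()

table = diversity_table(gm)
write(table, "06_diversity_table.tsv")
print("Per-location diversity (pi over all assayed sites):")
print(table.round(5).to_string(index=False))

for loc in gm.locations():
    fst = pairwise_fst(gm, loc)
    fst.round(6).to_csv(RESULTS / f"06_fst_{loc}.tsv", sep="\t")
    off_diag = fst.where(~(fst == 0)).stack()
    print(f"\n{loc} between-colony F_ST (Weir & Cockerham theta): "
          f"mean {off_diag.mean():.3f}, range {off_diag.min():.3f}-{off_diag.max():.3f}")

    recs, summary = within_between_distributions(gm, loc)
    write(recs.assign(location=loc), f"06_within_between_{loc}.tsv")
    s = summary.set_index("scope")
    print(f"{loc} genetic distances: within-colony mean "
          f"{s.loc['within_colony', 'mean_d']:.1f}, between-colony mean "
          f"{s.loc['between_colony', 'mean_d']:.1f} (ranges overlap: "
          f"{s.loc['within_colony', 'max_d'] >= s.loc['between_colony', 'min_d']})")
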