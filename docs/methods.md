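# Methods

`polypkin` analyzes genetic chimerism and clonality inside colonies of
aplanulate hydrozoans (the motivating system is *Ectopleura larynx*-like:
colonies begin with 4–6 determinate clonal buds of a founder, then grow by
fusing sexually produced juvenile polyps).  Input is a matrix of diploid,
biallelic SNP dosages with per-call read depth for individual polyps,
grouped into colonies and collecting locations.  All analyses run equally
on a real VCF + sample map or on the package's synthetic generator, which
provides ground truth for every polyp and pair.

## Genotype model and filtering

Genotypes are unphased alternate-allele dosages (0, 1, 2; missing = no
call).  Colony-level panels mask calls below a depth floor (default 8
reads), keep sites genotyped in a configurable fraction of the colony's
polyps (default all of them, so colony panels have no missing data), and
keep sites that are polymorphic *allele-wise* within the colony — a site
where every polyp is heterozygous carries both alleles and is a SNP.
Colonies enter the analysis only with more than four retained polyps and
at least 100 SNPs.  Location-level panels relax the presence fraction
(default 0.5) and optionally thin to one SNP per RAD locus (lowest
position, deterministically) where inter-SNP independence matters; the
kinship analyses use the thinned panel, the diversity statistics use all
SNPs.  Filtering is idempotent and every panel records per-rule drop
counts.

Nucleotide diversity is reported over *all* assayed sites, variant and
invariant, so the genotype matrix carries the total assayed-site count
explicitly (VCFs do not record invariant sites); the VCF writer stores it
in a `##total_assayed_sites` header line.

## Pairwise distance and relationship classification

The within-colony distance between two polyps is the number of sites at
which their genotype calls differ (any dosage difference counts one site;
an L1 dosage distance is available but not the default).  Sites missing
in either member are excluded and the comparable-site count reported.
Neighbor-joining trees (Saitou–Nei, negative branches clamped with the
excess moved to the sister branch) summarize each colony.

Observed distances are classified against a null of *hypothetical
within-colony sexual reproduction*.  Two gamete schemes are implemented:

* **pool** — each gamete allele is an independent draw per site from the
  colony's allele frequencies (the Hardy–Weinberg resampling null of the
  clonal-discrimination literature).  Sites are independent, so the null
  measures what the colony's allele *pool* can generate.
* **parents** — two distinct polyps are drawn as parents and one gamete
  per parent is produced by Mendelian segregation.  Whole-genotype
  linkage is preserved: if a divergent fused polyp is in the mating pool,
  half its genome enters single offspring, and the null widens to cover
  almost any observed distance, which destroys the ability to call
  fusion.  This scheme is retained for comparison and for brood-mate
  (shared-parent-pair) similarity.

Classification uses composite bounds: the lower bound is the minimum of
the parent-pair null (two brood-mates of a repeated cross are the most
similar offspring within-colony sex can produce) and the upper bound is
the maximum of the gamete-pool null (random unions of pool gametes are
the most novel).  Pairs below the lower bound are **Type I** (clone-mates
differing only by error or somatic mutation), within the bounds **Type
II** (consistent with within-colony sexual reproduction — siblings,
parent–offspring), above them **Type III** (more divergent than the
colony could produce sexually — fused unrelated polyps).  Bounds default
to the empirical min/max (the most conservative reading of "range
expected"); quantile bounds are config-exposed.  Selfing-mode nulls (both
gametes segregated from one polyp) are produced for visual contrast only,
because colonies are single-sex; they never set classification bounds.
The default null size is 1000 simulated offspring (all pairwise distances
among them form the null multiset).

A colony-level 2×2 Fisher's exact test (two-sided) asks whether colonies
possessing Type II comparisons also tend to possess Type III comparisons;
a table with a zero margin is reported as p = 1 with a degeneracy flag.

## Per-SNP segregation classes

The **main clonal lineage** of a colony is the largest set of polyps
connected by Type I calls (ties to the component containing the
lexicographically smallest polyp; a colony with no Type I pair degrades,
flagged, to the polyp with the smallest mean distance).  Its per-site
consensus is the modal genotype, ties resolved toward the genotype with
the smallest total dosage distance to the lineage, then the smaller
dosage.

Each within-colony polymorphic SNP is classified:

* **A (clonal noise)** — exactly one deviant configuration, one dosage
  step (0↔1 or 1↔2; 0↔2 counts as two steps) from the consensus.  A
  single carrier looks like sequencing error; multiple carriers like a
  shared somatic mutation.
* **B (Mendelian)** — all genotypes constructible from alleles present in
  the main lineage (segregation of clonal alleles), and not class A.
* **C (foreign)** — some polyp carries an allele absent from the
  lineage's genotypes at that site; subdivided into one-allele mismatches
  and **both-allele mismatches** (the alternate homozygote).  Because
  independent somatic mutation striking the same site twice is vanishingly
  unlikely, alternate homozygotes are the fusion signal.

Sites polymorphic *inside* the lineage are further broken down into
singleton configurations (one carrier, one step: sporadic error),
repeated one-step configurations (≥2 carriers of each of two
configurations: somatic mutation shared along the budding order), and
unexplained (more configurations or larger steps).

The allelic-dropout diagnostic guards the fusion signal: if alternate
homozygotes were false homozygotes from one allele dropping out, those
sites should be shallower.  Per-site mean colony depth is compared
between alternate-homozygote sites and all others with a Welch t-test
(fractional Welch–Satterthwaite df) and a two-sided Mann–Whitney U
(exact enumeration below 25 observations and without ties, otherwise the
normal approximation with tie correction).

## Kinship and IBD

KING-robust kinship for a pair (i, j) over shared sites:

φ = (N_het,het − 2·N_opposite-hom) / (N_het(i) + N_het(j))

It needs no allele frequencies and is robust to population structure.
Expectations: 0.5 identical clones, 0.25 parent–offspring or full sibs,
0 unrelated; pairs with no heterozygous calls are undefined and flagged
(never reported as 0).  Raw values are kept in tables; summaries also
report means with negatives clamped to 0 ("interpreted").

IBD-state probabilities Z0/Z1/Z2 use the PLINK-style method of moments:
observed identity-by-state counts are equated to their expectations given
allele frequencies, solved sequentially (Z0 from IBS0, Z1 from the IBS1
residual, Z2 as the complement), then bounded to [0, 1] and renormalized.
Frequencies come from all samples at the location; the allele-frequency
monomials (p²q², p³q, …) are replaced by unbiased falling-factorial
estimators from the sample allele counts — the standard small-sample
moment adjustment — with plug-in frequencies as a config option.  Sites
monomorphic in the frequency sample are excluded.  Pairs sharing fewer
than 50 usable sites (config-exposed) are flagged.

## Diversity

Per site, the unbiased heterozygosity (n/(n−1))·2p̂(1−p̂) over n observed
allele copies is summed across polymorphic sites and divided by the total
assayed-site count to give π.  F_IS = 1 − ΣH_obs/ΣH_exp is computed
ratio-of-sums (stable when per-site expected heterozygosity is tiny, as
in this low-diversity system) with Nei's 2n/(2n−1) small-sample
correction in H_exp.  Between-colony differentiation uses the Weir &
Cockerham (1984) θ estimator, per-site a/b/c variance components
aggregated ratio-of-sums; single-polyp colonies are excluded with a
warning and the estimator name is recorded in output metadata.

## Distance clustering and error baselines

The proportions of differing sites from all within-colony comparisons are
clustered in one dimension with Lloyd's k-means (k-means++, best of 25
restarts; validated in tests against an exact dynamic-programming 1-D
partition).  Cluster-count selection takes a majority vote of the elbow
(largest second difference of the within-SS curve), mean silhouette and
Calinski–Harabasz, ties to the smaller k.  This deliberately replaces a
20-index battery with three standard indices.  A mean Phred score Q is
converted to a per-base error probability 10^(−Q/10) as the noise floor
for clone-mate distances, alongside a published HiSeq 2000/2500
substitution-error reference (0.00191, SD 0.00027).

Note one geometry caveat: whether Type III comparisons occupy their own
k-means cluster at K = 2 depends on where family distances fall between
the clone and fusion scales.  In real low-diversity data sib distances
sit near the error scale and Type III isolates; in the default synthetic
study sib distances are intermediate, so at K = 2 the split separates
clones from everything else.  The crosstab records the isolation flag
either way.

## Synthetic colony generator

The generator is first-class, tested code and defines the study
conditions:

* **Population**: 100,000 assayed sites, 0.5% polymorphic (field
  estimates for this system span roughly 0.3–0.8% per location),
  alternate-allele frequencies Uniform(0.05, 0.95), giving expected
  π ≈ 0.0018 — the low-diversity regime (π ~ 0.001–0.002) these
  populations show.
* **Colony differentiation**: colonies in this system carry distinct
  allele frequencies (elevated between-colony F_ST).  Each colony's
  founder and the sire of her brood are drawn from *natal* frequencies —
  a Balding–Nichols Beta draw around the population frequencies with
  differentiation `colony_fst` (default 0.10; 0 recovers a panmictic
  population, used in tests of Hardy–Weinberg expectations).  Drawing the
  sire from the founder's natal stock encodes locally related sires
  (limited gamete dispersal); each unrelated settler is the product of a
  different natal colony and gets its own frequency draw.  Without this
  differentiation, settlers from a panmictic low-diversity pool are
  statistically indistinguishable from brooded offspring.
* **Composition** (defaults, config-exposed): 5 clonal ramets of the
  founder (determinate budding of 4–6 polyps), 4 brooded offspring by
  Mendelian segregation from founder × sire, 2 fused settlers — a colony
  of 11 polyps, within the 5–15 polyps per colony a field sample yields.
* **Noise**: per-call genotype miscalls at rate 0.001, each moving one
  dosage step (between the Phred-derived floor 1.7×10⁻⁴ and the published
  HiSeq rate 1.9×10⁻³); somatic mutations at rate 0.001 per site per
  colony, each shared by a contiguous run of the budding order (producing
  the repeated one-step configurations the classifier looks for); read
  depths Negative-Binomial (mean 30, dispersion 5; the depth filter is 8);
  optional allelic dropout models per-haplotype coverage — a heterozygote
  whose minor haplotype receives zero reads is recorded as a homozygote
  at roughly half depth.
* **Scope**: somatic mutations and miscalls are simulated at the assayed
  polymorphic sites (the emitted VCF's site universe); mutations at
  invariant sites, raw reads, restriction sites and library artifacts are
  not modeled.  The generator therefore validates the genotype-level
  analysis, not upstream read processing: passing tests say nothing about
  locus-assembly errors, paralog collapse, or batch effects in real
  RAD-seq data.

Every simulated polyp and pair carries a truth label (clone / offspring /
unrelated; clonal / family / unrelated per pair), and somatic, miscall
and dropout events are logged individually, so classifier outputs can be
scored exactly.

## Determinism and problem sizes

A single master seed drives every stage; derived stage seeds come from a
`numpy` Generator seeded with it, and all tables are written with fixed
float formatting, so reruns are byte-identical.  The default analysis
(six colonies, ~54 polyps, 500 SNPs, 1000-offspring nulls) completes in
a few seconds; the kinship calibration (50 sib and 100 unrelated pairs at
10,000 SNPs) in under a minute.  These sizes were chosen as the smallest
at which the Monte-Carlo error of each check is comfortably below its
tolerance.

## Known limitations

* The null-bound rule (min/max of the composite null) is a design choice;
  the "range expected under sexual reproduction" has no unique
  operationalization, and per-class error rates trade off against each
  other as the bounds move.  Quantile bounds are exposed for sensitivity
  analysis.
* KING-robust φ between members of *different* differentiated colonies is
  biased negative (visible in the between-colony means); this mirrors the
  estimator's behavior on real structured samples and is why negative
  values are interpreted as 0.
* The segregation classifier assumes the main clonal lineage is correctly
  identified; in a colony dominated by settlers the lineage degrades to a
  single polyp and class assignments lose meaning (flagged).
* W&C θ between colonies that are clone stacks measures differentiation
  between essentially two genotypes; values are meaningful as "elevated
  vs not", not as migration-model parameters.
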