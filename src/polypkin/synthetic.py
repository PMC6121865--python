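"""Synthetic colony generator with ground truth.

Emulates the genetic structure of an aplanulate hydrozoan colony growing
by limited determinate budding plus fusion of sexually produced polyps:

* a founder genotype drawn in Hardy-Weinberg proportions from a
  low-diversity population (a small fraction of assayed sites polymorphic,
  nucleotide diversity on the order of 1e-3);
* ``n_clonal`` ramets of the founder, differing only by per-call genotype
  miscalls and by somatic mutations shared along contiguous runs of the
  budding order;
* ``n_offspring`` brooded juveniles produced by Mendelian segregation from
  the founder crossed with one independently drawn father;
* ``n_unrelated`` settlers drawn fresh from the same population;
* per-call read depths from a negative binomial, with optional allelic
  dropout that converts a heterozygote with single-allele coverage into a
  false homozygote at roughly half depth.

Every emitted polyp and every within-colony pair carries a ground-truth
label, so downstream classifiers can be scored without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, write_sample_map, write_vcf

LOCUS_LENGTH = 86  # bp per RAD locus (read length after trimming)


@dataclass
class PopulationModel:
    """Low-diversity source population for founders, fathers and settlers.

    Defaults give ~500 polymorphic sites out of 100,000 assayed
    (0.5% polymorphic) with allele frequencies Uniform(0.05, 0.95),
    hence expected nucleotide diversity ~= 0.0018.
    """

    n_total_sites: int = 100_000
    fraction_polymorphic: float = 0.005
    freq_low: float = 0.05
    freq_high: float = 0.95
    colony_fst: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_polymorphic < 1.0:
            raise ValueError("fraction_polymorphic must be in (0, 1)")
        if not 0.0 <= self.colony_fst < 1.0:
            raise ValueError("colony_fst must be in [0, 1)")

    @property
    def n_polymorphic(self) -> int:
        return int(round(self.n_total_sites * self.fraction_polymorphic))

    def expected_heterozygosity(self) -> float:
        """Closed-form E[2p(1-p)] for p ~ Uniform(freq_low, freq_high)."""
        a, b = self.freq_low, self.freq_high
        ep = (a + b) / 2.0
        ep2 = (a * a + a * b + b * b) / 3.0
        return 2.0 * (ep - ep2)


@dataclass
class ColonyRecipe:
    """Composition and noise model of one synthetic colony."""

    colony_id: str = "C1"
    location: str = "LOC1"
    sex: str = "F"
    n_clonal: int = 5
    n_offspring: int = 4
    n_unrelated: int = 2
    somatic_mutation_rate: float = 0.001
    sequencing_error_rate: float = 0.001
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    dropout_enabled: bool = False

    def __post_init__(self) -> None:
        if min(self.n_clonal, self.n_offspring, self.n_unrelated) < 0:
            raise ValueError("polyp counts must be >= 0")
        if self.n_clonal + self.n_offspring + self.n_unrelated < 1:
            raise ValueError("colony must contain at least one polyp")
        for r in (self.somatic_mutation_rate, self.sequencing_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")

    @property
    def n_polyps(self) -> int:
        return self.n_clonal + self.n_offspring + self.n_unrelated


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated colony."""

    colony_id: str
    labels: dict[str, str]  # sample -> clone | offspring | unrelated
    pair_classes: dict[tuple[str, str], str]  # sorted pair -> clonal|family|unrelated
    founder_genotype: np.ndarray
    father_genotype: np.ndarray
    somatic_events: list[dict] = field(default_factory=list)
    error_events: list[dict] = field(default_factory=list)
    dropout_events: list[dict] = field(default_factory=list)

    def expected_type(self, a: str, b: str) -> str:
        """Relationship type a perfect classifier should assign to a pair."""
        cls = self.pair_classes[tuple(sorted((a, b)))]
        return {"clonal": "I", "family": "II", "unrelated": "III"}[cls]


def simulate_population(pm: PopulationModel, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the polymorphic-site table: locus, position, alt-allele frequency.

    Exactly ``round(n_total_sites * fraction_polymorphic)`` sites are
    polymorphic; the remaining assayed sites are invariant and carried only
    through ``n_total_sites``.  Sites are scattered over RAD loci of
    LOCUS_LENGTH bp, so a locus can hold more than one SNP.
    """
    if pm.n_polymorphic < 1:
        raise ValueError("model yields zero polymorphic sites")
    rng = np.random.default_rng(pm.seed) if rng is None else rng
    n_loci = max(1, pm.n_total_sites // LOCUS_LENGTH)
    taken: set[tuple[int, int]] = set()
    while len(taken) < pm.n_polymorphic:
        locus = int(rng.integers(n_loci))
        pos = int(rng.integers(1, LOCUS_LENGTH + 1))
        taken.add((locus, pos))
    sites = sorted(taken)
    freqs = rng.uniform(pm.freq_low, pm.freq_high, size=len(sites))
    return pd.DataFrame(
        {
            "site_id": [f"L{locus}:{pos}" for locus, pos in sites],
            "locus": [f"L{locus}" for locus, _ in sites],
            "pos": [pos for _, pos in sites],
            "freq": freqs,
        }
    )


def _hw_genotype(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One diploid genotype in Hardy-Weinberg proportions."""
    return (
        (rng.random(p.size) < p).astype(np.int16) + (rng.random(p.size) < p).astype(np.int16)
    )


def _natal_freqs(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Colony-of-origin allele frequencies: a Balding-Nichols draw around
    the population frequencies with differentiation ``fst``.  Colonies in
    this system carry distinct allele frequencies at the few polymorphic
    sites (elevated between-colony F_ST), and that differentiation is what
    makes fused unrelated settlers genetically conspicuous."""
    if fst <= 0:
        return p
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b)


def _gamete(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One allele per site by independent Mendelian segregation."""
    return (rng.random(parent.size) < parent / 2.0).astype(np.int16)


def _one_step(g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Move each dosage one step (0->1, 2->1, 1->0 or 2 at random)."""
    out = g.copy()
    out[g == 0] = 1
    out[g == 2] = 1
    het = np.flatnonzero(g == 1)
    out[het] = rng.choice([0, 2], size=het.size).astype(np.int16)
    return out


def simulate_colony(
    freqs: pd.DataFrame, recipe: ColonyRecipe, seed: int, colony_fst: float = 0.10
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Simulate one colony's genotype matrix with full ground truth.

    The founder and the sire of her brood are drawn from the colony's
    natal allele frequencies (sperm dispersal is local, so sires are
    related to the resident lineage's natal stock); each unrelated settler
    is the product of a different natal colony and gets its own
    Balding-Nichols frequency draw.  Somatic mutations and genotype
    miscalls are simulated over the assayed polymorphic sites (the site
    universe of the emitted VCF).
    """
    rng = np.random.default_rng(seed)
    p = freqs["freq"].to_numpy()
    L = p.size

    natal = _natal_freqs(p, colony_fst, rng)
    founder = _hw_genotype(natal, rng)
    father = _hw_genotype(natal, rng)

    ids: list[str] = []
    labels: dict[str, str] = {}
    rows: list[np.ndarray] = []

    clone_ids = [f"{recipe.colony_id}_c{i + 1}" for i in range(recipe.n_clonal)]
    for cid in clone_ids:
        ids.append(cid)
        labels[cid] = "clone"
        rows.append(founder.copy())

    truth = SyntheticTruth(
        colony_id=recipe.colony_id,
        labels=labels,
        pair_classes={},
        founder_genotype=founder,
        father_genotype=father,
    )

    # shared somatic mutations along contiguous runs of the budding order
    if recipe.n_clonal > 0 and recipe.somatic_mutation_rate > 0:
        hit = np.flatnonzero(rng.random(L) < recipe.somatic_mutation_rate)
        for j in hit:
            start = int(rng.integers(recipe.n_clonal))
            length = int(rng.integers(1, recipe.n_clonal + 1))
            members = list(range(start, min(start + length, recipe.n_clonal)))
            mutated = _one_step(founder[j : j + 1], rng)[0]
            for i in members:
                rows[i][j] = mutated
            truth.somatic_events.append(
                {
                    "site_id": str(freqs["site_id"].iloc[j]),
                    "samples": [clone_ids[i] for i in members],
                    "from": int(founder[j]),
                    "to": int(mutated),
                }
            )

    for i in range(recipe.n_offspring):
        oid = f"{recipe.colony_id}_o{i + 1}"
        ids.append(oid)
        labels[oid] = "offspring"
        rows.append(_gamete(founder, rng) + _gamete(father, rng))

    for i in range(recipe.n_unrelated):
        uid = f"{recipe.colony_id}_u{i + 1}"
        ids.append(uid)
        labels[uid] = "unrelated"
        rows.append(_hw_genotype(_natal_freqs(p, colony_fst, rng), rng))

    true_calls = np.stack(rows) if rows else np.zeros((0, L), np.int16)
    calls = true_calls.copy()

    # independent per-call genotype miscalls, one dosage step each
    if recipe.sequencing_error_rate > 0:
        err = rng.random(calls.shape) < recipe.sequencing_error_rate
        for i, j in zip(*np.nonzero(err)):
            old = calls[i, j]
            calls[i, j] = _one_step(calls[i : i + 1, j], rng)[0]
            truth.error_events.append(
                {
                    "sample": ids[i],
                    "site_id": str(freqs["site_id"].iloc[j]),
                    "from": int(old),
                    "to": int(calls[i, j]),
                }
            )

    # read depths; optional allelic dropout on heterozygous calls
    m, k = recipe.depth_mean, recipe.depth_dispersion
    depth = rng.negative_binomial(k, k / (k + m), size=calls.shape).astype(np.int32)
    if recipe.dropout_enabled:
        het = calls == 1
        # per-allele coverage: each haplotype sequenced at half the mean
        a_ref = rng.negative_binomial(k / 2, (k / 2) / (k / 2 + m / 2), size=calls.shape)
        a_alt = rng.negative_binomial(k / 2, (k / 2) / (k / 2 + m / 2), size=calls.shape)
        depth[het] = (a_ref + a_alt)[het].astype(np.int32)
        drop_ref = het & (a_ref == 0) & (a_alt > 0)
        drop_alt = het & (a_alt == 0) & (a_ref > 0)
        for mask, dosage, reads in ((drop_ref, 2, a_alt), (drop_alt, 0, a_ref)):
            for i, j in zip(*np.nonzero(mask)):
                calls[i, j] = dosage
                depth[i, j] = int(reads[i, j])
                truth.dropout_events.append(
                    {"sample": ids[i], "site_id": str(freqs["site_id"].iloc[j]), "kept": dosage}
                )
    calls[depth == 0] = MISSING

    for a, b in combinations(ids, 2):
        la, lb = labels[a], labels[b]
        if "unrelated" in (la, lb):
            cls = "unrelated"
        elif la == lb == "clone":
            cls = "clonal"
        else:
            cls = "family"
        truth.pair_classes[tuple(sorted((a, b)))] = cls

    sample_map = pd.DataFrame(
        {
            "sample": ids,
            "colony": recipe.colony_id,
            "location": recipe.location,
            "sex": recipe.sex,
        }
    ).set_index("sample")
    gm = GenotypeMatrix(
        sample_ids=ids,
        site_ids=list(freqs["site_id"]),
        calls=calls,
        depth=depth,
        sample_map=sample_map,
        total_assayed_sites=int(freqs.attrs.get("n_total_sites", 0)) or L,
        meta={"recipe": recipe.colony_id, "seed": seed},
    )
    return gm, truth


def simulate_dataset(
    pm: PopulationModel, recipes: list[ColonyRecipe], seed: int
) -> tuple[GenotypeMatrix, dict[str, SyntheticTruth], pd.DataFrame]:
    """Simulate colonies sharing one population's allele frequencies.

    All colonies are genotyped at the same polymorphic-site panel, so the
    combined matrix can be sliced by colony or by collecting location.
    """
    rng = np.random.default_rng(seed)
    freqs = simulate_population(pm, rng)
    freqs.attrs["n_total_sites"] = pm.n_total_sites
    gms: list[GenotypeMatrix] = []
    truths: dict[str, SyntheticTruth] = {}
    for recipe in recipes:
        colony_seed = int(rng.integers(2**31 - 1))
        gm, truth = simulate_colony(freqs, recipe, colony_seed, pm.colony_fst)
        gms.append(gm)
        truths[recipe.colony_id] = truth
    combined = GenotypeMatrix(
        sample_ids=[s for g in gms for s in g.sample_ids],
        site_ids=list(freqs["site_id"]),
        calls=np.vstack([g.calls for g in gms]),
        depth=np.vstack([g.depth for g in gms]),
        sample_map=pd.concat([g.sample_map for g in gms]),
        total_assayed_sites=pm.n_total_sites,
        meta={"seed": seed},
    )
    return combined, truths, freqs


def simulate_pair_cohort(
    relationship: str,
    n_pairs: int,
    n_sites: int = 10_000,
    freq_low: float = 0.05,
    freq_high: float = 0.95,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Simulate genotype pairs of known relatedness for kinship calibration.

    All individuals are drawn at ``n_sites`` biallelic SNPs with allele
    frequencies Uniform(freq_low, freq_high).

    * ``"clone"``     — a genotype and an identical copy (kinship 0.5);
    * ``"full_sib"``  — two offspring of the same two parents, each built
      by independent Mendelian segregation (kinship 0.25);
    * ``"unrelated"`` — two independent Hardy-Weinberg draws (kinship 0).
    """
    if relationship not in ("clone", "full_sib", "unrelated"):
        raise ValueError(f"unknown relationship: {relationship}")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        p = rng.uniform(freq_low, freq_high, size=n_sites)
        if relationship == "clone":
            g = _hw_genotype(p, rng)
            pairs.append((g, g.copy()))
        elif relationship == "full_sib":
            mother = _hw_genotype(p, rng)
            father = _hw_genotype(p, rng)
            sib1 = _gamete(mother, rng) + _gamete(father, rng)
            sib2 = _gamete(mother, rng) + _gamete(father, rng)
            pairs.append((sib1, sib2))
        else:
            pairs.append((_hw_genotype(p, rng), _hw_genotype(p, rng)))
    return pairs


def default_recipes() -> list[ColonyRecipe]:
    """The default synthetic study: two locations, colony compositions
    mixing pure-clone colonies, clone+sib colonies and chimeric colonies
    with unrelated settlers."""
    return [
        ColonyRecipe(colony_id="C1", location="LOC1", n_clonal=6, n_offspring=0, n_unrelated=0),
        ColonyRecipe(colony_id="C2", location="LOC1", n_clonal=5, n_offspring=4, n_unrelated=0),
        ColonyRecipe(colony_id="C3", location="LOC1", n_clonal=5, n_offspring=4, n_unrelated=2),
        ColonyRecipe(colony_id="C4", location="LOC1", n_clonal=5, n_offspring=0, n_unrelated=2),
        ColonyRecipe(colony_id="C5", location="LOC2", n_clonal=6, n_offspring=4, n_unrelated=0),
        ColonyRecipe(colony_id="C6", location="LOC2", n_clonal=5, n_offspring=4, n_unrelated=2),
    ]


def emit_vcf(gm: GenotypeMatrix, truths: dict[str, SyntheticTruth], out_dir) -> dict[str, Path]:
    """Write VCF, sample map and ground-truth tables for a simulated dataset."""
    if gm.n_samples == 0:
        raise ValueError("refusing to emit an empty dataset")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "sample_map": out / "sample_map.tsv",
        "truth_pairs": out / "truth_pairs.tsv",
        "truth_labels": out / "truth_labels.tsv",
        "events": out / "events.json",
    }
    write_vcf(gm, paths["vcf"])
    write_sample_map(gm.sample_map.loc[gm.sample_ids], paths["sample_map"])

    pair_rows = []
    label_rows = []
    events = {}
    for cid, truth in truths.items():
        for (a, b), cls in sorted(truth.pair_classes.items()):
            pair_rows.append(
                {
                    "colony": cid,
                    "sample_a": a,
                    "sample_b": b,
                    "true_class": cls,
                    "expected_type": truth.expected_type(a, b),
                }
            )
        for s, lab in truth.labels.items():
            label_rows.append({"colony": cid, "sample": s, "label": lab})
        events[cid] = {
            "somatic": truth.somatic_events,
            "errors": truth.error_events,
            "dropout": truth.dropout_events,
        }
    pd.DataFrame(pair_rows).to_csv(paths["truth_pairs"], sep="\t", index=False)
    pd.DataFrame(label_rows).to_csv(paths["truth_labels"], sep="\t", index=False)
    paths["events"].write_text(json.dumps(events, indent=1, sort_keys=True))
    return paths
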