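"""Per-SNP allelic segregation classes within a colony.

Each within-colony polymorphic SNP is assigned to one of three classes,
relative to the colony's main clonal lineage (the largest set of polyps
connected by Type I relationship calls):

* A (clonal noise)   — the only deviation from the lineage consensus is a
  single repeated configuration one mutational/error step away
  (sequencing error when carried by one polyp, somatic mutation when
  shared);
* B (Mendelian)      — genotypes explicable by segregation of alleles
  already present in the main lineage;
* C (foreign allele) — some polyp carries an allele absent from the
  lineage at that site; mismatching at both alleles (the alternate
  homozygote) is the fusion signal.

"One mutational/error step" means one dosage unit for a diploid biallelic
genotype (0<->1 or 1<->2); 0<->2 is two steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

CLASS_A = "A_clonal_noise"
CLASS_B = "B_mendelian"
CLASS_C = "C_foreign"


@dataclass
class MainLineage:
    members: list[str]
    consensus: np.ndarray  # per-site consensus dosage (MISSING if none)
    flagged: bool = False  # True when no Type I pair existed


@dataclass
class SNPClassification:
    site_id: str
    colony_id: str
    snp_class: str
    foreign_detail: str = "none"  # none | one_allele | both_alleles
    typeI_subclass: str = "not_applicable"

    def __post_init__(self) -> None:
        if (self.foreign_detail != "none") != (self.snp_class == CLASS_C):
            raise ValueError("foreign_detail set iff class C")


def _components(nodes: list[str], edges: set[frozenset]) -> list[set[str]]:
    seen: set[str] = set()
    comps = []
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    for n in nodes:
        if n in seen:
            continue
        stack, comp = [n], {n}
        seen.add(n)
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in comp:
                    comp.add(nb)
                    seen.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps


def _consensus_genotypes(calls: np.ndarray) -> np.ndarray:
    """Per-site modal dosage; ties resolved toward the genotype one step
    from fewer members (minimal total dosage distance), then the smaller
    dosage.  All-missing sites get MISSING."""
    n_sites = calls.shape[1]
    out = np.full(n_sites, MISSING, dtype=np.int16)
    for j in range(n_sites):
        col = calls[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            continue
        values, counts = np.unique(obs, return_counts=True)
        best = counts.max()
        tied = values[counts == best]
        if tied.size == 1:
            out[j] = tied[0]
        else:
            cost = [(int(np.abs(obs - g).sum()), int(g)) for g in tied]
            out[j] = min(cost)[1]
    return out


def main_lineage(panel: GenotypeMatrix, relationship_calls: pd.DataFrame) -> MainLineage:
    """Largest set of polyps connected by Type I calls, plus its consensus.

    Ties between equal-sized components go to the one containing the
    lexicographically smallest sample id.  If the colony has no Type I
    pair at all, the lineage degenerates to the single polyp with the
    smallest mean distance to the others and is flagged.
    """
    nodes = list(panel.sample_ids)
    t1 = relationship_calls[relationship_calls["type"] == "I"]
    edges = {frozenset((a, b)) for a, b in zip(t1["sample_a"], t1["sample_b"])}
    flagged = False
    if edges:
        comps = _components(nodes, edges)
        # singletons with no Type I edge are not lineage candidates
        touched = set().union(*edges)
        comps = [c for c in comps if c & touched]
        comps.sort(key=lambda c: (-len(c), min(c)))
        members = sorted(comps[0], key=nodes.index)
    else:
        flagged = True
        mean_d = (
            pd.concat(
                [
                    relationship_calls[["sample_a", "d"]].rename(columns={"sample_a": "s"}),
                    relationship_calls[["sample_b", "d"]].rename(columns={"sample_b": "s"}),
                ]
            )
            .groupby("s")["d"]
            .mean()
        )
        members = [min(mean_d.index, key=lambda s: (mean_d[s], s))]
    rows = [nodes.index(s) for s in members]
    consensus = _consensus_genotypes(panel.calls[rows, :])
    return MainLineage(members=members, consensus=consensus, flagged=flagged)


def _alleles(dosage: int) -> set[int]:
    return {0: {0}, 1: {0, 1}, 2: {1}}[dosage]


def classify_snp(
    column: np.ndarray,
    lineage_rows: list[int],
    consensus_g: int,
    site_id: str = "",
    colony_id: str = "",
) -> SNPClassification:
    """Classify one within-colony polymorphic site (see module docstring).

    ``column`` holds the colony's dosages at the site; ``lineage_rows``
    index the main-lineage members within it.
    """
    obs_mask = column != MISSING
    obs = column[obs_mask]
    polymorphic = obs.size > 0 and (
        (obs == 1).any() or ((obs == 0).any() and (obs == 2).any())
    )
    if not polymorphic:
        raise ValueError(f"site {site_id} is monomorphic; classify polymorphic sites only")
    if consensus_g == MISSING:
        raise ValueError(f"site {site_id}: consensus undefined")

    lineage_vals = [int(column[i]) for i in lineage_rows if column[i] != MISSING]
    lineage_alleles: set[int] = set()
    for g in lineage_vals:
        lineage_alleles |= _alleles(g)

    foreign = [int(g) for g in obs if not _alleles(int(g)) <= lineage_alleles]
    if foreign:
        cons_alleles = _alleles(int(consensus_g))
        both = any(
            consensus_g in (0, 2) and g == 2 - consensus_g for g in foreign
        )
        detail = "both_alleles" if both else "one_allele"
        if not both and not any(_alleles(g) & cons_alleles for g in foreign):
            detail = "both_alleles"  # shares no allele with consensus at all
        return SNPClassification(site_id, colony_id, CLASS_C, detail)

    deviants = [int(g) for g in obs if g != consensus_g]
    configs = sorted(set(deviants))
    if len(configs) == 1 and abs(configs[0] - int(consensus_g)) == 1:
        return SNPClassification(site_id, colony_id, CLASS_A)
    return SNPClassification(site_id, colony_id, CLASS_B)


def classify_colony(
    panel: GenotypeMatrix, relationship_calls: pd.DataFrame
) -> tuple[pd.DataFrame, MainLineage]:
    """Classify every site of a colony panel; returns table + lineage."""
    lineage = main_lineage(panel, relationship_calls)
    rows = [panel.sample_ids.index(s) for s in lineage.members]
    colony_id = str(panel.meta.get("colony_id", ""))
    records = []
    for j, site in enumerate(panel.site_ids):
        cls = classify_snp(panel.calls[:, j], rows, int(lineage.consensus[j]), site, colony_id)
        records.append(
            {
                "colony": colony_id,
                "site_id": site,
                "snp_class": cls.snp_class,
                "foreign_detail": cls.foreign_detail,
            }
        )
    return pd.DataFrame(records), lineage


def typeI_breakdown(panel: GenotypeMatrix, lineage: MainLineage) -> dict:
    """Break down sites polymorphic within the main clonal lineage.

    singleton          — one deviant configuration carried by exactly one
                         polyp, one step from the consensus (one-off
                         sequencing error);
    repeated_one_step  — exactly two configurations one step apart, each
                         carried by at least two polyps (shared somatic
                         mutation);
    unexplained        — anything else (more than two configurations or a
                         deviation of more than one step).
    """
    rows = [panel.sample_ids.index(s) for s in lineage.members]
    counts = {"singleton": 0, "repeated_one_step": 0, "unexplained": 0}
    for j in range(panel.n_sites):
        col = panel.calls[rows, j]
        obs = col[col != MISSING]
        values, n = np.unique(obs, return_counts=True)
        if values.size < 2:
            continue  # not polymorphic within the lineage
        if values.size == 2 and abs(int(values[0]) - int(values[1])) == 1:
            if n.min() == 1:
                counts["singleton"] += 1
            else:
                counts["repeated_one_step"] += 1
        else:
            counts["unexplained"] += 1
    total = sum(counts.values())
    fractions = {k: (v / total if total else np.nan) for k, v in counts.items()}
    return {"counts": counts, "fractions": fractions, "n_sites": total}


def dropout_diagnostic(panel: GenotypeMatrix, classifications: pd.DataFrame) -> dict:
    """Compare read-depth distributions at alternate-homozygote sites vs rest.

    Allelic dropout (loss of one allele of a true heterozygote) would make
    the fusion-signal sites — those where a polyp is the opposite
    homozygote — systematically shallower.  Per-site mean colony depth is
    compared with a Welch two-sample t-test and a two-sided Mann-Whitney U
    (exact below 25 observations, normal approximation with tie correction
    above).
    """
    flagged_sites = set(
        classifications.loc[classifications["foreign_detail"] == "both_alleles", "site_id"]
    )
    site_mean_depth = panel.depth.mean(axis=0)
    in_group = np.array([s in flagged_sites for s in panel.site_ids])
    a = site_mean_depth[in_group]
    b = site_mean_depth[~in_group]

    bins = np.histogram_bin_edges(site_mean_depth, bins=20)
    report: dict = {
        "n_alt_hom_sites": int(a.size),
        "n_other_sites": int(b.size),
        "hist_bins": bins.tolist(),
        "hist_alt_hom": np.histogram(a, bins=bins)[0].tolist(),
        "hist_other": np.histogram(b, bins=bins)[0].tolist(),
    }
    if a.size < 2 or b.size < 2:
        report["testable"] = False
        return report
    report["testable"] = True

    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        # identical constant groups: no evidence of any difference
        report["welch"] = {"t": 0.0, "df": float(a.size + b.size - 2), "p_value": 1.0}
    else:
        t = stats.ttest_ind(a, b, equal_var=False)
        report["welch"] = {"t": float(t.statistic), "df": float(t.df), "p_value": float(t.pvalue)}
    method = "exact" if (a.size + b.size) < 25 and not _has_ties(a, b) else "asymptotic"
    u = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    report["mannwhitney"] = {"U": float(u.statistic), "p_value": float(u.pvalue), "method": method}
    return report


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size
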