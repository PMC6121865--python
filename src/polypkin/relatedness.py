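"""Pairwise kinship (KING-robust) and IBD-state probabilities (moments).

KING-robust estimates the kinship coefficient phi for a pair (i, j) from
shared biallelic SNPs without requiring population allele frequencies:

    phi = (N_het,het - 2 * N_opp_hom) / (N_het(i) + N_het(j))

where N_het,het counts sites with both samples heterozygous, N_opp_hom
counts opposite-homozygote sites (dosages 0/2 or 2/0), and N_het(i),
N_het(j) count each sample's heterozygous calls over the shared sites.
Expected values: 0.5 for identical genotypes (clones), 0.25 for
parent-offspring or full sibs, 0 for unrelated pairs (negative estimates
are interpreted as 0).

IBD-state probabilities Z0/Z1/Z2 (sharing 0, 1 or 2 alleles identical by
descent at a random SNP) are estimated by the PLINK-style method of
moments: observed identity-by-state counts are equated to their
expectations given sample allele frequencies and solved sequentially
(Z0 from IBS0, Z1 from the IBS1 residual, Z2 as the complement), then
bounded to [0, 1] and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, FilterConfig, GenotypeMatrix, population_panel


@dataclass
class KinshipRecord:
    sample_a: str
    sample_b: str
    phi: float  # raw estimate (may be negative or NaN)
    phi_interpreted: float  # clamped at 0 for interpretation
    z0: float
    z1: float
    z2: float
    n_sites: int
    scope: str = ""
    flagged: bool = False


def king_robust_phi(gi: np.ndarray, gj: np.ndarray) -> tuple[float, dict]:
    """KING-robust kinship for one pair of dosage vectors.

    Returns (phi, counts); phi is NaN (flagged via counts["defined"])
    when neither sample is heterozygous over the shared sites.
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    shared = (gi != MISSING) & (gj != MISSING)
    a, b = gi[shared], gj[shared]
    n_hethet = int(((a == 1) & (b == 1)).sum())
    n_opp = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    n_het_i = int((a == 1).sum())
    n_het_j = int((b == 1).sum())
    denom = n_het_i + n_het_j
    counts = {
        "n_shared": int(shared.sum()),
        "n_hethet": n_hethet,
        "n_opp_hom": n_opp,
        "n_het_i": n_het_i,
        "n_het_j": n_het_j,
        "defined": denom > 0,
    }
    phi = (n_hethet - 2.0 * n_opp) / denom if denom > 0 else np.nan
    return phi, counts


def estimate_allele_freqs(panel: GenotypeMatrix) -> pd.DataFrame:
    """Per-site alternate-allele frequency and allele count from a panel."""
    valid = panel.calls != MISSING
    alt = np.where(valid, panel.calls, 0).sum(axis=0)
    n_alleles = 2 * valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return pd.DataFrame(
        {"site_id": panel.site_ids, "freq": freq, "alt_count": alt, "n_alleles": n_alleles}
    )


def _falling(x: np.ndarray, k: int) -> np.ndarray:
    out = np.ones_like(x, dtype=np.float64)
    for i in range(k):
        out *= x - i
    return out


def _ibs_expectations(
    alt: np.ndarray, n_alleles: np.ndarray, bias_adjust: bool
) -> dict[str, np.ndarray]:
    """Per-site expected IBS-state probabilities under each IBD state.

    With ``bias_adjust`` the allele-frequency monomials (p^2 q^2, p^3 q,
    ...) are replaced by their unbiased falling-factorial estimators from
    the sample allele counts, the standard method-of-moments small-sample
    adjustment; otherwise plug-in frequencies are used.
    """
    X = alt.astype(np.float64)
    A = n_alleles.astype(np.float64)
    Y = A - X
    if bias_adjust and np.all(A >= 4):

        def mono(i: int, j: int) -> np.ndarray:
            return _falling(X, i) * _falling(Y, j) / _falling(A, i + j)

    else:
        p = X / A
        q = 1.0 - p

        def mono(i: int, j: int) -> np.ndarray:
            return p**i * q**j

    return {
        "ibs0_z0": 2.0 * mono(2, 2),
        "ibs1_z0": 4.0 * mono(3, 1) + 4.0 * mono(1, 3),
        "ibs1_z1": 2.0 * mono(2, 1) + 2.0 * mono(1, 2),
    }


def ibd_moments(
    gi: np.ndarray,
    gj: np.ndarray,
    freqs: pd.DataFrame,
    bias_adjust: bool = True,
) -> tuple[tuple[float, float, float], dict]:
    """Method-of-moments (Z0, Z1, Z2) for one pair given allele frequencies.

    ``freqs`` must align with the genotype vectors (one row per site, as
    produced by :func:`estimate_allele_freqs` on the same panel).  Sites
    monomorphic in the frequency source or missing in either sample are
    excluded.  Returns the bounded, renormalized Z vector plus counts.
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    alt = freqs["alt_count"].to_numpy()
    n_alleles = freqs["n_alleles"].to_numpy()
    usable = (
        (gi != MISSING)
        & (gj != MISSING)
        & (n_alleles > 0)
        & (alt > 0)
        & (alt < n_alleles)
    )
    info = {"n_sites": int(usable.sum()), "defined": True}
    if not usable.any():
        info["defined"] = False
        return (np.nan, np.nan, np.nan), info

    a, b = gi[usable], gj[usable]
    ibs = 2 - np.abs(a - b)
    n_ibs0 = float((ibs == 0).sum())
    n_ibs1 = float((ibs == 1).sum())
    exp = _ibs_expectations(alt[usable], n_alleles[usable], bias_adjust)
    e0 = float(exp["ibs0_z0"].sum())
    e1_z0 = float(exp["ibs1_z0"].sum())
    e1_z1 = float(exp["ibs1_z1"].sum())
    if e0 <= 0 or e1_z1 <= 0:
        info["defined"] = False
        return (np.nan, np.nan, np.nan), info

    z0 = n_ibs0 / e0
    z1 = (n_ibs1 - z0 * e1_z0) / e1_z1
    z2 = 1.0 - z0 - z1
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    total = z.sum()
    z = z / total if total > 0 else np.array([np.nan] * 3)
    return (float(z[0]), float(z[1]), float(z[2])), info


def relatedness_report(
    gm: GenotypeMatrix,
    location_id: str,
    cfg: FilterConfig | None = None,
    min_shared_sites: int = 50,
    bias_adjust: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Kinship and IBD for all polyp pairs at a collecting location.

    Runs on the location-level one-SNP-per-locus panel; allele frequencies
    are estimated from all samples at the location.  Pairs sharing fewer
    than ``min_shared_sites`` usable sites are flagged.  The summary holds
    within-/between-colony means (raw and clamped-at-zero) and a Welch
    t-test comparing within vs between phi.
    """
    if cfg is None:
        cfg = FilterConfig(min_presence_fraction=0.5, one_snp_per_locus=True)
    panel = population_panel(gm, location_id, cfg)
    if panel.n_samples < 2:
        raise ValueError(f"location {location_id} has fewer than 2 samples")
    freqs = estimate_allele_freqs(panel)
    colony = gm.sample_map.loc[:, "colony"]
    records = []
    for i, j in combinations(range(panel.n_samples), 2):
        sa, sb = panel.sample_ids[i], panel.sample_ids[j]
        phi, counts = king_robust_phi(panel.calls[i], panel.calls[j])
        (z0, z1, z2), info = ibd_moments(panel.calls[i], panel.calls[j], freqs, bias_adjust)
        flagged = (
            not counts["defined"]
            or not info["defined"]
            or counts["n_shared"] < min_shared_sites
        )
        records.append(
            KinshipRecord(
                sample_a=sa,
                sample_b=sb,
                phi=phi,
                phi_interpreted=max(phi, 0.0) if np.isfinite(phi) else np.nan,
                z0=z0,
                z1=z1,
                z2=z2,
                n_sites=counts["n_shared"],
                scope="within_colony" if colony[sa] == colony[sb] else "between_colony",
                flagged=flagged,
            )
        )
    table = pd.DataFrame(
        [
            {
                "sample_a": r.sample_a,
                "sample_b": r.sample_b,
                "colony_a": colony[r.sample_a],
                "colony_b": colony[r.sample_b],
                "scope": r.scope,
                "n_sites": r.n_sites,
                "phi": r.phi,
                "phi_interpreted": r.phi_interpreted,
                "z0": r.z0,
                "z1": r.z1,
                "z2": r.z2,
                "flagged": r.flagged,
            }
            for r in records
        ]
    )
    within = table.loc[table["scope"] == "within_colony", "phi"].dropna()
    between = table.loc[table["scope"] == "between_colony", "phi"].dropna()
    summary: dict = {
        "location": location_id,
        "n_pairs": len(table),
        "mean_phi_within": float(within.mean()) if len(within) else None,
        "mean_phi_between": float(between.mean()) if len(between) else None,
        "mean_phi_within_interpreted": float(within.clip(lower=0).mean()) if len(within) else None,
        "mean_phi_between_interpreted": float(between.clip(lower=0).mean()) if len(between) else None,
        "single_colony": len(between) == 0,
    }
    if len(within) >= 2 and len(between) >= 2:
        t = stats.ttest_ind(within, between, equal_var=False)
        summary["welch"] = {"t": float(t.statistic), "df": float(t.df), "p_value": float(t.pvalue)}
    return table, summary
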