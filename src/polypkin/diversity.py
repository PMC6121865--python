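"""Per-location diversity statistics and between-colony differentiation.

Nucleotide diversity pi is averaged over ALL assayed sites, variant and
invariant: the per-site unbiased heterozygosity (n/(n-1)) * 2 p (1-p) is
summed over polymorphic sites and divided by the total assayed-site
count, which the genotype matrix carries explicitly because VCFs do not
record invariant sites.

F_IS is computed ratio-of-sums (total observed heterozygote count over
total small-sample-corrected expected count), which stays stable when
per-site expected heterozygosity is tiny, as in this low-diversity
system.  Between-colony differentiation uses the Weir & Cockerham (1984)
theta estimator with the a/(a+b+c) variance components, ratio-of-sums
across sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, FilterConfig, GenotypeMatrix, population_panel


@dataclass
class DiversityStats:
    location_id: str
    n_polyps: int
    n_colonies: int
    n_snps: int
    pct_polymorphic: float
    pi: float
    fis: float


def _site_freq_het(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n diploids, alt freq, observed het count), missing-aware."""
    valid = calls != MISSING
    n = valid.sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
    het = ((calls == 1) & valid).sum(axis=0)
    return n, p, het


def nucleotide_diversity(panel: GenotypeMatrix, total_assayed_sites: int | None = None) -> float:
    """pi over all assayed sites using the unbiased per-site estimator.

    per site: pi_site = (n/(n-1)) * 2 p (1-p) over n = 2 * (diploids with
    a call) allele copies; pi = sum(pi_site) / total_assayed_sites.
    """
    total = panel.total_assayed_sites if total_assayed_sites is None else total_assayed_sites
    if total <= 0:
        raise ValueError("total_assayed_sites must be positive")
    if total < panel.n_sites:
        raise ValueError("total_assayed_sites < panel site count")
    n_dip, p, _ = _site_freq_het(panel.calls)
    n = 2.0 * n_dip
    usable = n >= 2
    with np.errstate(invalid="ignore"):
        pi_site = np.where(usable, (n / np.maximum(n - 1.0, 1.0)) * 2.0 * p * (1.0 - p), 0.0)
    return float(np.nansum(pi_site) / total)


def fis(panel: GenotypeMatrix) -> float:
    """Inbreeding coefficient F_IS = 1 - sum(H_obs) / sum(H_exp).

    Expected heterozygote counts use Nei's small-sample correction
    2n/(2n-1); sites with zero expected heterozygosity are excluded.
    Returns NaN (with a warning) when no polymorphic site remains.
    """
    if panel.n_samples < 2:
        raise ValueError("F_IS needs at least 2 diploids")
    n_dip, p, het = _site_freq_het(panel.calls)
    with np.errstate(invalid="ignore"):
        h_exp = n_dip * 2.0 * p * (1.0 - p) * (2.0 * n_dip / np.maximum(2.0 * n_dip - 1.0, 1.0))
    usable = (n_dip >= 2) & (np.nan_to_num(h_exp) > 0)
    if not usable.any():
        warnings.warn("no polymorphic sites; F_IS undefined", stacklevel=2)
        return float("nan")
    return float(1.0 - het[usable].sum() / h_exp[usable].sum())


def wc_theta_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray, n2: np.ndarray, p2: np.ndarray, h2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components a, b, c for
    two populations with sample sizes n (diploids), alt frequencies p and
    heterozygote frequencies h."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0)) * (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def _colony_site_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, p, het = _site_freq_het(calls)
    with np.errstate(invalid="ignore"):
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n.astype(float), p, h


def pairwise_fst(gm: GenotypeMatrix, location_id: str, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Between-colony pairwise W&C theta matrix for one location.

    Colonies with a single polyp are excluded with a warning (recorded in
    ``result.attrs["excluded_colonies"]``).  Theta is the ratio of summed
    ``a`` components to summed ``a+b+c`` over all sites genotyped in at
    least two diploids of both colonies.
    """
    if cfg is None:
        cfg = FilterConfig(min_presence_fraction=0.5, one_snp_per_locus=True)
    panel = population_panel(gm, location_id, cfg)
    colony = gm.sample_map.loc[:, "colony"]
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(panel.sample_ids):
        groups.setdefault(str(colony[s]), []).append(i)
    excluded = sorted(c for c, rows in groups.items() if len(rows) < 2)
    if excluded:
        warnings.warn(f"excluding single-polyp colonies: {excluded}", stacklevel=2)
    kept = sorted(c for c in groups if c not in set(excluded))
    if len(kept) < 2:
        raise ValueError("need at least 2 colonies with >=2 polyps")

    stats_by_colony = {c: _colony_site_stats(panel.calls[groups[c], :]) for c in kept}
    mat = pd.DataFrame(0.0, index=kept, columns=kept)
    for i, c1 in enumerate(kept):
        for c2 in kept[i + 1 :]:
            n1, p1, h1 = stats_by_colony[c1]
            n2, p2, h2 = stats_by_colony[c2]
            ok = (n1 >= 2) & (n2 >= 2)
            a, b, c = wc_theta_components(n1[ok], p1[ok], h1[ok], n2[ok], p2[ok], h2[ok])
            denom = np.nansum(a + b + c)
            theta = float(np.nansum(a) / denom) if denom != 0 else np.nan
            mat.loc[c1, c2] = mat.loc[c2, c1] = theta
    mat.attrs["excluded_colonies"] = excluded
    mat.attrs["estimator"] = "Weir & Cockerham (1984) theta, ratio-of-sums"
    return mat


def diversity_table(gm: GenotypeMatrix, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Per-location summary: polyps, colonies, SNPs, %polymorphic, pi, F_IS.

    Defaults keep every SNP (no one-per-locus thinning): diversity
    statistics average over sites, so independence is not required and
    thinning would understate the polymorphic fraction.
    """
    if cfg is None:
        cfg = FilterConfig(min_presence_fraction=0.5, one_snp_per_locus=False)
    rows = []
    for loc in gm.locations():
        panel = population_panel(gm, loc, cfg)
        n_colonies = len({gm.colony_of(s) for s in panel.sample_ids})
        if panel.n_sites and panel.n_samples >= 2:
            pi = nucleotide_diversity(panel)
            f = fis(panel)
        else:
            pi, f = 0.0, np.nan
        rows.append(
            {
                "location": loc,
                "n_polyps": panel.n_samples,
                "n_colonies": n_colonies,
                "n_snps": panel.n_sites,
                "pct_polymorphic": 100.0 * panel.n_sites / panel.total_assayed_sites,
                "pi": pi,
                "fis": f,
            }
        )
    return pd.DataFrame(rows)
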