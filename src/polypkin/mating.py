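"""Simulated within-colony mating nulls and Type I/II/III classification.

A colony's observed polyps serve as the mating pool.  Simulated offspring
are produced by drawing two parents uniformly at random (the same polyp
twice only in selfing mode) and one gamete per parent by independent
Mendelian segregation at every site.  The multiset of pairwise distances
among simulated offspring is the null against which observed within-colony
distances are classified:

* Type I  — observed distance below the null (clone-mates, differing only
  by error/somatic mutation);
* Type II — within the null range (compatible with sexual reproduction
  inside the colony, e.g. siblings/offspring);
* Type III — above the null (more divergent than within-colony sex could
  produce; fusion of unrelated polyps).

Colonies are single-sex, so within-colony selfing is not biologically
feasible; selfing-mode nulls are produced for visual contrast only and
classification bounds always come from the outcrossing null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distances import mismatch_counts
from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class SimulatedNull:
    """Null distribution of offspring pairwise distances for one colony."""

    mode: str  # "selfing" | "outcrossing"
    n_offspring: int
    distances: np.ndarray
    lower_bound: int
    upper_bound: int
    seed: int
    gamete_source: str = "pool"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError("lower_bound > upper_bound")


def simulate_offspring(
    panel: GenotypeMatrix,
    mode: str = "outcrossing",
    n_offspring: int = 1000,
    seed: int = 0,
    bounds: str | tuple[float, float] = "minmax",
    gamete_source: str = "pool",
) -> SimulatedNull:
    """Simulate offspring of hypothetical within-colony sex; null distances.

    ``gamete_source`` selects how outcrossed gametes are formed:

    * ``"pool"`` (default) — each gamete allele is drawn independently per
      site from the colony's allele frequencies, the Hardy-Weinberg
      resampling scheme of the clonal-discrimination literature.  Sites
      are independent, so the null reflects the amount of variation the
      colony's allele pool can generate, not the linkage of whole parental
      genomes.
    * ``"parents"`` — two distinct parent polyps are drawn uniformly and
      one gamete per parent is produced by Mendelian segregation at every
      site; parental across-site linkage is preserved, widening the null.

    Selfing mode always segregates both gametes from one uniformly drawn
    polyp (that is what selfing means); it is emitted for visual contrast
    only.  ``bounds`` is either ``"minmax"`` (empirical min/max of the
    null, the most conservative reading of "within the range expected")
    or a ``(low, high)`` quantile pair such as ``(0.025, 0.975)``.
    """
    if mode not in ("selfing", "outcrossing"):
        raise ValueError(f"unknown mode: {mode}")
    if gamete_source not in ("pool", "parents"):
        raise ValueError(f"unknown gamete_source: {gamete_source}")
    if n_offspring < 2:
        raise ValueError("need at least 2 simulated offspring")
    k = panel.n_samples
    if k < 1 or (mode == "outcrossing" and k < 2):
        raise ValueError("outcrossing requires at least 2 polyps in the colony")
    if (panel.calls == MISSING).any():
        raise ValueError("mating simulation requires a complete (no-missing) panel")

    rng = np.random.default_rng(seed)
    parents = panel.calls.astype(np.float64)
    shape = (n_offspring, panel.n_sites)
    if mode == "selfing":
        idx = rng.integers(k, size=n_offspring)
        g1 = (rng.random(shape) < parents[idx] / 2.0).astype(np.int16)
        g2 = (rng.random(shape) < parents[idx] / 2.0).astype(np.int16)
    elif gamete_source == "pool":
        p = parents.mean(axis=0) / 2.0  # colony alternate-allele frequency
        g1 = (rng.random(shape) < p).astype(np.int16)
        g2 = (rng.random(shape) < p).astype(np.int16)
    else:
        idx1 = rng.integers(k, size=n_offspring)
        shift = rng.integers(1, k, size=n_offspring)
        idx2 = (idx1 + shift) % k
        g1 = (rng.random(shape) < parents[idx1] / 2.0).astype(np.int16)
        g2 = (rng.random(shape) < parents[idx2] / 2.0).astype(np.int16)
    offspring = g1 + g2

    d, _ = mismatch_counts(offspring)
    iu = np.triu_indices(n_offspring, k=1)
    dist = d[iu]

    if bounds == "minmax":
        lo, hi = int(dist.min()), int(dist.max())
    else:
        qlo, qhi = bounds
        lo = int(np.floor(np.quantile(dist, qlo)))
        hi = int(np.ceil(np.quantile(dist, qhi)))
    return SimulatedNull(
        mode=mode,
        n_offspring=n_offspring,
        distances=np.sort(dist),
        lower_bound=lo,
        upper_bound=hi,
        seed=seed,
        gamete_source=gamete_source,
    )


def classification_null(
    panel: GenotypeMatrix,
    n_offspring: int = 1000,
    seed: int = 0,
    bounds: str | tuple[float, float] = "minmax",
) -> SimulatedNull:
    """Outcrossing null with composite bounds for Type classification.

    Within-colony sexual reproduction spans two extremes of mating
    structure: repeated crossing of one parental pair (brood-mates — the
    most similar offspring a colony can produce) and random union of
    gametes from the colony allele pool (the most novel).  The lower
    classification bound is therefore taken from the parent-pair null's
    minimum and the upper bound from the gamete-pool null's maximum:
    Type I pairs are closer than even brood-mates could be, Type III
    pairs more divergent than the colony's allele pool can generate.
    The returned null carries the gamete-pool distance multiset (the
    conventional resampling null, used for plotting).
    """
    pool = simulate_offspring(panel, "outcrossing", n_offspring, seed, bounds, "pool")
    brood = simulate_offspring(panel, "outcrossing", n_offspring, seed + 1, bounds, "parents")
    return SimulatedNull(
        mode="outcrossing",
        n_offspring=n_offspring,
        distances=pool.distances,
        lower_bound=min(brood.lower_bound, pool.lower_bound),
        upper_bound=pool.upper_bound,
        seed=seed,
        gamete_source="composite",
    )


def classify_pairs(observed: pd.DataFrame, null: SimulatedNull) -> pd.DataFrame:
    """Label every observed pair Type I, II or III against the null bounds."""
    if null.distances.size == 0:
        raise ValueError("empty null distribution")
    out = observed.copy()
    d = out["d"].to_numpy()
    types = np.where(d < null.lower_bound, "I", np.where(d > null.upper_bound, "III", "II"))
    out["type"] = types
    out["null_lower"] = null.lower_bound
    out["null_upper"] = null.upper_bound
    return out


def colony_type_summary(calls_by_colony: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, dict]:
    """Per-colony presence of each relationship type plus an association test.

    Tests whether colonies possessing Type II comparisons also tend to
    possess Type III comparisons: two-sided Fisher's exact test on the
    2x2 presence table.  A table with a zero margin carries no information
    about association; it is returned with p = 1 and flagged degenerate.
    """
    if len(calls_by_colony) < 2:
        raise ValueError("need at least 2 colonies")
    rows = []
    for colony, calls in sorted(calls_by_colony.items()):
        present = set(calls["type"])
        rows.append(
            {
                "colony": colony,
                "n_pairs": len(calls),
                "has_type_I": "I" in present,
                "has_type_II": "II" in present,
                "has_type_III": "III" in present,
            }
        )
    presence = pd.DataFrame(rows)
    has2 = presence["has_type_II"].to_numpy()
    has3 = presence["has_type_III"].to_numpy()
    table = np.array(
        [
            [int((has2 & has3).sum()), int((has2 & ~has3).sum())],
            [int((~has2 & has3).sum()), int((~has2 & ~has3).sum())],
        ]
    )
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if degenerate:
        p = 1.0
        odds = np.nan
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    test = {
        "table": table.tolist(),
        "odds_ratio": float(odds) if np.isfinite(np.float64(odds)) else None,
        "p_value": float(p),
        "degenerate": bool(degenerate),
    }
    return presence, test
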