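"""k-means clustering of distance proportions and sequencing-error baselines.

The proportions of differing sites from all within-colony comparisons are
clustered in one dimension to ask, independently of the mating-simulation
classification, how many distinct relationship classes the distance data
support.  Cluster-count selection takes a majority vote of three standard
indices (elbow on the within-cluster SS curve, mean silhouette,
Calinski-Harabasz).  A Phred-derived per-base error probability
(10^(-Q/10)) provides the expected noise floor for clone-mate distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

#: Mean +/- SD of three published empirical HiSeq 2000/2500 substitution
#: error-rate studies, used as the reference baseline.
PUBLISHED_ERROR_RATE = 0.00191
PUBLISHED_ERROR_SD = 0.00027


@dataclass
class ErrorRateEstimate:
    q: float
    p_error: float
    published_reference_rate: float = PUBLISHED_ERROR_RATE
    published_reference_sd: float = PUBLISHED_ERROR_SD


def phred_error(q: float) -> ErrorRateEstimate:
    """Probability a base call is incorrect, from a mean Phred score."""
    if q <= 0:
        raise ValueError("Phred score must be positive")
    return ErrorRateEstimate(q=float(q), p_error=float(10.0 ** (-q / 10.0)))


def kmeans_distances(
    proportions: np.ndarray, k: int, seed: int = 0, n_restarts: int = 25
) -> dict:
    """Lloyd's k-means (k-means++ init, best of n_restarts) on 1-D data.

    Returns assignments, centers, within-cluster SS and the fraction of
    total variance explained (between-cluster SS / total SS).
    """
    x = np.asarray(proportions, dtype=float).reshape(-1, 1)
    if k > x.shape[0]:
        raise ValueError("k exceeds number of points")
    if np.unique(x).size < k:
        raise ValueError("fewer distinct values than clusters")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(x)
    tss = float(((x - x.mean()) ** 2).sum())
    wss = float(km.inertia_)
    return {
        "k": k,
        "assignments": km.labels_.astype(int),
        "centers": np.sort(km.cluster_centers_.ravel()),
        "wss": wss,
        "variance_explained": (1.0 - wss / tss) if tss > 0 else 0.0,
    }


def _elbow_vote(ks: list[int], wss: list[float]) -> int:
    """k with the largest drop-off in marginal WSS reduction (discrete
    second difference); for 1-D curves this is the classic elbow."""
    if len(ks) < 3:
        return ks[0]
    curvature = [wss[i - 1] - 2 * wss[i] + wss[i + 1] for i in range(1, len(ks) - 1)]
    return ks[1 + int(np.argmax(curvature))]


def select_k(
    proportions: np.ndarray, k_range: tuple[int, int] = (2, 6), seed: int = 0, n_restarts: int = 25
) -> dict:
    """Majority vote over elbow, silhouette and Calinski-Harabasz.

    Ties go to the smaller k.  Constant data are flagged degenerate with
    chosen_k = 1.
    """
    x = np.asarray(proportions, dtype=float).reshape(-1, 1)
    if np.unique(x).size == 1:
        return {"chosen_k": 1, "degenerate": True, "votes": {}}
    k_min, k_max = k_range
    k_max = min(k_max, np.unique(x).size, x.shape[0] - 1)
    ks = list(range(max(2, k_min), k_max + 1))
    if not ks:
        return {"chosen_k": 1, "degenerate": True, "votes": {}}

    wss_curve_ks = [1] + ks
    wss = []
    sil = {}
    ch = {}
    for k in wss_curve_ks:
        if k == 1:
            wss.append(float(((x - x.mean()) ** 2).sum()))
            continue
        res = kmeans_distances(x.ravel(), k, seed=seed, n_restarts=n_restarts)
        wss.append(res["wss"])
        labels = res["assignments"]
        sil[k] = float(silhouette_score(x, labels)) if len(set(labels)) > 1 else -1.0
        ch[k] = float(calinski_harabasz_score(x, labels))

    votes = {
        "elbow": _elbow_vote(wss_curve_ks, wss),
        "silhouette": max(sil, key=lambda k: (sil[k], -k)),
        "calinski_harabasz": max(ch, key=lambda k: (ch[k], -k)),
    }
    tally: dict[int, int] = {}
    for v in votes.values():
        tally[v] = tally.get(v, 0) + 1
    best = max(tally.values())
    chosen = min(k for k, c in tally.items() if c == best)
    return {
        "chosen_k": chosen,
        "degenerate": False,
        "votes": votes,
        "wss_curve": dict(zip(wss_curve_ks, wss)),
        "silhouette": sil,
        "calinski_harabasz": ch,
    }


def cluster_vs_type_crosstab(
    assignments: np.ndarray, relationship_calls: pd.DataFrame
) -> pd.DataFrame:
    """Contingency table of cluster membership vs Type I/II/III.

    ``relationship_calls`` must cover exactly the comparisons that were
    clustered, in order.  ``result.attrs["type_iii_isolated"]`` records
    whether Type III comparisons occupy clusters free of Types I and II.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(relationship_calls):
        raise ValueError("assignments and relationship calls differ in length")
    tab = pd.crosstab(
        pd.Series(assignments, name="cluster"),
        pd.Series(relationship_calls["type"].to_numpy(), name="type"),
    )
    iii_clusters = set(tab.index[(tab.get("III", 0) > 0)])
    other_clusters = set()
    for t in ("I", "II"):
        if t in tab.columns:
            other_clusters |= set(tab.index[tab[t] > 0])
    tab.attrs["type_iii_isolated"] = not (iii_clusters & other_clusters)
    return tab
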