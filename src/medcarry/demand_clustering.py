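"""K-means typing of hospitals by workload indicators.

Hospitals are clustered on five yearly workload indicators (total visits,
outpatient visits, emergency visits, inpatient visits, discharges), the
number of clusters is picked by the elbow method on the within-cluster sum
of squares (WCSS), and the clusters are ranked into demand levels
(level 1 = heaviest workload).  Indicators are z-scored before clustering
because their raw scales differ by orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

__all__ = ["elbow_select_k", "type_hospitals", "cluster_significance", "DemandTyping"]


def _fit_kmeans(z: np.ndarray, k: int, seed: int | None) -> KMeans:
    return KMeans(n_clusters=k, n_init=10, random_state=seed).fit(z)


def elbow_select_k(
    features: pd.DataFrame | np.ndarray,
    k_max: int = 8,
    seed: int | None = None,
) -> tuple[int, pd.Series, bool]:
    """Pick the cluster count by the elbow of the WCSS curve.

    K-means (k-means++, 10 restarts) is run for k = 1..k_max on z-scored
    features; the chosen k maximizes the discrete second difference
    ``WCSS(k-1) - 2 WCSS(k) + WCSS(k+1)``, i.e. the sharpest bend of the
    curve.  When no bend clearly dominates (best second difference less
    than 3x the runner-up) the choice is flagged low-confidence.

    Returns
    -------
    (k, wcss_curve, low_confidence)
        ``wcss_curve`` is indexed by k = 1..k_max.
    """
    x = np.asarray(features, dtype=float)
    if x.shape[0] <= k_max:
        raise ValueError(f"need more than k_max = {k_max} rows")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate features: all rows identical")
    z = StandardScaler().fit_transform(x)
    ks = np.arange(1, k_max + 1)
    wcss = np.array([_fit_kmeans(z, k, seed).inertia_ for k in ks])

    second_diff = wcss[:-2] - 2 * wcss[1:-1] + wcss[2:]  # at k = 2..k_max-1
    best = int(np.argmax(second_diff))
    k_star = int(ks[best + 1])
    ordered = np.sort(second_diff)[::-1]
    runner_up = ordered[1] if len(ordered) > 1 else 0.0
    low_confidence = not (ordered[0] > 3.0 * max(runner_up, 0.0) and ordered[0] > 0)
    return k_star, pd.Series(wcss, index=ks, name="wcss"), low_confidence


@dataclass
class DemandTyping:
    """Hospital demand typing: cluster ids, demand levels and summaries.

    ``level`` ranks clusters by average workload, 1 = heaviest.
    """

    cluster: np.ndarray
    level: np.ndarray
    k: int
    cluster_means: pd.DataFrame
    level_counts: pd.Series
    wcss: float = np.nan
    extras: dict = field(default_factory=dict)


def type_hospitals(
    features: pd.DataFrame | np.ndarray,
    k: int = 4,
    seed: int | None = None,
    rank_on: str = "standardized",
    max_retries: int = 5,
) -> DemandTyping:
    """Cluster hospitals by workload and rank clusters into demand levels.

    Features are z-scored and clustered by k-means; clusters are ordered by
    the mean of their standardized indicator means, descending, so level 1
    is the heaviest-workload group (``rank_on="raw"`` ranks on raw means
    instead).  An empty cluster after convergence triggers a bounded
    reseeded retry.
    """
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    if n <= k:
        raise ValueError(f"need more than k = {k} rows")
    if rank_on not in ("standardized", "raw"):
        raise ValueError("rank_on must be 'standardized' or 'raw'")
    z = StandardScaler().fit_transform(x)

    attempt_seed = seed
    for _ in range(max_retries):
        km = _fit_kmeans(z, k, attempt_seed)
        labels = km.labels_
        if len(np.unique(labels)) == k:
            break
        attempt_seed = None if attempt_seed is None else attempt_seed + 1
    else:
        raise RuntimeError("k-means kept producing empty clusters")

    basis = z if rank_on == "standardized" else x
    cluster_ids = np.arange(k)
    means = np.array([basis[labels == c].mean(axis=0) for c in cluster_ids])
    order = np.argsort(-means.mean(axis=1), kind="stable")  # heaviest first
    level_of_cluster = np.empty(k, dtype=int)
    level_of_cluster[order] = np.arange(1, k + 1)
    levels = level_of_cluster[labels]

    columns = (
        list(features.columns)
        if isinstance(features, pd.DataFrame)
        else [f"f{i}" for i in range(x.shape[1])]
    )
    raw_means = pd.DataFrame(
        [x[labels == c].mean(axis=0) for c in cluster_ids],
        index=pd.Index(cluster_ids, name="cluster"),
        columns=columns,
    )
    raw_means["level"] = level_of_cluster
    counts = (
        pd.Series(levels, name="count")
        .value_counts()
        .reindex(range(1, k + 1), fill_value=0)
        .rename_axis("level")
    )
    return DemandTyping(
        cluster=labels,
        level=levels,
        k=k,
        cluster_means=raw_means,
        level_counts=counts,
        wcss=float(km.inertia_),
    )


def cluster_significance(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-indicator one-way ANOVA across clusters.

    Tests, for each workload indicator, whether cluster means differ;
    returns F, p, and a boolean ``significant`` at ``alpha`` per indicator.
    Requires at least two clusters, each with at least two members.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two clusters")
    sizes = [np.count_nonzero(labels == g) for g in groups]
    if min(sizes) < 2:
        raise ValueError("every cluster needs at least two members")
    columns = (
        list(features.columns)
        if isinstance(features, pd.DataFrame)
        else [f"f{i}" for i in range(x.shape[1])]
    )
    rows = []
    for j, name in enumerate(columns):
        samples = [x[labels == g, j] for g in groups]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*samples)
        rows.append((name, float(f_stat), float(p), bool(p <= alpha)))
    return pd.DataFrame(
        rows, columns=["indicator", "F", "p", "significant"]
    ).set_index("indicator")
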