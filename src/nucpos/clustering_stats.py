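"""Profile clustering and gene-set enrichment statistics.

k-means (Euclidean, k = 5 by default) groups per-gene normalized occupancy
profiles; hypergeometric upper-tail tests score overlap between positioning
calls and differential-expression gene sets. Raw p-values are reported by
default (matching the study's usage); Benjamini-Hochberg adjustment is
available for batch queries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .model import GeneSet

__all__ = [
    "ClusterResult",
    "EnrichmentResult",
    "OverlapResult",
    "cluster_profiles",
    "hypergeom_enrichment",
    "overlap_sets",
    "bh_adjust",
]


@dataclass
class ClusterResult:
    k: int
    assignments: dict  # gene_id -> 1-based cluster index
    centroids: np.ndarray  # (k, n_offsets)
    inertia: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.assignments), "cluster": list(self.assignments.values())}
        )


@dataclass(frozen=True)
class EnrichmentResult:
    N: int  # population size
    K: int  # category size
    n: int  # draw size
    k_obs: int  # observed overlap
    p_value: float  # upper-tail hypergeometric probability
    expected: float  # n * K / N


@dataclass(frozen=True)
class OverlapResult:
    venn: tuple[int, int, int]  # |a only|, |a and b|, |b only|
    enrichment: EnrichmentResult
    frac_of_a: float
    frac_of_b: float
    frac_of_universe: float


def cluster_profiles(
    matrix: pd.DataFrame | np.ndarray,
    k: int = 5,
    n_restarts: int = 100,
    seed: int = 1729,
    gene_ids: Sequence[str] | None = None,
) -> ClusterResult:
    """Lloyd k-means with k-means++ seeding, best of ``n_restarts`` by inertia.

    Rows are genes (per-gene normalized profiles so depth does not drive the
    partition), columns offsets. Deterministic for a fixed seed.
    """
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = list(gene_ids) if gene_ids is not None else [str(i) for i in range(len(X))]
    if not np.all(np.isfinite(X)):
        raise ValueError("profile matrix contains non-finite values")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({X.shape[0]})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    assignments = {gid: int(lab) + 1 for gid, lab in zip(ids, km.labels_)}
    return ClusterResult(
        k=k,
        assignments=assignments,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def hypergeom_enrichment(
    N: int, K: int, n: int, k_obs: int, alternative: str = "greater"
) -> EnrichmentResult:
    """Hypergeometric overlap significance.

    Drawing ``n`` genes from a universe of ``N`` containing ``K`` category
    members, the upper-tail probability of observing ``k_obs`` or more in
    the overlap:

        p = sum_{i=k_obs}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n)

    evaluated through scipy's survival function (stable in log space).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got N={N} K={K} n={n}")
    if not (max(0, n + K - N) <= k_obs <= min(n, K)):
        raise ValueError(
            f"k_obs={k_obs} outside [{max(0, n + K - N)}, {min(n, K)}]"
        )
    upper = float(stats.hypergeom.sf(k_obs - 1, N, K, n))
    if alternative == "greater":
        p = upper
    elif alternative == "two-sided":
        lower = float(stats.hypergeom.cdf(k_obs, N, K, n))
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(N=N, K=K, n=n, k_obs=k_obs, p_value=p, expected=n * K / N)


def overlap_sets(a: GeneSet, b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Venn counts and hypergeometric enrichment of two sets in a universe."""
    for s in (a, b):
        extra = s.gene_ids - universe.gene_ids
        if extra:
            raise ValueError(
                f"set {s.label!r} has {len(extra)} ids outside the universe"
            )
    inter = len(a.gene_ids & b.gene_ids)
    enr = hypergeom_enrichment(len(universe), len(a), len(b), inter)
    return OverlapResult(
        venn=(len(a) - inter, inter, len(b) - inter),
        enrichment=enr,
        frac_of_a=inter / len(a) if len(a) else 0.0,
        frac_of_b=inter / len(b) if len(b) else 0.0,
        frac_of_universe=inter / len(universe) if len(universe) else 0.0,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for batch enrichment queries."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")


def plot_centroids(result: ClusterResult, path, offsets: np.ndarray | None = None) -> None:
    """Optional centroid line plot (PNG); requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = offsets if offsets is not None else np.arange(result.centroids.shape[1])
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, c in enumerate(result.centroids, 1):
        ax.plot(x, c, label=f"cluster {i}")
    ax.set_xlabel("offset from anchor (bp)")
    ax.set_ylabel("normalized dyad frequency")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
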