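"""Consensus clustering with PAC scoring and ensemble pooling.

A single trial clusters an (80% by default) random subsample of the samples
with agglomerative hierarchical clustering (Euclidean distance, average
linkage) cut at k.  Over many trials (default 100) the consensus matrix
records, for each sample pair, the fraction of co-sampled trials in which
the pair landed in the same cluster.  The final assignment hierarchically
clusters 1 - consensus as a distance; the proportion of ambiguous
clustering (PAC) is the fraction of off-diagonal pairs with consensus
strictly between the lower and upper thresholds (defaults 0.2 and 0.8) and
is used both to choose k and to compare models.  Consensus matrices from
several independently trained models may be pooled elementwise (equal-vote
ensemble) into a consensus of consensus before the final cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k) per sample plus the linkage merge record."""

    labels: np.ndarray
    k: int
    linkage: np.ndarray
    sample_ids: list | None = None

    def series(self) -> pd.Series:
        idx = self.sample_ids if self.sample_ids is not None else range(len(self.labels))
        return pd.Series(self.labels, index=idx, name="cluster")


@dataclass
class ConsensusMatrix:
    """Symmetric samples x samples co-clustering frequencies in [0, 1],
    diagonal 1.  ``n_never_cosampled`` counts pairs imputed as 0 because
    they were never drawn into the same trial."""

    values: np.ndarray
    sample_ids: list | None
    trials: int
    subsample_fraction: float
    n_never_cosampled: int = 0

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("consensus matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("consensus matrix must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("consensus values must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("consensus diagonal must be 1")

    def frame(self) -> pd.DataFrame:
        ids = self.sample_ids or list(range(self.values.shape[0]))
        return pd.DataFrame(self.values, index=ids, columns=ids)


def _as_matrix(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.index)
    return np.asarray(X, dtype=float), None


def hierarchical_cluster(X, k: int, precomputed: bool = False) -> ClusterAssignment:
    """Average-linkage agglomerative clustering cut at k clusters.

    ``X`` is either a (samples x features) matrix clustered on Euclidean
    distances, or (with ``precomputed``) a square distance-like matrix.
    """
    x, ids = _as_matrix(X)
    n = x.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n} samples")
    if precomputed:
        d = squareform(np.clip((x + x.T) / 2, 0, None), checks=False)
        Z = linkage(d, method="average")
    else:
        Z = linkage(x, method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(labels=labels, k=k, linkage=Z, sample_ids=ids)


def consensus_cluster(
    X, k: int, trials: int = 100, fraction: float = 0.8, seed: int = 0
) -> tuple[ConsensusMatrix, ClusterAssignment]:
    """Subsampled consensus clustering.

    Each trial draws ``floor(fraction * n)`` samples without replacement,
    clusters them (Euclidean, average linkage, cut at k) and tallies
    pairwise co-clustering; the consensus entry is co-cluster count over
    co-sample count.  Pairs never co-sampled are imputed 0 (logged).  The
    final assignment clusters ``1 - consensus`` at k.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    x, ids = _as_matrix(X)
    n = x.shape[0]
    m = max(k, int(np.floor(fraction * n)))
    rng = np.random.default_rng(seed)

    together = np.zeros((n, n))
    cosampled = np.zeros((n, n))
    for _ in range(trials):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n \
            else np.arange(n)
        asg = hierarchical_cluster(x[idx], k)
        cosampled[np.ix_(idx, idx)] += 1
        for c in np.unique(asg.labels):
            members = idx[asg.labels == c]
            together[np.ix_(members, members)] += 1

    never = (cosampled == 0)
    np.fill_diagonal(never, False)
    n_never = int(never.sum() // 2)
    if n_never:
        logger.info("consensus: %d pairs never co-sampled; imputed 0", n_never)
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(cosampled > 0, together / np.maximum(cosampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    cm = ConsensusMatrix(values=consensus, sample_ids=ids, trials=trials,
                         subsample_fraction=fraction, n_never_cosampled=n_never)
    cm.validate()
    final = hierarchical_cluster(1.0 - consensus, k, precomputed=True)
    final.sample_ids = ids
    return cm, final


def pac(cm: ConsensusMatrix | np.ndarray, lower: float = 0.2,
        upper: float = 0.8) -> float:
    """Proportion of ambiguous clustering: fraction of off-diagonal
    unordered pairs with consensus strictly between ``lower`` and
    ``upper``."""
    if lower >= upper:
        raise ValueError("require lower < upper")
    v = cm.values if isinstance(cm, ConsensusMatrix) else np.asarray(cm, float)
    iu = np.triu_indices(v.shape[0], k=1)
    pairs = v[iu]
    if pairs.size == 0:
        return 0.0
    return float(np.mean((pairs > lower) & (pairs < upper)))


def consensus_of_consensus(
    matrices: list[ConsensusMatrix], k: int, method: str = "mean"
) -> tuple[ConsensusMatrix, ClusterAssignment]:
    """Equal-vote ensemble pooling of consensus matrices from multiple
    models, then a final hierarchical cut of ``1 - pooled`` at k.

    ``method='mean'`` averages consensus values elementwise;
    ``method='indicator'`` averages each input's final co-assignment
    indicator matrix instead.
    """
    if len(matrices) < 2:
        raise ValueError("need >= 2 consensus matrices to pool")
    ref_ids = matrices[0].sample_ids
    nsamp = matrices[0].values.shape[0]
    for cmx in matrices[1:]:
        if cmx.values.shape[0] != nsamp or cmx.sample_ids != ref_ids:
            raise ValueError("consensus matrices cover different sample sets")
    if method == "mean":
        pooled = np.mean([cmx.values for cmx in matrices], axis=0)
    elif method == "indicator":
        inds = []
        for cmx in matrices:
            labels = hierarchical_cluster(1.0 - cmx.values, k,
                                          precomputed=True).labels
            inds.append((labels[:, None] == labels[None, :]).astype(float))
        pooled = np.mean(inds, axis=0)
        np.fill_diagonal(pooled, 1.0)
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    cm = ConsensusMatrix(values=pooled, sample_ids=ref_ids,
                         trials=sum(m.trials for m in matrices),
                         subsample_fraction=matrices[0].subsample_fraction)
    cm.validate()
    final = hierarchical_cluster(1.0 - pooled, k, precomputed=True)
    final.sample_ids = ref_ids
    return cm, final


@dataclass
class KSelection:
    k: int
    table: pd.DataFrame  # columns: k, pac


def select_k(cm_by_k: dict[int, ConsensusMatrix], lower: float = 0.2,
             upper: float = 0.8) -> KSelection:
    """Choose the candidate k with the lowest PAC; ties go to smaller k."""
    if not cm_by_k:
        raise ValueError("no candidate k")
    rows = [{"k": k, "pac": pac(cm, lower, upper)}
            for k, cm in sorted(cm_by_k.items())]
    table = pd.DataFrame(rows)
    best = table.loc[table["pac"].idxmin(), "k"]  # idxmin: first (smallest k) tie
    return KSelection(k=int(best), table=table)


def plot_consensus_heatmap(cm: ConsensusMatrix, path) -> None:
    """Heatmap of the consensus matrix ordered by its dendrogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list

    Z = linkage(squareform(1.0 - cm.values, checks=False), method="average")
    order = leaves_list(Z)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(cm.values[np.ix_(order, order)], cmap="Greens", vmin=0, vmax=1)
    ax.set_title(f"Consensus ({cm.trials} trials, "
                 f"{cm.subsample_fraction:.0%} subsampling)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120)
    plt.close(fig)
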