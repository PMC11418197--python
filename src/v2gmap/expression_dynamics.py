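"""Expression-trajectory clustering and the immune expression-specificity score.

Differential genes are clustered with k-means over a k range; the number of
clusters is chosen by the elbow of the within-cluster sum of squares
(the point farthest from the chord of the WCSS curve, with a
second-difference variant available), and each gene is scored by the Pearson
correlation to its own cluster centroid. The specificity score is the
summed median expression over immune tissues (whole blood, spleen) divided
by the summed median over all other tissues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

IMMUNE_TISSUES = ("Whole Blood", "Spleen")


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series  # gene -> cluster label (1-based)
    centroids: pd.DataFrame  # cluster x condition
    correlations: pd.Series  # gene -> Pearson r to own centroid
    wcss: dict[int, float]  # k -> within-cluster sum of squares
    degenerate: bool = False


@dataclass(frozen=True)
class SpecificityScore:
    gene_id: str
    immune_sum: float
    other_sum: float
    score: float
    undefined: bool = False


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across conditions; zero-variance rows become 0."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((values - mean) / sd, index=matrix.index, columns=matrix.columns)


def select_k_elbow(wcss: Mapping[int, float], method: str = "max_distance") -> int:
    """Pick the elbow of a WCSS-versus-k curve.

    ``max_distance`` (default) returns the k whose (k, WCSS) point lies
    farthest from the chord joining the curve's endpoints — the usual
    geometric reading of "the elbow". ``second_difference`` returns the
    interior k maximizing the discrete second difference of WCSS; note
    that on nearly one-dimensional cluster layouts the early WCSS drops
    dominate and this variant systematically underestimates k. Ties go
    to smaller k.
    """
    ks = sorted(wcss)
    if len(ks) < 3:
        raise ValueError("elbow selection needs >= 3 k values")
    if method == "second_difference":
        best_k, best_d2 = None, -np.inf
        for i in range(1, len(ks) - 1):
            d2 = wcss[ks[i - 1]] - 2 * wcss[ks[i]] + wcss[ks[i + 1]]
            if d2 > best_d2 + 1e-12:
                best_k, best_d2 = ks[i], d2
        return best_k
    if method != "max_distance":
        raise ValueError(f"unknown elbow method {method!r}")
    karr = np.array(ks, dtype=float)
    warr = np.array([wcss[k] for k in ks], dtype=float)
    x0, y0, x1, y1 = karr[0], warr[0], karr[-1], warr[-1]
    numer = np.abs((y1 - y0) * karr - (x1 - x0) * warr + x1 * y0 - y1 * x0)
    dist = numer / math.hypot(y1 - y0, x1 - x0)
    return int(karr[int(np.argmax(dist))])


def cluster_trajectories(
    matrix: pd.DataFrame,
    k_range: Sequence[int] = range(2, 10),
    seed: int = 0,
    n_restarts: int = 10,
    standardize: bool = True,
    elbow_method: str = "max_distance",
) -> ClusterResult:
    """Cluster gene expression trajectories with elbow-selected k-means.

    Parameters
    ----------
    matrix : DataFrame
        Genes x conditions expression values (differential genes only).
    k_range : sequence of int
        Candidate cluster numbers (subset of [2, 15]); the elbow is only
        evaluated at interior points of the grid.
    seed : int
        Random state for k-means; with ``n_restarts`` restarts the best
        inertia is kept, so results are deterministic given the seed.
    standardize : bool
        Per-gene z-scoring across conditions before clustering (default).
    """
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k > 15 for k in ks):
        raise ValueError("k_range must lie within [2, 15]")
    if len(matrix) < max(ks):
        raise ValueError(
            f"fewer genes ({len(matrix)}) than the largest candidate k ({max(ks)})"
        )
    data = zscore_rows(matrix) if standardize else matrix.astype(float)
    X = data.to_numpy()

    n_distinct = np.unique(X, axis=0).shape[0]
    degenerate = n_distinct < max(ks)
    if degenerate:
        logger.warning(
            "only %d distinct trajectories for k up to %d; clustering is degenerate",
            n_distinct,
            max(ks),
        )

    wcss: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(X)
        wcss[k] = float(km.inertia_)
        fits[k] = km

    # anchor the curve at k=1 (total sum of squares) so that an elbow at
    # the smallest candidate k is geometrically visible; k=1 itself is an
    # endpoint of the curve and can never be selected
    curve = dict(wcss)
    if 1 not in curve:
        curve[1] = float(((X - X.mean(axis=0)) ** 2).sum())
    k_best = select_k_elbow(curve, method=elbow_method) if len(ks) >= 2 else ks[0]
    if k_best not in fits:
        k_best = min(ks)
    km = fits[k_best]
    labels = km.labels_ + 1  # 1-based cluster ids
    centroids = pd.DataFrame(
        km.cluster_centers_,
        index=range(1, k_best + 1),
        columns=matrix.columns,
    )
    correlations = pd.Series(
        [
            centroid_correlation(X[i], km.cluster_centers_[labels[i] - 1])
            for i in range(len(matrix))
        ],
        index=matrix.index,
    )
    return ClusterResult(
        k=k_best,
        assignments=pd.Series(labels, index=matrix.index),
        centroids=centroids,
        correlations=correlations,
        wcss=wcss,
        degenerate=degenerate,
    )


def centroid_correlation(trajectory: np.ndarray, centroid: np.ndarray) -> float:
    """Pearson product-moment correlation between a gene and its centroid."""
    x = np.asarray(trajectory, dtype=float)
    y = np.asarray(centroid, dtype=float)
    if x.shape != y.shape:
        raise ValueError("trajectory and centroid lengths differ")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance vector has no defined correlation")
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def specificity_score(
    tissue_medians: Mapping[str, float] | pd.Series,
    gene_id: str = "",
    immune_tissues: Sequence[str] = IMMUNE_TISSUES,
) -> SpecificityScore:
    """Immune specificity: sum of immune-tissue medians / sum of the rest.

    ``undefined`` is flagged (score nan) when the non-immune sum is zero.
    Scale-invariant: multiplying all tissues by a constant leaves the
    score unchanged.
    """
    medians = dict(tissue_medians)
    present_immune = [t for t in immune_tissues if t in medians]
    if not present_immune:
        raise ValueError(f"no immune tissue columns among {list(immune_tissues)}")
    others = [t for t in medians if t not in immune_tissues]
    if not others:
        raise ValueError("need at least one non-immune tissue")
    immune_sum = float(sum(medians[t] for t in present_immune))
    other_sum = float(sum(medians[t] for t in others))
    if other_sum == 0:
        return SpecificityScore(gene_id, immune_sum, other_sum, float("nan"), True)
    return SpecificityScore(gene_id, immune_sum, other_sum, immune_sum / other_sum, False)


def specificity_table(
    tissue_matrix: pd.DataFrame, immune_tissues: Sequence[str] = IMMUNE_TISSUES
) -> pd.DataFrame:
    """Specificity scores for a genes x tissues median-expression table."""
    rows = []
    for gene_id, row in tissue_matrix.iterrows():
        s = specificity_score(row, gene_id=str(gene_id), immune_tissues=immune_tissues)
        rows.append(
            {
                "gene_id": s.gene_id,
                "immune_sum": s.immune_sum,
                "other_sum": s.other_sum,
                "score": s.score,
                "undefined": s.undefined,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
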