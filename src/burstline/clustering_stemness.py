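"""Cell clustering and the entropy-times-links stemness score.

Cells are clustered by k-medoids on 1 - Spearman correlation distance over
highly variable genes.  Each cluster is then scored for "stemness" as the
product of its median transcriptome entropy (stem-like cells express many
incipient programs, hence high entropy) and its number of significant links
to other clusters (stem-like states connect to many downstream states).
Links follow a simplified medoid-line projection scheme: a cell supports a
link from its own cluster a to cluster b when, among all lines from medoid a
to other medoids, the cell lies closest to the a->b line with a projection
strictly between the medoids; a link is significant when its supporting cell
count exceeds the 95th percentile of a label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc_filtering import CountMatrix

__all__ = [
    "cluster_cells",
    "cell_entropy",
    "cluster_links",
    "stemness_score",
    "stemness_table",
]


def _spearman_distance_matrix(x: np.ndarray) -> np.ndarray:
    """1 - Spearman rho between columns (cells) of a genes x cells matrix."""
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    rho = np.corrcoef(ranks, rowvar=False)
    rho = np.where(np.isnan(rho), 0.0, rho)
    return 1.0 - rho


def cluster_cells(matrix: CountMatrix, hvg, k: int, seed: int = 0,
                  max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """k-medoids (PAM-style alternation) on 1 - Spearman distance.

    Returns ``(labels, medoid_indices)``; deterministic given the seed.
    Initial medoids are drawn without replacement from the seeded RNG, then
    assignment and medoid-update steps alternate to convergence.
    """
    hvg = list(hvg)
    if not hvg:
        raise ValueError("hvg list must be non-empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.n_cells:
        raise ValueError(f"k={k} exceeds {matrix.n_cells} cells")
    x = matrix.subset_genes(np.asarray(hvg, dtype=object)).to_dense().astype(float)
    dist = _spearman_distance_matrix(x)
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(matrix.n_cells, size=k, replace=False))
    labels = np.argmin(dist[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        new_labels = np.argmin(dist[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels, medoids


def cell_entropy(cell_counts) -> float:
    """Shannon entropy (natural log) of a cell's expression proportions."""
    x = np.asarray(cell_counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("cell has zero total count; entropy undefined")
    p = x[x > 0] / total
    return float(-np.sum(p * np.log(p)))


def _link_counts(points: np.ndarray, labels: np.ndarray,
                 medoid_points: np.ndarray, k: int) -> np.ndarray:
    """counts[a, b] = cells of cluster a whose nearest medoid-line points to b."""
    counts = np.zeros((k, k), dtype=int)
    diffs = medoid_points[None, :, :] - medoid_points[:, None, :]   # a -> b vectors
    norms2 = np.sum(diffs ** 2, axis=2)
    for a in range(k):
        members = np.flatnonzero(labels == a)
        if members.size == 0:
            continue
        v = points[members] - medoid_points[a]                       # cells rel. medoid a
        best_b = np.full(members.size, -1)
        best_d = np.full(members.size, np.inf)
        for b in range(k):
            if b == a or norms2[a, b] == 0:
                continue
            t = v @ diffs[a, b] / norms2[a, b]
            # strict interior with a guard so cells sitting exactly on a
            # medoid are excluded regardless of floating-point path
            eps = 1e-9
            interior = (t > eps) & (t < 1.0 - eps)
            proj = np.outer(t, diffs[a, b])
            d = np.linalg.norm(v - proj, axis=1)
            d = np.where(interior, d, np.inf)
            better = d < best_d
            best_d[better] = d[better]
            best_b[better] = b
        for b in best_b[best_b >= 0]:
            counts[a, b] += 1
    return counts


def cluster_links(labels: np.ndarray, medoids: np.ndarray, matrix: CountMatrix,
                  hvg=None, n_permutations: int = 1000, seed: int = 0,
                  quantile: float = 0.95) -> pd.DataFrame:
    """Significant inter-cluster links via a label-permutation null.

    Cells are placed in log1p expression space over ``hvg`` (all genes when
    None).  For each ordered pair (a, b) the observed supporting-cell count
    is compared with the ``quantile`` of its permutation null (labels
    shuffled, medoid positions fixed); a link is significant when observed >
    null.  Returns a per-cluster table with ``n_links`` (significant links
    touching the cluster in either direction, counted once per partner) and
    a ``singleton`` flag.
    """
    labels = np.asarray(labels)
    k = len(medoids)
    if k < 2:
        raise ValueError("need >= 2 clusters")
    sub = matrix if hvg is None else matrix.subset_genes(np.asarray(list(hvg), dtype=object))
    points = np.log1p(sub.to_dense().astype(float)).T    # cells x genes
    medoid_points = points[np.asarray(medoids)]

    observed = _link_counts(points, labels, medoid_points, k)
    rng = np.random.default_rng(seed)
    null = np.zeros((n_permutations, k, k), dtype=int)
    for i in range(n_permutations):
        null[i] = _link_counts(points, rng.permutation(labels), medoid_points, k)
    threshold = np.quantile(null, quantile, axis=0)
    significant = observed > threshold

    partner = significant | significant.T
    np.fill_diagonal(partner, False)
    rows = []
    for c in range(k):
        size = int(np.sum(labels == c))
        rows.append({
            "cluster": c,
            "n_cells": size,
            "n_links": int(partner[c].sum()) if size > 1 else 0,
            "singleton": size <= 1,
        })
    return pd.DataFrame(rows)


def stemness_score(median_entropy: float, n_links: int) -> float:
    """Stemness = median transcriptome entropy x number of significant links."""
    return float(median_entropy) * int(n_links)


def stemness_table(matrix: CountMatrix, labels: np.ndarray,
                   links: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster median entropy, link count and stemness score."""
    counts = matrix.to_dense()
    entropies = np.array([cell_entropy(counts[:, j]) for j in range(matrix.n_cells)])
    rows = []
    for _, link_row in links.iterrows():
        c = int(link_row["cluster"])
        members = np.flatnonzero(np.asarray(labels) == c)
        med_h = float(np.median(entropies[members])) if members.size else np.nan
        rows.append({
            "cluster": c,
            "n_cells": int(members.size),
            "median_entropy": med_h,
            "n_links": int(link_row["n_links"]),
            "stemness": stemness_score(med_h, int(link_row["n_links"]))
            if members.size else np.nan,
        })
    return pd.DataFrame(rows)
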