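"""Per-gene noise statistics and cell-to-cell heterogeneity measures.

Covers the snapshot noise toolbox for two-condition comparisons: per-gene
mean / SD / CV on depth-normalized expression, two-sample distribution tests
(KS, Mann-Whitney, Welch), CV comparisons within mean-expression bins,
distance-to-median (DM) highly-variable-gene selection, and gene-gene
Spearman-correlation pairwise distances (1 - rho) as a dispersion measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc_filtering import CountMatrix

__all__ = [
    "gene_stats",
    "compare_stat_distributions",
    "binned_cv_compare",
    "select_hvg_dm",
    "distance_to_median",
    "pairwise_gene_distance",
    "DistanceDistribution",
]


def _normalized_expression(matrix: CountMatrix) -> np.ndarray:
    """Library-size normalization: scale each cell to the median total count."""
    x = matrix.to_dense().astype(float)
    libsize = x.sum(axis=0)
    med = np.median(libsize[libsize > 0])
    factors = np.where(libsize > 0, med / np.where(libsize > 0, libsize, 1.0), 0.0)
    return x * factors[None, :]


def gene_stats(matrix: CountMatrix, per_condition: bool = False,
               normalize: bool = True) -> pd.DataFrame:
    """Per-gene mean, SD (n-1 denominator), CV and detection fraction.

    CV = SD / mean; genes with zero mean get ``cv = NaN`` and
    ``cv_defined = False`` rather than raising.  With ``per_condition`` one
    record per gene per condition label is produced.
    """
    if per_condition:
        parts = []
        for lab in sorted(set(matrix.condition)):
            sub = matrix.subset_cells(matrix.condition == lab)
            t = gene_stats(sub, per_condition=False, normalize=normalize)
            t.insert(1, "condition", lab)
            parts.append(t)
        return pd.concat(parts, ignore_index=True)

    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells to compute an SD")
    x = _normalized_expression(matrix) if normalize else matrix.to_dense().astype(float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    detection = (matrix.to_dense() > 0).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    table = pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "mean": mean,
        "sd": sd,
        "cv": cv,
        "cv_defined": mean > 0,
        "detection_fraction": detection,
    })
    table["dm"] = distance_to_median(table)
    return table


def compare_stat_distributions(wt_values, ko_values, test: str = "ks"):
    """Two-sided two-sample test plus the KO - WT median difference.

    ``test`` is one of "ks" (Kolmogorov-Smirnov), "mannwhitney" or "welch".
    Returns ``(statistic, pvalue, median_difference)``.
    """
    wt = np.asarray(wt_values, dtype=float)
    ko = np.asarray(ko_values, dtype=float)
    wt, ko = wt[~np.isnan(wt)], ko[~np.isnan(ko)]
    if wt.size == 0 or ko.size == 0:
        raise ValueError("both value vectors must be non-empty")
    if test == "ks":
        res = stats.ks_2samp(wt, ko)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(wt, ko, alternative="two-sided")
    elif test == "welch":
        res = stats.ttest_ind(wt, ko, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue), float(np.median(ko) - np.median(wt))


def binned_cv_compare(stats_wt: pd.DataFrame, stats_ko: pd.DataFrame,
                      n_bins: int = 10, min_genes: int = 3) -> pd.DataFrame:
    """KS comparison of CVs within quantile bins of log mean expression.

    Bins are deciles (by default) of log10 mean over the pooled gene set, so
    the CV contrast is assessed at matched expression levels.  Bins with
    fewer than ``min_genes`` genes in either condition are flagged and their
    p-value omitted.
    """
    wt = stats_wt[stats_wt["cv_defined"]]
    ko = stats_ko[stats_ko["cv_defined"]]
    pooled_log_mean = np.log10(np.concatenate([wt["mean"], ko["mean"]]))
    edges = np.unique(np.quantile(pooled_log_mean, np.linspace(0, 1, n_bins + 1)))
    edges[0], edges[-1] = -np.inf, np.inf
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_wt = wt[(np.log10(wt["mean"]) >= lo) & (np.log10(wt["mean"]) < hi)]
        in_ko = ko[(np.log10(ko["mean"]) >= lo) & (np.log10(ko["mean"]) < hi)]
        row = {"bin_lo": lo, "bin_hi": hi,
               "n_wt": len(in_wt), "n_ko": len(in_ko), "flagged": False}
        if len(in_wt) < min_genes or len(in_ko) < min_genes:
            row.update(ks_statistic=np.nan, pvalue=np.nan, flagged=True,
                       cv_median_difference=np.nan)
        else:
            ks, p, dmed = compare_stat_distributions(in_wt["cv"], in_ko["cv"], "ks")
            row.update(ks_statistic=ks, pvalue=p, cv_median_difference=dmed)
        rows.append(row)
    return pd.DataFrame(rows)


def distance_to_median(stats_table: pd.DataFrame, window: int = 50) -> np.ndarray:
    """DM variability score: residual of log10 CV^2 to a running median.

    Genes are ordered by log10 mean and each gene's log10 CV^2 is compared
    with the median over a ``window``-gene sliding window (clipped at the
    edges), removing the mean-expression trend from the variability score.
    Genes without a defined positive CV get NaN.
    """
    mean = stats_table["mean"].to_numpy(dtype=float)
    cv = stats_table["cv"].to_numpy(dtype=float)
    ok = (mean > 0) & np.isfinite(cv) & (cv > 0)
    dm = np.full(len(stats_table), np.nan)
    if ok.sum() == 0:
        return dm
    idx = np.flatnonzero(ok)
    order = idx[np.argsort(mean[idx], kind="stable")]
    log_cv2 = np.log10(cv[order] ** 2)
    half = window // 2
    n = len(order)
    run_med = np.array([
        np.median(log_cv2[max(0, i - half): min(n, i - half + window)])
        for i in range(n)
    ])
    dm[order] = log_cv2 - run_med
    return dm


def select_hvg_dm(stats_table: pd.DataFrame, n: int = 500) -> list[str]:
    """Top-``n`` highly variable genes by DM score, deterministically ordered.

    Ties are broken by gene id so the selection is stable across runs.
    """
    usable = stats_table[np.isfinite(stats_table["dm"])]
    if len(usable) < n:
        raise ValueError(f"requested {n} HVGs but only {len(usable)} genes have a DM score")
    ranked = usable.sort_values(["dm", "gene_id"], ascending=[False, True], kind="stable")
    return ranked["gene_id"].head(n).tolist()


@dataclass
class DistanceDistribution:
    """Pairwise gene-gene distances (1 - Spearman rho) for one condition."""

    condition: str
    distances: np.ndarray          # flat upper-triangle distances, flagged pairs removed
    n_genes: int
    n_flagged_pairs: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    def summary(self, confidence: float = 0.95) -> dict:
        d = self.distances
        se = d.std(ddof=1) / np.sqrt(d.size)
        z = stats.norm.ppf(0.5 + confidence / 2)
        return {"condition": self.condition, "mean": self.mean,
                "ci_low": self.mean - z * se, "ci_high": self.mean + z * se,
                "n_pairs": int(d.size), "n_flagged": self.n_flagged_pairs}


def pairwise_gene_distance(matrix: CountMatrix, genes, condition: str,
                           metric: str = "one_minus_spearman") -> DistanceDistribution:
    """Distances between all gene pairs across cells of one condition.

    The default metric is ``1 - rho`` with Spearman rank correlation
    (average ranks on ties), giving distances in [0, 2].  The alternative
    "correlation_rows" metric is the Euclidean distance between rows of the
    gene-gene correlation matrix.  Pairs involving a zero-variance gene are
    excluded from the distribution and counted.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    sub = matrix.subset_genes(np.asarray(genes, dtype=object))
    sub = sub.subset_cells(sub.condition == condition)
    x = sub.to_dense().astype(float)
    variance = x.var(axis=1)
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks)
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    good = (variance[iu[0]] > 0) & (variance[iu[1]] > 0)
    if metric == "one_minus_spearman":
        dist = 1.0 - rho[iu]
    elif metric == "correlation_rows":
        rho0 = np.where(np.isnan(rho), 0.0, rho)
        sq = np.sum((rho0[:, None, :] - rho0[None, :, :]) ** 2, axis=2)
        dist = np.sqrt(sq[iu])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceDistribution(
        condition=condition,
        distances=dist[good],
        n_genes=n,
        n_flagged_pairs=int((~good).sum()),
    )
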