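"""Promoter acetylation classification from ChIP-seq peak BED files.

Promoters are strand-aware windows around each TSS (-1 kb to +500 bp).  A
promoter is assessable in a genotype when it overlaps an H3K4me3 peak of
that genotype (>= 1 bp, BEDtools-intersect style); it is then categorized by
its acetylation overlap as K9only / K27only / dual / none.  An acetylation
target is a gene whose promoter is K9only in WT and overlaps no KO H3K9ac
peak at all — a WT-exclusive H3K9ac promoter without concomitant H3K27ac,
i.e. one that loses its single activating acetylation upon knockout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "read_bed",
    "write_bed",
    "promoter_windows",
    "classify_acetylation",
    "target_burst_comparison",
]

CATEGORIES = ("K9only", "K27only", "dual", "none")


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file (0-based half-open) into chrom/start/end."""
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write chrom/start/end intervals as 3-column BED."""
    bad = intervals[(intervals["start"] < 0) | (intervals["start"] >= intervals["end"])]
    if len(bad):
        raise ValueError(f"{len(bad)} invalid intervals (start < 0 or start >= end)")
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def promoter_windows(tss_table: pd.DataFrame, upstream: int = 1000,
                     downstream: int = 500) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS.

    + strand TSS t -> [t - upstream, t + downstream); - strand mirrored to
    [t - downstream, t + upstream); clamped at coordinate 0.  One window per
    TSS row (a gene may contribute several).
    """
    required = {"gene_id", "chrom", "pos", "strand"}
    missing = required - set(tss_table.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    strands = tss_table["strand"].to_numpy()
    unknown = set(strands) - {"+", "-"}
    if unknown:
        raise ValueError(f"unknown strand value(s): {sorted(unknown)}")
    pos = tss_table["pos"].to_numpy(dtype=np.int64)
    plus = strands == "+"
    start = np.where(plus, pos - upstream, pos - downstream)
    end = np.where(plus, pos + downstream, pos + upstream)
    return pd.DataFrame({
        "gene_id": tss_table["gene_id"].to_numpy(),
        "chrom": tss_table["chrom"].to_numpy(),
        "start": np.maximum(start, 0),
        "end": end,
        "strand": strands,
    })


def _build_trees(peaks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in peaks.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int)))
    return trees


def _overlaps(trees: dict[str, IntervalTree], chrom, start, end) -> np.ndarray:
    """>=1 bp overlap flags for vectors of query intervals."""
    out = np.zeros(len(chrom), dtype=bool)
    for i, (c, s, e) in enumerate(zip(chrom, start, end)):
        tree = trees.get(c)
        if tree is not None and tree.overlaps(int(s), int(e)):
            out[i] = True
    return out


def _categorize(k9: np.ndarray, k27: np.ndarray) -> np.ndarray:
    cat = np.full(len(k9), "none", dtype=object)
    cat[k9 & ~k27] = "K9only"
    cat[~k9 & k27] = "K27only"
    cat[k9 & k27] = "dual"
    return cat


def classify_acetylation(promoters: pd.DataFrame,
                         k4me3_wt: pd.DataFrame, k9ac_wt: pd.DataFrame,
                         k27ac_wt: pd.DataFrame, k9ac_ko: pd.DataFrame,
                         k27ac_ko: pd.DataFrame, k4me3_ko: pd.DataFrame,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-promoter acetylation categories per genotype plus target calls.

    Returns ``(annotation, category_counts)``.  The annotation has one row
    per promoter window with ``category_WT`` / ``category_KO`` (NaN when the
    promoter overlaps no H3K4me3 peak of that genotype, i.e. not assessable)
    and a ``target`` flag: WT category K9only AND no overlap with any KO
    H3K9ac peak.  The counts table tallies categories over assessable
    promoters per genotype.
    """
    if len(k4me3_wt) == 0 or len(k4me3_ko) == 0:
        raise ValueError("empty H3K4me3 peak set: no promoters assessable")
    chrom = promoters["chrom"].to_numpy()
    start = promoters["start"].to_numpy()
    end = promoters["end"].to_numpy()

    marks = {
        ("k4", "WT"): _build_trees(k4me3_wt), ("k4", "KO"): _build_trees(k4me3_ko),
        ("k9", "WT"): _build_trees(k9ac_wt), ("k9", "KO"): _build_trees(k9ac_ko),
        ("k27", "WT"): _build_trees(k27ac_wt), ("k27", "KO"): _build_trees(k27ac_ko),
    }
    hits = {key: _overlaps(trees, chrom, start, end) for key, trees in marks.items()}

    annotation = promoters.copy()
    for genotype in ("WT", "KO"):
        assessable = hits[("k4", genotype)]
        cat = _categorize(hits[("k9", genotype)], hits[("k27", genotype)])
        annotation[f"assessable_{genotype}"] = assessable
        annotation[f"category_{genotype}"] = np.where(assessable, cat, None)
    annotation["target"] = (
        annotation["assessable_WT"].to_numpy()
        & (annotation["category_WT"].to_numpy() == "K9only")
        & ~hits[("k9", "KO")]
    )

    counts = []
    for genotype in ("WT", "KO"):
        sub = annotation[annotation[f"assessable_{genotype}"]]
        tally = sub[f"category_{genotype}"].value_counts()
        counts.append({"genotype": genotype,
                       **{c: int(tally.get(c, 0)) for c in CATEGORIES},
                       "assessable": int(len(sub))})
    return annotation, pd.DataFrame(counts)


def gene_targets(annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse promoter-level calls to genes: target if ANY promoter is."""
    return annotation.groupby("gene_id", as_index=False)["target"].any()


def target_burst_comparison(differential_table: pd.DataFrame,
                            annotation: pd.DataFrame) -> dict:
    """Rank tests of bursting between acetylation targets and non-targets.

    Mann-Whitney (two-sided) on burst frequency within each genotype and on
    the relative frequency differential Fburst between the target and
    non-target gene sets; medians are reported per group.
    """
    targets = gene_targets(annotation)
    merged = differential_table.merge(targets, on="gene_id", how="inner")
    t = merged[merged["target"]]
    nt = merged[~merged["target"]]
    if len(t) < 3 or len(nt) < 3:
        raise ValueError(
            f"need >= 3 genes per group, got {len(t)} targets / {len(nt)} non-targets")
    out = {"n_targets": int(len(t)), "n_non_targets": int(len(nt))}
    for col, label in (("f_WT", "f_WT"), ("f_KO", "f_KO"), ("Fburst", "Fburst")):
        tv = t[col].dropna().to_numpy()
        nv = nt[col].dropna().to_numpy()
        res = stats.mannwhitneyu(tv, nv, alternative="two-sided")
        out[label] = {
            "statistic": float(res.statistic),
            "pvalue": float(res.pvalue),
            "median_targets": float(np.median(tv)),
            "median_non_targets": float(np.median(nv)),
        }
    return out
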