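"""End-to-end orchestration: simulate/load -> filter -> noise -> burst ->
targets -> stemness -> machine-readable report.

Every stage persists its intermediate as TSV/JSON under the output directory
so each report number can be recomputed from the stored artifacts, and
identical config + seed reproduces identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .burst_model import differential_burst, fit_gene_table, regression_decomposition
from .chip_targets import (classify_acetylation, promoter_windows, read_bed,
                           target_burst_comparison)
from .clustering_stemness import cluster_cells, cluster_links, stemness_table
from .noise_metrics import (binned_cv_compare, compare_stat_distributions,
                            gene_stats, pairwise_gene_distance, select_hvg_dm)
from .qc_filtering import read_matrix, robust_filter, write_matrix
from .synthetic_data import SimConfig, write_experiment

log = logging.getLogger("burstline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    Exactly one input mode: either ``simulation`` holds a SimConfig, or
    ``inputs`` maps the real-data file paths (wt_mtx/wt_genes/wt_barcodes,
    ko_*, tss, and per-mark BED paths).
    """

    outdir: str = "burstline_run"
    simulation: SimConfig | None = None
    inputs: dict | None = None
    min_gene_detection_fraction: float = 0.10
    min_genes_per_cell: int = 500
    n_bins: int = 10
    n_hvg: int = 500
    k_clusters: int = 4
    fit_method: str = "moments"      # "moments" | "mle"
    n_link_permutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of simulation / inputs must be set")
        for name in ("min_gene_detection_fraction", "min_genes_per_cell",
                     "n_bins", "n_hvg", "k_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimConfig(**raw["simulation"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulation is not None:
        sim_dir = outdir / "simulated"
        paths = write_experiment(config.simulation, sim_dir)
        wt = read_matrix(sim_dir / "wt" / "matrix.mtx", sim_dir / "wt" / "genes.tsv",
                         sim_dir / "wt" / "barcodes.tsv", "WT")
        ko = read_matrix(sim_dir / "ko" / "matrix.mtx", sim_dir / "ko" / "genes.tsv",
                         sim_dir / "ko" / "barcodes.tsv", "KO")
        tss = pd.read_csv(paths["tss"], sep="\t")
        beds = {key: read_bed(paths[f"{mark}_{geno}"])
                for mark in ("H3K4me3", "H3K9ac", "H3K27ac")
                for geno in ("WT", "KO")
                for key in [(mark, geno)]}
        return wt, ko, tss, beds
    inp = config.inputs
    wt = read_matrix(inp["wt_mtx"], inp["wt_genes"], inp["wt_barcodes"], "WT")
    ko = read_matrix(inp["ko_mtx"], inp["ko_genes"], inp["ko_barcodes"], "KO")
    tss = pd.read_csv(inp["tss"], sep="\t")
    beds = {(mark, geno): read_bed(inp[f"{mark.lower()}_{geno.lower()}"])
            for mark in ("H3K4me3", "H3K9ac", "H3K27ac") for geno in ("WT", "KO")}
    return wt, ko, tss, beds


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order and return the report dict.

    Artifacts: resolved config, filtered matrix, per-gene stats, fits,
    differential table, promoter annotation, stemness table, and
    ``report.json`` under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    log.info("stage: load/simulate")
    wt_raw, ko_raw, tss, beds = _load_inputs(config, outdir)
    log.info("loaded %d genes; %d WT + %d KO cells",
             wt_raw.n_genes, wt_raw.n_cells, ko_raw.n_cells)

    log.info("stage: robust filter")
    joint, filter_report = robust_filter(
        wt_raw, ko_raw,
        min_gene_detection_fraction=config.min_gene_detection_fraction,
        min_genes_per_cell=config.min_genes_per_cell)
    filter_report.to_json(outdir / "filter_report.json")
    write_matrix(joint, outdir / "filtered")
    log.info("retained %d genes, %d cells", joint.n_genes, joint.n_cells)

    log.info("stage: noise metrics")
    stats_by_cond = {
        lab: gene_stats(joint.subset_cells(joint.condition == lab))
        for lab in ("WT", "KO")
    }
    for lab, table in stats_by_cond.items():
        table.to_csv(outdir / f"gene_stats_{lab}.tsv", sep="\t", index=False)
    mean_cmp = compare_stat_distributions(
        stats_by_cond["WT"]["mean"], stats_by_cond["KO"]["mean"], "ks")
    cv_cmp = compare_stat_distributions(
        stats_by_cond["WT"]["cv"], stats_by_cond["KO"]["cv"], "ks")
    binned = binned_cv_compare(stats_by_cond["WT"], stats_by_cond["KO"],
                               n_bins=config.n_bins)
    binned.to_csv(outdir / "binned_cv.tsv", sep="\t", index=False)
    hvg = sorted(set(select_hvg_dm(stats_by_cond["WT"], config.n_hvg))
                 | set(select_hvg_dm(stats_by_cond["KO"], config.n_hvg)))
    dist_summ = {
        lab: pairwise_gene_distance(joint, hvg, lab).summary() for lab in ("WT", "KO")
    }

    log.info("stage: burst model fits (%s)", config.fit_method)
    fits = {lab: fit_gene_table(joint, condition=lab, method=config.fit_method)
            for lab in ("WT", "KO")}
    for lab, table in fits.items():
        table.to_csv(outdir / f"telegraph_fits_{lab}.tsv", sep="\t", index=False)
    diff = differential_burst(fits["WT"], fits["KO"])
    diff["table"].to_csv(outdir / "differential_burst.tsv", sep="\t", index=False)
    regression = regression_decomposition(stats_by_cond["WT"], fits["WT"])
    regression.to_csv(outdir / "regression_decomposition.tsv", sep="\t", index=False)

    log.info("stage: acetylation targets")
    promoters = promoter_windows(tss)
    annotation, category_counts = classify_acetylation(
        promoters, beds[("H3K4me3", "WT")], beds[("H3K9ac", "WT")],
        beds[("H3K27ac", "WT")], beds[("H3K9ac", "KO")],
        beds[("H3K27ac", "KO")], beds[("H3K4me3", "KO")])
    annotation.to_csv(outdir / "promoter_annotation.tsv", sep="\t", index=False)
    target_stats = target_burst_comparison(diff["table"], annotation)

    log.info("stage: clustering and stemness")
    labels, medoids = cluster_cells(joint, hvg, k=config.k_clusters, seed=config.seed)
    links = cluster_links(labels, medoids, joint, hvg=hvg,
                          n_permutations=config.n_link_permutations, seed=config.seed)
    stemness = stemness_table(joint, labels, links)
    stemness.to_csv(outdir / "stemness.tsv", sep="\t", index=False)

    report = {
        "burstline_version": __version__,
        "config": config.to_dict(),
        "filter": asdict(filter_report),
        "mean_comparison": {"ks": mean_cmp[0], "pvalue": mean_cmp[1],
                            "median_difference": mean_cmp[2]},
        "cv_comparison": {"ks": cv_cmp[0], "pvalue": cv_cmp[1],
                          "median_difference": cv_cmp[2]},
        "binned_cv_all_significant": bool(
            (binned.loc[~binned["flagged"], "pvalue"] < 0.05).all()),
        "pairwise_distance": dist_summ,
        "burst_frequency_median_difference": diff["frequency_median_difference"],
        "burst_size_median_difference": diff["size_median_difference"],
        "burst_frequency_ks": diff["frequency_ks"],
        "burst_size_ks": diff["size_ks"],
        "regression": regression.to_dict(orient="records"),
        "target_comparison": target_stats,
        "category_counts": category_counts.to_dict(orient="records"),
        "stemness": stemness.to_dict(orient="records"),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                   default=float) + "\n")
    return report
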