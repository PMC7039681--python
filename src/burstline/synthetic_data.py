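"""Synthetic two-condition scRNA-seq experiment with known telegraph truth.

Emulates a WT/KO genotype contrast in which a designated subset of target
genes has its promoter activation rate alpha reduced in KO (default halved)
while, optionally, the transcription rate gamma is rescaled so the stationary
mean is preserved — reduced burst frequency at constant mean, the regime in
which expression noise rises.  Technical capture is modeled as binomial
thinning, which keeps counts Poisson-Beta (gamma -> efficiency * gamma).

Alongside the two count matrices the generator emits a TSS table and BED
peak files (H3K4me3 / H3K9ac / H3K27ac per genotype) in which target-gene
promoters carry H3K9ac without H3K27ac in WT and lose H3K9ac in KO — the
structure the promoter-acetylation classifier is designed to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .burst_model import TelegraphParams
from .qc_filtering import CountMatrix, write_matrix

__all__ = [
    "SimConfig",
    "sample_stationary_counts",
    "apply_capture",
    "generate_experiment",
    "write_experiment",
]


@dataclass
class SimConfig:
    """Configuration of one synthetic two-genotype experiment.

    Defaults give 1000 genes x 1000 cells per genotype, 20% target genes with
    burst frequency halved in KO at preserved mean, and 30% UMI capture.
    Per-gene rates are drawn log-normally: log10 rate ~ Normal(log10 loc,
    spread), with loc alpha=0.3, beta=2, gamma=20 and spread 0.5 dex, which
    spans bursty (alpha << beta) through near-Poisson regimes.
    """

    n_genes: int = 1000
    n_cells_per_condition: int = 1000
    target_fraction: float = 0.2
    frequency_effect: float = 0.5
    mean_preserving: bool = True
    capture_efficiency: float = 0.3
    param_priors: dict = field(default_factory=lambda: {
        "alpha_loc": 0.3, "beta_loc": 2.0, "gamma_loc": 20.0, "spread": 0.5,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_condition < 1:
            raise ValueError("n_genes and n_cells_per_condition must be positive")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must be in [0, 1]")
        if not 0.0 < self.capture_efficiency <= 1.0:
            raise ValueError("capture_efficiency must be in (0, 1]")
        if self.frequency_effect <= 0:
            raise ValueError("frequency_effect must be positive")


def sample_stationary_counts(params: TelegraphParams, n_cells: int, seed=None) -> np.ndarray:
    """Draw i.i.d. stationary telegraph counts via the Poisson-Beta mixture.

    count ~ Poisson(gamma * u) with u ~ Beta(alpha, beta); the empirical
    mean converges to gamma * alpha / (alpha + beta).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.beta(params.alpha, params.beta, size=n_cells)
    return rng.poisson(params.gamma * u)


def apply_capture(counts, efficiency: float, seed=None) -> np.ndarray:
    """Binomial thinning of integer counts; expected mean scales by efficiency."""
    if not 0.0 < efficiency <= 1.0:
        raise ValueError(f"capture efficiency must be in (0, 1], got {efficiency}")
    counts = np.asarray(counts)
    if efficiency == 1.0:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.binomial(counts, efficiency)


def _sample_gene_params(config: SimConfig, rng: np.random.Generator) -> list[TelegraphParams]:
    pri = config.param_priors
    spread = pri["spread"]
    logs = rng.normal(
        loc=np.log10([pri["alpha_loc"], pri["beta_loc"], pri["gamma_loc"]]),
        scale=spread, size=(config.n_genes, 3),
    )
    rates = 10.0 ** logs
    return [TelegraphParams(*row) for row in rates]


def _ko_params(wt: TelegraphParams, config: SimConfig) -> TelegraphParams:
    alpha_ko = wt.alpha * config.frequency_effect
    gamma_ko = wt.gamma
    if config.mean_preserving:
        # rescale gamma so gamma*alpha/(alpha+beta) is unchanged; the single
        # ratio keeps the null effect (factor 1) an exact no-op
        ratio = (wt.alpha * (alpha_ko + wt.beta)) / (alpha_ko * (wt.alpha + wt.beta))
        gamma_ko = wt.gamma * ratio
    return TelegraphParams(alpha=alpha_ko, beta=wt.beta, gamma=gamma_ko)


def generate_experiment(config: SimConfig):
    """Simulate the full two-genotype experiment.

    Returns ``(wt, ko, truth, tss, peaks)`` where ``wt``/``ko`` are
    CountMatrix objects, ``truth`` is the per-gene TruthTable DataFrame,
    ``tss`` the TSS annotation DataFrame and ``peaks`` a dict mapping
    ``(mark, genotype)`` to BED-interval DataFrames.
    """
    rng = np.random.default_rng(config.seed)
    n_targets = int(round(config.target_fraction * config.n_genes))
    if config.target_fraction > 0 and n_targets == 0:
        warnings.warn("target_fraction * n_genes < 1; simulating zero target genes")
    gene_ids = np.array([f"gene{i:05d}" for i in range(config.n_genes)], dtype=object)
    target = np.zeros(config.n_genes, dtype=bool)
    target[rng.choice(config.n_genes, size=n_targets, replace=False)] = True

    wt_params = _sample_gene_params(config, rng)
    ko_params = [
        _ko_params(p, config) if is_t else p
        for p, is_t in zip(wt_params, target)
    ]

    n = config.n_cells_per_condition
    eff = config.capture_efficiency
    mats = {}
    for label, plist in (("WT", wt_params), ("KO", ko_params)):
        rows = np.empty((config.n_genes, n), dtype=np.int64)
        for i, p in enumerate(plist):
            raw = sample_stationary_counts(p, n, seed=rng)
            rows[i] = apply_capture(raw, eff, seed=rng)
        mats[label] = CountMatrix(
            sparse.csr_matrix(rows), gene_ids,
            np.array([f"{label}_cell{j:05d}" for j in range(n)], dtype=object),
            np.repeat(label, n),
        )

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "target": target,
        "alpha_WT": [p.alpha for p in wt_params],
        "beta_WT": [p.beta for p in wt_params],
        "gamma_WT": [p.gamma for p in wt_params],
        "alpha_KO": [p.alpha for p in ko_params],
        "beta_KO": [p.beta for p in ko_params],
        "gamma_KO": [p.gamma for p in ko_params],
        "mean_WT": [p.mean * eff for p in wt_params],
        "mean_KO": [p.mean * eff for p in ko_params],
        "burst_size_WT": [p.burst_size for p in wt_params],
        "burst_size_KO": [p.burst_size for p in ko_params],
        "burst_frequency_WT": [p.burst_frequency for p in wt_params],
        "burst_frequency_KO": [p.burst_frequency for p in ko_params],
    })

    tss, peaks = _make_annotation(gene_ids, target)
    return mats["WT"], mats["KO"], truth, tss, peaks


# genes are laid out on a synthetic genome: round-robin over 19 autosomes,
# one TSS per 10 kb, strands alternating
_N_CHROM = 19
_TSS_SPACING = 10_000
_PEAK_HALF = 250  # peaks are 500 bp centered on the promoter window


def _make_annotation(gene_ids: np.ndarray, target: np.ndarray):
    n = len(gene_ids)
    chroms = np.array([f"chr{(i % _N_CHROM) + 1}" for i in range(n)], dtype=object)
    pos = np.array([_TSS_SPACING * (i // _N_CHROM + 1) for i in range(n)])
    strand = np.array(["+" if i % 2 == 0 else "-" for i in range(n)], dtype=object)
    tss = pd.DataFrame({"gene_id": gene_ids, "chrom": chroms, "pos": pos, "strand": strand})

    # promoter window center: +strand [t-1000, t+500) -> center t-250; mirrored on -
    center = np.where(strand == "+", pos - 250, pos + 250)
    start = np.maximum(center - _PEAK_HALF, 0)
    end = center + _PEAK_HALF
    all_peaks = pd.DataFrame({"chrom": chroms, "start": start, "end": end})

    peaks = {}
    for genotype in ("WT", "KO"):
        peaks[("H3K4me3", genotype)] = all_peaks.copy()
        k9_mask = np.ones(n, dtype=bool) if genotype == "WT" else ~target
        peaks[("H3K9ac", genotype)] = all_peaks[k9_mask].reset_index(drop=True)
        # K27ac marks only non-target promoters, so targets are K9only in WT
        peaks[("H3K27ac", genotype)] = all_peaks[~target].reset_index(drop=True)
    return tss, peaks


def write_experiment(config: SimConfig, outdir) -> dict:
    """Run generate_experiment and persist every artifact under ``outdir``.

    Layout: ``wt/``, ``ko/`` MTX triplets, ``truth.tsv``, ``tss.tsv`` and
    ``peaks/<mark>_<genotype>.bed``.  Deterministic: the same config (seed
    included) produces byte-identical files.
    """
    from .chip_targets import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wt, ko, truth, tss, peaks = generate_experiment(config)
    paths = {
        "wt": write_matrix(wt, outdir / "wt"),
        "ko": write_matrix(ko, outdir / "ko"),
        "truth": outdir / "truth.tsv",
        "tss": outdir / "tss.tsv",
    }
    truth.to_csv(paths["truth"], sep="\t", index=False)
    tss.to_csv(paths["tss"], sep="\t", index=False)
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for (mark, genotype), table in peaks.items():
        p = peak_dir / f"{mark}_{genotype}.bed"
        write_bed(table, p)
        paths[f"{mark}_{genotype}"] = p
    return paths
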