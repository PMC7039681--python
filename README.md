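# burstline

Transcriptional-noise and promoter-bursting analysis for two-genotype
single-cell RNA-seq experiments, with an integrated promoter
histone-acetylation target classifier and a telegraph-model simulator.

## What it is for

Loss of a promoter-bound histone acetyltransferase (e.g. Kat2a/Gcn5) can
leave average gene expression almost unchanged while making expression
*noisier*: cell-to-cell variability rises because promoters fire less often
(lower burst frequency) even when each firing produces a similar number of
transcripts (unchanged burst size). `burstline` packages the analysis needed
to detect and dissect that phenotype from UMI count matrices of two
genotypes (WT vs knockout) plus ChIP-seq peak calls:

1. **Robust filtering** — keep cells with ≥ 500 detected genes, then genes
   detected in ≥ 10% of all retained cells (thresholds configurable).
2. **Noise metrics** — per-gene mean, SD, CV = σ/μ; KS / Mann-Whitney /
   Welch comparisons between genotypes; CV compared within deciles of mean
   expression; distance-to-median (DM) selection of highly variable genes;
   gene–gene pairwise distance 1 − ρ (Spearman) as a dispersion measure.
3. **Burst inference** — fit the two-state (telegraph) promoter model per
   gene per genotype and compare burst size and frequency distributions,
   including the per-gene relative frequency differential
   Fburst = (f_KO − f_WT) / f_WT, and a regression decomposition of
   log mean and log CV onto log s and log f.
4. **Acetylation targets** — classify promoters (−1 kb to +500 bp of each
   TSS, strand-aware) by H3K9ac/H3K27ac overlap at H3K4me3 promoters per
   genotype, call genes whose promoters are H3K9ac-only in WT and lose
   H3K9ac in KO, and test whether those targets show a stronger bursting
   change.
5. **Stemness scoring** — k-medoids clustering on 1 − Spearman distance,
   per-cell transcriptome entropy H = −Σ pᵢ ln pᵢ, significant
   inter-cluster links by a medoid-line projection permutation test, and a
   per-cluster stemness score = median entropy × number of links.
6. **Synthetic data** — a generator that simulates the whole experiment
   from known telegraph parameters (including BED peak files whose
   WT-exclusive H3K9ac promoters are the target genes), so every stage is
   verifiable by parameter recovery.

## The model

The telegraph model describes a promoter switching OFF→ON at rate α and
ON→OFF at rate β, transcribing at rate γ while ON; mRNA degrades at unit
rate (all rates in units of the degradation rate). The stationary mRNA
count is Poisson-Beta:

    X ~ Poisson(γ·u),  u ~ Beta(α, β)

with burst size s = γ/β, burst frequency f = αβ/(α+β), and mean = s·f =
γα/(α+β) exactly. Fitting is closed-form inversion of the first three
factorial moments (E[X⋯(X−k+1)] = γᵏ(α)ₖ/(α+β)ₖ) with optional
maximum-likelihood refinement in log-parameter space; the pmf is evaluated
through the confluent-hypergeometric representation in log space. Genes
whose moments admit no positive solution get a flagged Poisson fallback so
gene universes stay aligned across genotypes.

## Worked example

Simulate a small two-genotype experiment in which 20% of genes have their
burst frequency halved in KO at preserved mean, then run the full pipeline:

```python
from burstline.pipeline import PipelineConfig, run_pipeline
from burstline.synthetic_data import SimConfig

config = PipelineConfig(
    outdir="example_run",
    simulation=SimConfig(n_genes=300, n_cells_per_condition=400, seed=7),
    min_genes_per_cell=30, n_hvg=100, k_clusters=3,
    n_link_permutations=100, seed=7)
report = run_pipeline(config)

print(f"robust gene set: {report['filter']['n_genes_out']} genes, "
      f"{sum(report['filter']['n_cells_out'].values())} cells")
print(f"CV median difference (KO - WT): {report['cv_comparison']['median_difference']:.3f}")
fb = report["target_comparison"]["Fburst"]
print(f"median Fburst, targets:     {fb['median_targets']:.3f}")
print(f"median Fburst, non-targets: {fb['median_non_targets']:.3f}")
print(f"Mann-Whitney p (targets vs non-targets): {fb['pvalue']:.2e}")
```

Output:

```
robust gene set: 252 genes, 800 cells
CV median difference (KO - WT): 0.144
median Fburst, targets:     -0.488
median Fburst, non-targets: 0.000
Mann-Whitney p (targets vs non-targets): 3.27e-08
```

Reading: expression noise (CV) rises in KO; the per-gene burst-frequency
differential is ≈ −0.5 for the genes whose activation rate was halved and
≈ 0 elsewhere, and the rank test separates the two groups decisively. The
same numbers are persisted in `example_run/report.json` together with every
intermediate table (filtered matrix, per-gene stats, telegraph fits,
promoter annotation, stemness scores).

The same stages are available from the shell:

```sh
burstline simulate --config sim.yaml --outdir data/
burstline filter --wt data/wt --ko data/ko --outdir filtered/
burstline burst --matrix filtered/ --out fits/burst
burstline targets --tss data/tss.tsv --k4me3-wt ... --out annotation.tsv
burstline run --config pipeline.yaml
```

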