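# Methods

## The telegraph model and its parameterization

A gene's promoter is a two-state Markov switch: OFF→ON at rate α, ON→OFF at
rate β, transcription at rate γ while ON, and first-order mRNA degradation.
All rates are expressed in units of the degradation rate (degradation ≡ 1),
so parameters are dimensionless and comparable across genes. At
stationarity the mRNA count is Poisson-Beta distributed,
X ~ Poisson(γu) with u ~ Beta(α, β).

Burst parameters follow the identity-consistent convention: burst size
s = γ/β (expected transcripts per ON period) and burst frequency
f = αβ/(α+β), chosen so that mean = s·f = γα/(α+β) holds exactly — every
fit in the package satisfies this identity to machine precision, which
downstream consumers (the regression decomposition, the differential
tables) rely on. α is also exported per fit, so the alternative convention
that equates burst frequency with α alone can be compared directly.

In the bursty regime (α ≪ β) noise decomposes as CV² ≈ 1/mean · (1 + s)
· (...), so at fixed mean a lower f (and correspondingly higher s) raises
CV: this is the signature the pipeline is designed to detect, and the
direction the CV regression quantifies.

## pmf evaluation

P(X=k) = γᵏ/k! · B(α+k, β)/B(α, β) · e^(−γ) · ₁F₁(β; α+β+k; γ), i.e. the
confluent-hypergeometric form after the Kummer transformation, which makes
the ₁F₁ argument positive so its series has only positive terms. The series
is summed by logsumexp with truncation past its mode (j ≈ γ), giving
normalization error < 1e−8 (measured ~1e−15) and no overflow anywhere on
the tested grid α, β ∈ [1e−2, 1e2], γ ∈ [1e−1, 1e3]. The term matrix is
chunked so memory stays bounded for large γ.

## Fitting

1. **Moments.** The first three factorial moments of the Poisson-Beta law,
   E[X(X−1)⋯(X−k+1)] = γᵏ(α)ₖ/(α+β)ₖ, invert in closed form (the r1, r2, r3
   ratio construction; verified symbolically before implementation and
   tested against exact analytic moments). The fitted mean always equals
   the empirical mean by construction.
2. **MLE.** Nelder-Mead on (log α, log β, log γ) starting from the moment
   fit, tolerance 1e−6, ≤ 500 iterations, search domain bounded to rates in
   [1e−4, 1e4] (far outside any UMI-scale fit; the bound keeps pmf series
   lengths sane). The fit is deterministic — no seeds — and returns the
   initializer with `converged=False` if the optimizer fails to improve the
   likelihood, never silently.

Degenerate inputs are handled in two distinct ways:

- **Infeasible moments** (no positive-rate solution; common for weakly
  expressed genes): flagged fallback to a near-Poisson parameterization
  α = β = 1e4, γ matched to the mean — the frequent-tiny-burst limit, s→0 —
  with `feasible=False`. Genes are never dropped, so gene universes remain
  aligned between conditions.
- **Near-Poisson data**: when the telegraph likelihood improves on a plain
  Poisson fit by < 2 log-units, the fit carries `near_poisson=True`. On
  this likelihood ridge s and f are not identifiable (many (α, β, γ) fit
  equally well) and should not be interpreted quantitatively.

Distribution-level comparisons (KS on f and s, median differences) exclude
genes that are infeasible in either condition: the fallback contributes
constant atoms that would otherwise dominate the KS statistic and turn it
into a test of the feasibility *rate*. Per-gene differential tables keep
every gene, with a `feasible_both` column.

Counts are depth-normalized to the median library size and rounded back to
integers before fitting (the stationary law is a count distribution);
cluster-restricted fits renormalize within the cluster.

## Noise metrics

- Expression for mean/CV is library-size-normalized (per-cell scaling to
  the median total of retained cells); SD uses the n−1 denominator; CV is
  flagged undefined at zero mean rather than raising.
- Binned CV comparison uses decile bins of log10 mean over the pooled gene
  set (10 bins by default); bins with < 3 genes on either side are flagged
  and contribute no p-value. With one bin it reproduces the global KS
  comparison exactly.
- DM (distance-to-median) is the residual of log10 CV² against a running
  median over 50 genes ordered by log10 mean, clipped at the edges. It is
  invariant to a global depth factor, near-zero with no mean-rank trend for
  Poisson genes, and ties in the top-n selection break by gene id so the
  selection is deterministic.
- Pairwise gene distance is 1 − Spearman ρ (average ranks on ties) over
  cells of one condition, in [0, 2]; an alternative metric (Euclidean
  distance between correlation-matrix rows) is available behind a flag.
  Pairs involving zero-variance genes are excluded and counted.

## Promoter classification

Promoters are −1 kb/+500 bp windows around each TSS, strand-aware, clamped
at 0; coordinates are BED-style 0-based half-open throughout and overlap
means ≥ 1 bp intersection (bedtools-intersect default). A promoter is
assessable in a genotype iff it overlaps an H3K4me3 peak of that genotype;
its category (K9only / K27only / dual / none) comes from that genotype's
acetylation peaks, and categories partition assessable promoters. A target
is a promoter that is K9only in WT with no overlap of *any* KO H3K9ac peak
(any KO H3K9ac contradicts a unique loss). Genes with multiple TSS get one
window per TSS and are targets if any window is. Overlap queries go through
an interval tree and are tested against a brute-force all-pairs oracle.

## Clustering and stemness

Cells are clustered by PAM-style k-medoids on 1 − Spearman distance over
highly variable genes; initialization draws medoids from the seeded RNG,
so labels are deterministic given the seed. k is user-chosen (the cluster
count of the original analyses depended on a specific clustering tool's
internal criterion and is not reproduced).

Transcriptome entropy is H = −Σ pᵢ ln pᵢ over a cell's expression
proportions (natural log; the base only rescales scores uniformly).
Inter-cluster links use a simplified medoid-line projection: each cell is
projected onto the lines from its cluster medoid to all other medoids, and
supports the link whose line it is closest to with a strictly interior
projection (an epsilon guard excludes cells sitting exactly on a medoid,
which would otherwise flip between t=0/1 by floating-point path). A link is
significant when its supporting count exceeds the 95th percentile of a
label-permutation null (medoid positions fixed; 1000 permutations by
default, seeded). Stemness = median member entropy × number of significant
links; singleton clusters score zero links. This is a deliberately
simplified re-implementation of cluster-graph stemness scoring — no outlier
reassignment, no embedding-based layout.

## Synthetic experiment generator

The generator emulates the WT/KO contrast the pipeline targets: per-gene
rates drawn log-normally (medians α = 0.3, β = 2, γ = 20; spread 0.5 dex),
spanning bursty through near-Poisson regimes at UMI-scale means; 1000 genes
× 1000 cells per condition by default — desk-scale but large enough for
distributional tests; 20% target genes whose α is multiplied by 0.5 in KO;
mean-preserving mode rescales γ by a single exact ratio so target means
match between conditions to machine precision (and frequency_effect = 1 is
an exact no-op). Capture is binomial thinning at 30% efficiency — the
simplest model that keeps counts Poisson-Beta (γ → εγ), so thinning scales
burst size by ε and leaves burst frequency untouched. Sampling uses the
stationary Poisson-Beta mixture directly; an exact continuous-time Gillespie
simulation of the same process is kept as an independent test oracle
(equivalence within total-variation 0.01 at 1e5 draws).

Peak files encode the target structure: all promoters carry H3K4me3 in both
genotypes; H3K9ac covers all promoters in WT but omits targets in KO;
H3K27ac covers exactly the non-targets, so targets are K9only in WT. Genes
are laid on a synthetic genome (19 chromosomes, one TSS per 10 kb,
alternating strands) with 500 bp peaks centered on the promoter windows.
Identical config (seed included) yields byte-identical output files.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, cell-cycle or lineage structure, gene-gene correlation (genes are
independent given their parameters), or partial/graded acetylation loss.
Passing tests therefore demonstrate correctness of the estimators and
classifiers under the stated generative model, not robustness to every
artifact of real droplet data.

## Filtering semantics

Cells are filtered first (≥ 500 detected genes, counted on the full gene
universe), then genes (detected in ≥ 10% of retained cells, both conditions
pooled; the 10% bound is inclusive — "fewer than 10%" is removed). This
order makes the filter idempotent, and both thresholds are monotone:
raising either never adds genes or cells. A per-condition gene filter
(pass in both conditions) is available behind a flag. Synthetic runs use a
scaled cell threshold (50 detected genes) matching the generator's
1000-gene, 30%-capture depth.

## Statistical tests and problem sizes

Genotype comparisons use two-sided KS (distribution shape), Mann-Whitney
(rank shifts between gene groups), and Welch's t (means of distance
distributions), all from scipy.stats; the regression decomposition is OLS
(statsmodels) of log10 mean and log10 CV on log10 s and log10 f. Where a
called-differential count is requested, Benjamini-Hochberg at 0.05 is
applied. The acceptance script runs the pmf checks at 1e5 draws, parameter
recovery at 200 genes × 1000 cells, and the full contrast at the
generator's default 1000 × 1000 scale; the worked example in the README
uses a smaller instance (300 genes × 400 cells) chosen to run in seconds.

A note on detection power at this design: the frequency perturbation is
confined to 20% of genes, so a KS test over the *entire* gene set has an
effect size of at most a few percent of CDF mass and does not reach
significance even with error-free parameter estimates; restricted to the
perturbed genes it is decisive (p < 1e−4 at truth, p < 5e−3 with moment
fits). The acceptance script reports both. Likewise, because the design
preserves means, burst size on perturbed genes rises by exactly the factor
frequency falls, so a size contrast exists in truth but is detectable only
on the perturbed subset and only marginally — size estimates are noisier
than frequency estimates at these depths.
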