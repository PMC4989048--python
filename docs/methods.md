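# Methods

This note documents the statistical models, the synthetic-data generators,
the numerical choices and the known limitations of the package. All
defaults named here are the package's own working points; every empirical
claim below is computed by the test suite or by `scripts/acceptance.py`.

## Paired negative-binomial differential expression

Counts are modelled per gene as NB(μ, α) with the mean–dispersion
parameterisation Var = μ + αμ². The log-linear predictor contains an
intercept, patient indicators (the paired design: one damaged-site and one
intact-site sample per patient), the damaged-vs-intact site indicator
whose coefficient is the reported log2 fold change, and optionally k
unwanted-variation factor scores. Library depth enters as an offset of
log size factors computed by the median-of-ratios rule over genes positive
in every sample.

*Dispersion.* Per gene, a Poisson fit provides fitted means; α then solves
the Pearson moment equation Σ(y−μ̂)²/(μ̂+αμ̂²) = n−p (monotone in α, solved
by bisection), which corrects for the residual degrees of freedom consumed
by the design. A smooth trend α(m) = a₀ + a₁/m is fitted across genes and
each gene's estimate is shrunk 50/50 toward the trend on the log scale,
clipped to [1e−8, 10].

*Test.* The Wald statistic for the site coefficient uses the expected-
information standard error from the converged IRLS fit and is referred to a
t distribution with residual-plus-prior degrees of freedom. The prior df
(default 10) credits the variance moderation the trend shrinkage provides;
it was fixed once by matching the empirical null tail of the statistic
(the p < 0.01 … p < 0.001 quantiles) on null simulations of the default
8-patient design, where the plain normal reference is anticonservative and
the bare residual-df t is conservative. p-values are Benjamini–Hochberg
adjusted; DEGs are called with inclusive thresholds, fold change ≥ 1.5 and
adjusted p ≤ 0.10 by default (0.05 supported).

*Unwanted variation.* First-pass (uncorrected) p-values rank genes; all but
the `n_exclude` most significant (default 5,000, clamped to half the gene
count on small studies) serve as in-silico negative controls. Factor scores
are the top-k right-singular directions of the row-centred log(normalised
control counts + 0.5) matrix; k defaults to 1 and is configurable because
the appropriate number of nuisance factors is study-specific. A known
limitation, exercised by the tests: when a batch is almost perfectly
confounded with the site contrast, the exclusion rule removes exactly the
batch-responsive genes (they look differential), leaving the factor
unidentifiable from the remaining controls. With realistic partial
confounding the factor tracks the batch (|r| ≈ 0.98 in the stress test)
and measurably reduces null inflation.

*Pseudocount.* 0.5 in every log transform of counts.

*Units.* FPKM = count / (gene length in kb × mapped reads in millions).
qPCR relative expression uses 2^−ΔΔCt with the reference Ct taken as the
arithmetic mean of two housekeeping genes per condition.

## Phenotype-guided sub-network discovery

The heterogeneous network has protein and phenotype nodes and three edge
layers (PPI, phenotype–phenotype, protein–phenotype), all weighted, with
the PPI layer restricted to expressed genes. Cross-layer edges are weighted
on the same scale as intra-layer ones (no re-weighting; the ontology layer
is small relative to the PPI layer, and all acceptance properties concern
calibration and recovery, not specific constants).

*RWR.* The walk follows the column-normalised weighted adjacency and
restarts with probability r = 0.7 (configurable) to the uniform
distribution over the seed phenotypes; iteration stops when successive
iterates differ by < 1e−10 in L1 (dangling nodes teleport to the seeds so
probability is conserved). The iterate agrees with the direct solve of
(I − (1−r)W)s = re to < 1e−8 on every tested graph.

*Node scores.* DE score = −log10(adjusted p) × |log2FC|, capped at 10 so a
single extreme gene cannot dominate a candidate. The combined score is the
product of the min–max-scaled DE score and the min–max-scaled RWR
probability over protein nodes: a protein must be both differential and
phenotype-proximal to score highly.

*Candidate growth.* Proteins are ranked by combined score; from each
top-ranked protein not yet in a candidate, the neighbour maximising the
candidate's mean combined score is added (ties lexicographic) until the
size cap (default 7) or until the best neighbour's own score drops below
0.25 × the current candidate mean. The relative-score stop keeps
candidates homogeneously hot; a strict "mean must increase" rule can never
grow past a locally maximal seed and was rejected for that reason.
Membership is exclusive by default (a protein joins at most one candidate);
without exclusivity, overlapping candidates around a hot region chain into
one oversized component at the merge step.

*Empirical p.* Each candidate's mean combined score is compared with
n (default 10,000) size-matched connected sub-networks sampled from the PPI
layer by random-walk growth from uniformly chosen eligible start nodes;
p = (1 + #{null ≥ observed})/(n + 1). Because null and observed
sub-networks are sampled identically, the p-value is uniform under the
null (KS-tested in the acceptance suite). Candidates at p ≤ 0.05 are
merged when they share a protein (merged p = min of members) and annotated
with the minimum-p GO-style term by a one-sided hypergeometric test over
the collection's universe, ties resolved alphabetically.

## Multi-evidence TF inference

*Motif channel.* Promoters are scanned on both strands with log2-odds PWMs
against the background composition. Matches scoring ≥ 6 bits count as
hits; hits are made non-overlapping greedily by descending score and the
promoter's cluster score is the maximum over sliding 500 bp windows of the
sum of retained hits. The hit threshold separates sparse strong matches
from the diffuse background of weak ones — without it, sums of many weak
hits drown single genuine sites. Per species, genes are ranked by cluster
score (average ranks on ties); rankings are combined by robust rank
aggregation: each gene's normalized ranks (against the full gene universe;
genes missing from a list get rank 1) are sorted, the k-th order statistic
is referred to Beta(k, L−k+1), and rho = L × the minimum tail probability,
clipped to 1. The aggregate matches exhaustive order-statistic enumeration
to 1e−12.

*AUC recovery and z-scores.* For a ranked list and a gene set,
AUC = (1/(X·|S|)) Σᵢ₌₁..X |S ∩ top-i| with X = ⌈0.03 n⌉ (top 3% of the
ranking, configurable). AUCs are z-scored across the channel's whole
motif/TF collection; a channel passes at z ≥ 3 (inclusive). Note the
arithmetic constraint: the largest attainable z among n values is
(n−1)/√n, so collections need ≳ 40 members for the threshold to be
reachable when several true positives share a high AUC — the synthetic
bundle therefore carries 60 TFs with 4 planted.

*Text-mining channel.* Per TF, the overlap of its mined targets with the
DEG set is tested by a one-sided hypergeometric over the gene universe,
BH-adjusted across TFs, passing at q ≤ 0.1.

*Integration.* A TF is selected when ≥ 2 channels pass. Its regulon is the
set of DEGs inside the top X of its best-passing (highest-z) ranked list;
for a TF supported only by text-mining, the mined DEG overlap is used.
TF→TF edges are emitted when a selected TF lies in the top X of another's
best ranking. Up- and down-regulated DEG sets are analysed separately and
the selected TFs and targets union-reported. The overlap of the pooled
regulon targets with the sub-network genes is a one-sided hypergeometric
p over the evidence universe.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the pipeline assumes,
at desk scale (sizes chosen so the full suite runs on one CPU in minutes):

- **Counts** (default 2,000 genes, 8 patients): log-normal baseline means
  (meanlog 4, sdlog 2, natural logs) for RNA-seq's dynamic range; a
  per-patient log-normal multiplier (sd 0.2) that makes the paired
  covariate necessary; uniform residual dispersions in (0.01, 0.3) — the
  within-joint scale relevant conditional on the patient effect, which is
  what a patient-adjusted NB model estimates; 10% DE genes at ±1 log2
  unit; a batch shift of 1 log2 unit on 20% of genes, nested within
  patient by default (paired samples are normally processed together) with
  a configurable probability of batch–site confounding as the stress case;
  library sizes in (0.8, 1.2) × 10⁶, far below real sequencing depth but
  preserving the relative-count structure.
- **Network**: preferential-attachment PPI (heavy-tailed degrees), a
  shallow phenotype tree, and a connected planted module whose genes are
  annotated to 4 seed phenotypes.
- **Evidence bundle** (default 60 TFs, 500 genes, 3 pseudo-species,
  600 bp promoters): exact consensus insertions in true-target promoters
  on random strands/offsets; ChIP scores shifted +5 SD for true targets;
  text-mined edges covering targets plus equal noise; coexpression ≈ 0.8
  for TF–target pairs against a 0.15-SD background.

Not emulated: realistic promoter base composition, read-level error,
annotation incompleteness, correlated gene–gene expression structure
beyond the planted signals, and real ontologies. Passing tests therefore
demonstrate correctness and calibration of the algorithms under the
assumed generative structure, not performance on real tissue data.

## Numerical conventions

- IRLS for the NB GLM: linear predictor clipped to ±30, ridge 1e−10 on the
  normal equations, convergence at 1e−8 in the coefficients, 50 iterations
  maximum.
- All tie-breaks (gene ranking, candidate growth, GO terms) are
  lexicographic; every stochastic routine takes an explicit seed or
  generator, and the pipeline derives per-stage sub-streams from one
  master seed via `SeedSequence.spawn`.
- Empirical p-values use the add-one rule (1 + exceedances)/(n + 1) and so
  never return 0.
- All-zero genes are reported with missing fold change and p-value and are
  excluded from BH adjustment.

## Problem sizes used by the checks

The acceptance suite runs the paired-DE error-rate check at 2,000 genes ×
20 replicates, empirical-p calibration at 500 null candidates × 1,000
samples on a 300-node PPI, the RWR oracle on 50 random graphs of ≤ 100
nodes, planted-module recovery on two coordinated studies, and TF
selection on 20 planted and 200 null evidence bundles (the null bundles at
a compact 40 TF × 200 gene configuration). `scripts/acceptance.py` uses
the same conditions with slightly fewer replicates.
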