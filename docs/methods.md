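# Methods

`msub` re-implements, as a tested pipeline over synthetic cohorts, the
integrative DNA-methylation subtyping workflow used to characterise
hypomethylated, driver-inactivated subtypes of squamous cell carcinoma:
beta-mixture calling of abnormal methylation states against matched normal
tissue, consensus k-means subtype discovery, nearest-shrunken-centroid
(NSC/PAM) subtype classification with cross-cohort transfer, and
CpG-signature overlap statistics tied to a driver lesion score.

## Preprocessing

Input tables are TSV: a probes × samples beta-value matrix in [0, 1] with
tumor/normal labels, a genes × samples expression matrix (log2(x+1)
convention), a MAF-like mutation table, a GISTIC-thresholded copy-number
table and a BED-like probe manifest. Rows and columns whose missing fraction
strictly exceeds a threshold are removed — 20% for methylation, 10% for
expression — rows first, then columns, iterated to a fixed point so the
output satisfies both bounds (a single row-then-column pass can leave rows
above threshold after columns drop, and would not be idempotent). Remaining
gaps are KNN-imputed (default k = 15): each missing cell takes the mean of
the k nearest rows observing that column, with Euclidean distance over
co-observed columns rescaled for coverage (the standard KNNimpute
convention). Mutations flagged silent are removed before any counting. A
batch-correction hook exists but deliberately raises: batch structure is out
of scope here.

## Probe clustering

To reduce multiple testing over co-methylated probes, each gene's probes are
clustered by complete-linkage hierarchical clustering on d = 1 − Pearson r
across samples, cutting the tree at height 0.4 (configurable). The distance
is our choice — the linkage is standard for this step, and correlation
distance matches how co-regulated CpGs behave on arrays; d = 0.4
corresponds to r = 0.6 within a cluster. Zero-variance probes have no
defined correlation and are isolated as singletons with a warning; probes
annotated to several genes are duplicated into each gene's pool, since genes
are modelled independently. Cluster methylation is the unweighted mean beta
of member probes.

## Beta-mixture state calling

Per CpG cluster, tumor beta values (clamped to [1e-6, 1 − 1e-6]) are fitted
with mixtures of beta distributions for K = 1, 2, 3; the fit minimising
BIC = −2·loglik + (3K − 1)·ln n is kept. The EM uses an exact E-step and a
Newton-ascent M-step on the weighted beta log-likelihood (three backtracked
Newton steps per iteration), which makes it a monotone generalized EM: the
observed-data log-likelihood never decreases. Numerical choices:

- initialisation: deterministic quantile split of the sorted values plus
  three seeded random restarts; components are always reported sorted by
  mean, so labelling is canonical;
- convergence: tolerance 1e-6 on the log-likelihood, at most 500
  iterations, plus a parameter-stall stop;
- degenerate fits: when two component means come within 0.05 the
  components will be merged anyway, so the EM stops early on that ridge
  (collapse is otherwise extremely slow) and the merged model is refitted at
  lower K; shape parameters are capped at 1e4 to stop a near-singular
  component concentrating on a handful of identical values;
- components closer than 0.05 in mean are merged before model selection
  (parsimony mirroring the cited state-calling method).

Each component's DM value is its mean minus the normal-tissue mean beta; a
tumor sample takes the state of its maximum-posterior component: hypo if
DM ≤ −0.10, hyper if DM ≥ +0.10, normal otherwise. The 0.10 threshold
stands in for the upstream method's differential test and is recorded in
output metadata. A cluster is called abnormal only if at least one component
is differential *and* cluster methylation is inversely coupled with the
gene's expression across tumors (Pearson r ≤ −0.3, p < 0.05, defaults) —
methylation changes without a transcriptional echo are ignored.

## Consensus subtyping

Tumors are clustered on their DM-value profiles over abnormal clusters (0
for the normal state; a {−1, 0, 1} state encoding is available by config).
For each k in 2..k_max, k-means (k-means++, 10 restarts) runs on repeated
80% sample subsamples; the consensus entry for a pair is its co-clustering
count over its co-sampling count, and final assignments cut an
average-linkage tree on 1 − consensus. The cluster number is selected by
PAC, the fraction of off-diagonal consensus entries in (0.1, 0.9), as an
automated surrogate for reading consensus CDF plots. Pure PAC minimisation
under-segments: merging two true clusters consistently is also "stable"
(PAC 0), so we take the **largest** k whose PAC ties the minimum within
0.01 — beyond the true k, forced splits become subsample-dependent and PAC
rises sharply. A near-flat PAC profile (spread < 0.05) means no structure;
k = 2 is returned with an inspect flag. The package default is 1000
resampling rounds with k up to 10; the bundled analyses and the acceptance
script use 200 rounds with k up to 6, which gives byte-identical partitions
on these cohort sizes at a fraction of the cost.

Driver enrichment in a subtype is Pearson's chi-squared on the
in-subtype/out-of-subtype 2×2 table, without continuity correction.

## NSC classification and transfer

The subtype classifier is a nearest-shrunken-centroid model in the
Tibshirani (2002) parameterisation: standardised centroid contrasts
d_ik = (x̄_ik − x̄_i) / (m_k (s_i + s0)) are soft-thresholded by Δ,
d′_ik = sign(d_ik)(|d_ik| − Δ)₊, jointly selecting features and shrinking
centroids; s0 is the median of the pooled within-class deviations s_i and
guards constant features. Class posteriors are exp(−δ_k/2) over the
discriminant scores with equal priors by default (cohort prevalences are
study-specific). Δ is chosen by 5-fold inner cross-validation minimising
error, preferring larger Δ on ties. Performance is stratified 10-fold CV
AUC; both the pooled-score AUC and the per-fold mean are reported, since
either pooling convention is defensible, with a 2000-resample bootstrap CI.

Transfer to a second cohort restricts to shared features (model features
absent from the cohort are imputed at the overall centroid, with a count
warning) and applies the confidence-abstention rule: call positive only if
P(subtype) > 0.60, other only if < 0.40, abstain in between — strict
inequalities, so 0.60 and 0.40 themselves abstain. Minimal panels raise Δ
until at most n features survive; during panel CV the cap is re-applied
inside every training fold, because a Δ tuned on the full cohort shrinks
all features to zero on the smaller folds and collapses the panel to chance.

## Signature overlap and lesion score

A patient's hypomethylated CpG set is every probe inside a cluster called
hypo for that patient. The overlap index is |hypo ∩ signature| / |hypo|;
its null is the mean over ten random same-size signatures drawn uniformly
from the probe universe (expectation m/N). The driver lesion score is the
nonsilent mutation count plus the additive inverse of the GISTIC call, an
allele-loss proxy; the literal formula is kept, so an amplification scores
negatively and triggers a warning. The lesion-overlap association is OLS of
the overlap index on the lesion score with the usual two-sided slope test.
SAM statistics use d_i = Δmean / (s_i + s0) with s0 the median s_i and
q-values by the median-false-positive permutation convention; Wilcoxon
comparisons are exact for small tie-free samples and normal-approximated
with tie correction otherwise; rank-test panels are BH-adjusted. The T-cell
score is the unweighted mean expression of the 13-transcript signature
(CD8A, CCL2, CCL3, CCL4, CXCL9, CXCL10, ICOS, GZMK, IRF1, HLA-DMA,
HLA-DMB, HLA-DOA, HLA-DOB), shipped as a packaged text file. Printed
percentages are reproduced with half-up integer rounding.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes.
Defaults: 400 tumors, 40 normals, 500 genes with 1–5 probes each, three
subtypes. Betas are drawn hierarchically — a per-sample latent level from
Beta(mβ·30, (1−m)·30) around the gene's component mean, then per-probe
values at precision 200 around the latent — so probes within a gene are
strongly correlated, as on arrays. Each subtype hypomethylates 40 planted
genes (abnormal mean = baseline − 0.45) and hypermethylates 10; the driver
subtype hypomethylates twice as many (80), reproducing the elevated
hypomethylated-gene burden that defines such subtypes. Expression at
abnormal genes is baseline − 4·(beta − baseline beta) + N(0, 0.5) —
strong inverse coupling; background genes are uncoupled. Driver lesions are
enriched in the planted subtype (mutation 0.6 vs 0.05; deletion 0.8 vs
0.35, 20% deep), driver expression falls with lesion burden, and the T-cell
signature tracks driver expression. A 300-CpG signature overlaps the
planted hypomethylated CpGs at a configurable fraction (default 0.5), with
the remainder drawn uniformly from the whole universe so that a zero
fraction yields a purely random signature. The probe layout comes from a
fixed structure seed, so cohorts generated under different seeds share one
"array design" — which also lets a paired validation cohort (whose planted
subtype shares a configurable fraction of the discovery gene set) be scored
by the discovery classifier. Half the probes are flagged as shared between
the 450k and 27k platforms. Outputs are byte-identical given a seed.

What the generator does *not* emulate: probe-chemistry (type I/II)
measurement error, tumor purity dilution, clinical covariates, batch
effects, or genomic autocorrelation beyond the per-gene probe hierarchy.
Passing tests therefore demonstrate that the implementation recovers planted
structure under idealised mixture assumptions, not that it would match any
particular clinical cohort's gene lists or subtype counts.

## Problem sizes and determinism

Bundled analyses and the acceptance script run the default cohort scale
(400 tumors / 500 genes), 50-seed mixture-recovery batches, 20-seed
permutation nulls, 10-seed transfer nulls, 200-repeat overlap nulls and
500-seed regression-null calibrations — sizes at which every check is
stable from run to run. All randomness flows from explicit seeds
(`numpy.random.default_rng`); reruns with equal seeds reproduce reports and
files exactly.

## Known limitations

- The differential-from-normal test of the upstream state-calling method is
  approximated by the fixed DM threshold (0.10).
- PAC-based k selection can under- or over-segment when cluster sizes are
  very unbalanced; the CDF/PAC tables are emitted for manual override.
- The lesion score treats amplifications literally (negative contribution).
- Beta-mixture model selection by BIC assumes the clamped likelihood is
  well-specified; heavy zero/one inflation beyond the clamp is not modelled.
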