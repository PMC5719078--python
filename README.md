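# msub — DNA-methylation subtyping with beta mixtures, consensus clustering and shrunken centroids

Tumors that inactivate a chromatin-modifying driver gene can lose DNA
methylation genome-wide, forming a distinct hypomethylated subtype that
recurs across cancer sites. `msub` implements the full analysis used to
find and characterise such subtypes from Illumina 450k/27k-style beta-value
matrices with matched normals:

1. **Abnormal methylation calling** — per gene, correlated CpG probes are
   collapsed (complete linkage on 1 − r, cut at 0.4) and cluster
   methylation is modelled as a beta mixture, K ≤ 3 chosen by BIC. Each
   tumor gets a state per gene — hypo/normal/hyper — by maximum-posterior
   component, with a DM value (component mean beta − normal mean beta). A
   gene counts as abnormal only when it is differential from normal tissue
   *and* inversely coupled with its own expression (Pearson r ≤ −0.3,
   p < 0.05).
2. **Subtype discovery** — consensus k-means over tumors' DM profiles
   (resampled co-clustering frequencies); the cluster number is the largest
   k whose proportion of ambiguous clustering (PAC) ties the minimum.
3. **Subtype classification** — a nearest-shrunken-centroid (PAM) model,
   d′_ik = sign(d_ik)(|d_ik| − Δ)₊, with stratified 10-fold CV AUC,
   minimal CpG panels, and cross-cohort transfer over shared probes using a
   confidence-abstention rule (call only if P > 0.60 or P < 0.40).
4. **Signature and lesion statistics** — per-patient overlap of
   hypomethylated CpGs with a disease signature (against a
   random-signature null), a driver lesion score
   (nonsilent mutations + (−GISTIC call)) regressed on that overlap, SAM
   permutation statistics, Wilcoxon panels, cross-cohort patient
   correlation matrices and a 13-gene T-cell expression score.

Everything is exercised end-to-end on synthetic cohorts with planted ground
truth (`msub.simulate`), so each stage is testable without downloads. See
`docs/methods.md` for models, parameters and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
discovery/validation cohort pair (400 tumors, 40 normals, 500 genes each;
three subtypes, the first hypomethylating 80 genes and carrying most driver
lesions):

```sh
python analysis/01_simulate_cohorts.py       --seed 1 --out results
python analysis/02_call_methylation_states.py --seed 1 --out results
python analysis/03_discover_subtypes.py       --seed 1 --out results
python analysis/04_classify_and_transfer.py   --seed 1 --out results
python analysis/05_signature_overlap.py       --seed 1 --out results
```

which prints, at seed 1:

```
500 CpG clusters from 1473 probes
189 clusters abnormal (differential vs normal + inverse expression coupling)
chosen k = 3 (PAC 0.000)
adjusted Rand index vs planted subtypes: 1.000
hypomethylated subtype 1: 71.3 hypo genes/patient vs 36.3 elsewhere (Wilcoxon p = 4.59e-58)
driver-lesion enrichment in subtype 1: chi2 = 122.0, p = 2.34e-28
10-fold CV AUC 1.000 (95% CI 1.000-1.000; fold-mean 1.000); 154 CpGs selected
5-CpG minimal panel: AUC 0.961
transfer: 119/400 called positive, 119 inside the validation planted subtype (chi2 = 400.0, p = 5.51e-89)
signature overlap index: mean 0.304 vs random-signature mean 0.204 (400 patients)
lesion-score association: slope 0.1708 per lesion, p = 2.06e-44
T-cell score vs driver expression: Pearson r = 0.938, p = 1.15e-184
```

Reading this: the mixture/coupling filter recovers the planted abnormal
genes; consensus clustering finds exactly the three planted subtypes; the
methylation classifier separates the hypomethylated subtype perfectly in
cross-validation and, transferred to an independent cohort sharing the
signature, its positive calls land entirely inside that cohort's planted
subtype; patients' hypomethylated CpGs overlap the planted signature well
above the random-signature null, and the overlap rises by ≈0.17 per
inactivated driver allele.

The same pipeline is scriptable as a CLI (`msub simulate`, `msub states`,
`msub subtype`, `msub classify`, `msub transfer`, `msub scores`, `msub all`)
over a YAML config, and as plain library calls (`msub.pipeline`).

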