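"""Signature overlap, driver lesion score and immune signature analyses.

For each patient, the hypomethylated CpG set (probes of clusters called
hypo) is intersected with the disease hypomethylation CpG signature to give
an overlap index, compared against the mean of ten random same-size
signatures. A driver lesion score (nonsilent mutations plus the additive
inverse of the GISTIC call) is regressed against the overlap index, the
cross-cohort patient correlation matrix is computed over shared probes, and
the 13-gene T-cell score is correlated with driver expression.

Usage: python analysis/05_signature_overlap.py [--seed 1] [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

from msub.cohort_io import drop_silent_mutations, load_cohort, read_gistic, read_maf
from msub.mixture import MethylationStateMatrix
from msub.pipeline import hypo_cpg_sets, preprocess_cohort
from msub.probe_clustering import ProbeClusterMap
from msub.stats import (
    lesion_overlap_association,
    lesion_scores,
    patient_correlation_matrix,
    score_gene_correlation,
    signature_overlap,
    tcell_score,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    base = args.out / "cohort_discovery"
    cohort = load_cohort(base / "cohort.yaml")
    cohort = preprocess_cohort(cohort)
    cmap = ProbeClusterMap.from_frame(
        pd.read_csv(args.out / "states" / "probe_clusters.tsv", sep="\t")
    )
    states = MethylationStateMatrix.from_long(
        pd.read_csv(args.out / "states" / "states.tsv", sep="\t")
    )
    signature = (base / "signature_cpgs.txt").read_text().split()
    universe = list(cohort.beta.values.index)

    hypo_sets = hypo_cpg_sets(states, cmap)
    overlap = signature_overlap(hypo_sets, signature, universe, seed=args.seed)
    lesions = drop_silent_mutations(read_maf(base / "mutations.tsv"))
    cn = read_gistic(base / "copy_number.tsv")
    lesion_tab = lesion_scores(lesions, cn, "DRV1", list(overlap.index))
    merged = overlap.join(lesion_tab)
    slope, p = lesion_overlap_association(merged["lesion_score"], merged["index"])

    outdir = args.out / "overlap"
    outdir.mkdir(parents=True, exist_ok=True)
    merged.to_csv(outdir / "overlap_indices.tsv", sep="\t")

    print(
        f"signature overlap index: mean {overlap['index'].mean():.3f} "
        f"vs random-signature mean {overlap['random_index'].mean():.3f} "
        f"({len(overlap)} patients)"
    )
    print(f"lesion-score association: slope {slope:.4f} per lesion, p = {p:.2e}")

    # cross-cohort methylation concordance over probes shared by both platforms
    cohort2 = load_cohort(args.out / "cohort_validation" / "cohort.yaml")
    cohort2 = preprocess_cohort(cohort2)
    shared = [
        p_ for p_ in cohort.beta.values.index
        if cohort.beta.platform.get(p_) == "both" and p_ in cohort2.beta.values.index
    ]
    R = patient_correlation_matrix(
        cohort.beta.values.loc[:, cohort.beta.tumor_samples],
        cohort2.beta.values.loc[:, cohort2.beta.tumor_samples],
        shared,
    )
    R.to_csv(outdir / "cross_cohort_correlation.tsv", sep="\t")
    print(
        f"cross-cohort correlation over {len(shared)} shared probes: "
        f"mean r {R.to_numpy().mean():.3f}"
    )

    tc = tcell_score(cohort.expression.values)
    tc.to_csv(outdir / "tcell_scores.tsv", sep="\t")
    r, p_tc = score_gene_correlation(tc, cohort.expression.values.loc["DRV1"])
    print(f"T-cell score vs driver expression: Pearson r = {r:.3f}, p = {p_tc:.2e}")


if __name__ == "__main__":
    main()
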