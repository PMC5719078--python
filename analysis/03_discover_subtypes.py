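"""Discover methylation subtypes by consensus clustering.

Clusters tumors on their DM-value profiles over abnormal CpG clusters
(consensus k-means with subsampling), selects the cluster number by PAC,
scores agreement with the planted truth, and tests enrichment of driver
lesions in the most hypomethylated subtype (Pearson chi-squared).

Usage: python analysis/03_discover_subtypes.py [--seed 1] [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from msub.consensus import enrichment_test, pac_table
from msub.mixture import MethylationStateMatrix, count_hypo_per_patient
from msub.pipeline import hypomethylated_subtype, subtype_stage
from msub.stats import lesion_scores, wilcoxon_rank_sum
from msub.cohort_io import read_maf, read_gistic, drop_silent_mutations


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-reps", type=int, default=200)
    args = ap.parse_args()

    states = MethylationStateMatrix.from_long(
        pd.read_csv(args.out / "states" / "states.tsv", sep="\t")
    )
    result = subtype_stage(states, k_max=6, n_reps=args.n_reps, seed=args.seed)
    focal, hypo_means = hypomethylated_subtype(result, states)

    outdir = args.out / "subtypes"
    outdir.mkdir(parents=True, exist_ok=True)
    assign = result.assignment_series()
    assign.to_csv(outdir / "subtypes.tsv", sep="\t")
    pac_table(result).to_csv(outdir / "pac.tsv", sep="\t", index=False)
    pd.DataFrame(
        result.matrices[result.chosen_k], index=assign.index, columns=assign.index
    ).to_csv(outdir / "consensus_matrix.tsv", sep="\t")
    from msub.plots import consensus_cdf_plot, consensus_heatmap

    consensus_heatmap(result, result.chosen_k, outdir / "consensus_heatmap.png")
    consensus_cdf_plot(result, outdir / "consensus_cdf.png")

    truth = pd.read_csv(
        args.out / "cohort_discovery" / "truth_samples.tsv", sep="\t", index_col=0
    )
    ari = adjusted_rand_score(truth["subtype"].reindex(assign.index), assign)

    muts = drop_silent_mutations(read_maf(args.out / "cohort_discovery" / "mutations.tsv"))
    cn = read_gistic(args.out / "cohort_discovery" / "copy_number.tsv")
    lesions = lesion_scores(muts, cn, "DRV1", list(assign.index))
    chi2, p = enrichment_test(
        assign.to_numpy(), (lesions["lesion_score"] > 0).to_numpy(), focal_subtype=focal
    )
    counts = count_hypo_per_patient(states)
    in_focal = counts[assign == focal]
    out_focal = counts[assign != focal]
    _, p_wilcox = wilcoxon_rank_sum(in_focal, out_focal)

    print(f"chosen k = {result.chosen_k} (PAC {result.pac[result.chosen_k]:.3f})")
    print(f"adjusted Rand index vs planted subtypes: {ari:.3f}")
    print(
        f"hypomethylated subtype {focal}: {in_focal.mean():.1f} hypo genes/patient "
        f"vs {out_focal.mean():.1f} elsewhere (Wilcoxon p = {p_wilcox:.2e})"
    )
    print(f"driver-lesion enrichment in subtype {focal}: chi2 = {chi2:.1f}, p = {p:.2e}")


if __name__ == "__main__":
    main()
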