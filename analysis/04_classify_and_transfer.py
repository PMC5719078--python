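"""Classify the hypomethylated subtype and transfer it across cohorts.

Trains a nearest-shrunken-centroid model on the CpG beta values of abnormal
clusters, evaluates it by stratified 10-fold cross-validated AUC, shrinks it
to a five-CpG panel, and applies it to the validation cohort with the
confidence-abstention rule (call only when P(subtype) > 0.6 or < 0.4),
testing enrichment of transferred calls in the validation cohort's planted
subtype.

Usage: python analysis/04_classify_and_transfer.py [--seed 1] [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

from msub.cohort_io import load_cohort
from msub.consensus import enrichment_test
from msub.mixture import MethylationStateMatrix, count_hypo_per_patient
from msub.nsc import cross_validate, minimal_panel, train_nsc, transfer_classify
from msub.pipeline import classifier_features, preprocess_cohort
from msub.probe_clustering import ProbeClusterMap


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = load_cohort(args.out / "cohort_discovery" / "cohort.yaml")
    cohort = preprocess_cohort(cohort)
    cmap = ProbeClusterMap.from_frame(
        pd.read_csv(args.out / "states" / "probe_clusters.tsv", sep="\t")
    )
    states = MethylationStateMatrix.from_long(
        pd.read_csv(args.out / "states" / "states.tsv", sep="\t")
    )
    assign = pd.read_csv(
        args.out / "subtypes" / "subtypes.tsv", sep="\t", index_col=0
    )["subtype"]
    feats = classifier_features(cohort, cmap, states)
    # positive class = consensus subtype with the most hypomethylation
    counts = count_hypo_per_patient(states)
    focal = counts.groupby(assign.reindex(counts.index)).mean().idxmax()
    labels = assign.reindex(feats.index).map(lambda s: "pos" if s == focal else "other")

    cv = cross_validate(feats, labels, "pos", n_folds=10, seed=args.seed)
    model = train_nsc(feats, labels, seed=args.seed)
    panel_model, panel_cv, stability = minimal_panel(
        feats, labels, "pos", n_features=5, n_folds=10, seed=args.seed
    )

    outdir = args.out / "classifier"
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"score": cv.scores, "truth": cv.truth, "fold": cv.fold}).to_csv(
        outdir / "cv_scores.tsv", sep="\t"
    )
    stability.to_csv(outdir / "panel_stability.tsv", sep="\t")

    print(
        f"10-fold CV AUC {cv.auc_pooled:.3f} "
        f"(95% CI {cv.auc_ci[0]:.3f}-{cv.auc_ci[1]:.3f}; "
        f"fold-mean {cv.auc_fold_mean:.3f}); "
        f"{len(model.selected_features)} CpGs selected"
    )
    print(
        f"5-CpG minimal panel: AUC {panel_cv.auc_pooled:.3f}, "
        f"panel {panel_model.selected_features}"
    )

    cohort2 = load_cohort(args.out / "cohort_validation" / "cohort.yaml")
    cohort2 = preprocess_cohort(cohort2)
    feats2 = cohort2.beta.values.loc[:, cohort2.beta.tumor_samples].T
    calls2 = transfer_classify(model, feats2, "pos")
    calls2.to_csv(outdir / "transfer_calls.tsv", sep="\t")
    truth2 = pd.read_csv(
        args.out / "cohort_validation" / "truth_samples.tsv", sep="\t", index_col=0
    )
    pos = (calls2["call"] == "positive").to_numpy()
    chi2, p = enrichment_test(
        truth2["subtype"].reindex(calls2.index).to_numpy(), pos, focal_subtype=0
    )
    n_in = (pos & (truth2["subtype"].reindex(calls2.index) == 0)).sum()
    print(
        f"transfer: {pos.sum()}/{len(calls2)} called positive, "
        f"{n_in} inside the validation planted subtype "
        f"(chi2 = {chi2:.1f}, p = {p:.2e}); "
        f"{(calls2['call'] == 'abstain').sum()} abstentions"
    )


if __name__ == "__main__":
    main()
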