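"""Simulate the study cohorts.

Writes a discovery cohort (400 tumors, 40 matched normals, 500 genes, three
planted subtypes — the first hypomethylates twice as many genes and carries
most driver mutations/deletions) and a paired validation cohort over the
same probe space whose hypomethylated subtype shares the discovery cohort's
planted gene set, for transfer classification.

Usage: python analysis/01_simulate_cohorts.py [--seed 1] [--out results]
"""

import argparse
from pathlib import Path

from msub.simulate import GeneratorConfig, generate_cohort, generate_second_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = GeneratorConfig(seed=args.seed)
    cohort, truth = generate_cohort(cfg, outdir=args.out / "cohort_discovery")
    cfg2 = GeneratorConfig(seed=args.seed + 1)
    _, truth2 = generate_second_cohort(
        cfg2, truth, share_frac=1.0, outdir=args.out / "cohort_validation"
    )
    n0 = (truth.samples["subtype"] == 0).sum()
    print(
        f"discovery cohort: {cfg.n_tumor} tumors / {cfg.n_normal} normals, "
        f"{cohort.beta.values.shape[0]} probes in {cfg.n_genes} genes"
    )
    print(
        f"planted hypomethylated subtype: {n0} tumors, "
        f"{len(truth.planted_hypo_genes(0))} hypomethylated genes, "
        f"signature of {len(truth.signature)} CpGs "
        f"({len(set(truth.signature) & set(truth.planted_hypo_cpgs(0)))} planted)"
    )
    print(f"validation cohort: {cfg2.n_tumor} tumors sharing the planted gene set")
    print(f"written to {args.out}/cohort_discovery and {args.out}/cohort_validation")


if __name__ == "__main__":
    main()
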