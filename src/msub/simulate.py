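"""Synthetic methylation cohorts with planted subtype structure.

The generator emulates the statistical structure the pipeline assumes in a
tumor/normal array study: per-gene beta values drawn from beta distributions
with normal-like, hypomethylated and hypermethylated components; a planted
subtype that hypomethylates a fixed gene set and is enriched for mutations
and copy-number deletions of a driver gene; negative methylation-expression
coupling at abnormal genes; a partial 450k/27k platform split; and a CpG
signature that partially overlaps the planted hypomethylated CpGs. Every
emitted table has a matching ground-truth record, so each pipeline stage can
be scored against construction.

Probes of one gene are drawn hierarchically (a per-sample latent methylation
level plus tight per-probe noise), so probes within a gene are strongly
correlated, as on real arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_io import (
    BetaMatrix,
    Cohort,
    CopyNumberTable,
    ExpressionMatrix,
    MutationTable,
    ProbeManifest,
    write_matrix,
    MISSING_TOKEN,
)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults give a desk-scale array study."""

    n_tumor: int = 400
    n_normal: int = 40
    n_genes: int = 500
    probes_per_gene: tuple[int, int] = (1, 5)
    n_subtypes: int = 3
    planted_hypo_per_subtype: int = 40
    planted_hyper_per_subtype: int = 10
    driver_hypo_boost: float = 2.0  # x more hypo genes in the driver subtype
    hypo_shift: float = 0.45  # beta drop of the abnormal component
    hyper_shift: float = 0.45
    precision: float = 30.0  # beta precision: (a, b) = (m*prec, (1-m)*prec)
    probe_precision: float = 200.0  # within-gene probe noise around the latent
    carrier_prob: float = 0.9  # P(abnormal state | planted gene, member sample)
    coupling: float = 4.0  # log2 expression units lost per unit beta gained
    expression_noise_sd: float = 0.5
    driver_gene: str = "DRV1"
    mut_rate_in: float = 0.6  # driver mutation rate inside the planted subtype
    mut_rate_out: float = 0.05
    del_rate_in: float = 0.8  # driver deletion rate inside the planted subtype
    del_rate_out: float = 0.35
    deep_del_frac: float = 0.2  # P(gistic=-2 | deleted)
    silent_rate: float = 0.08
    passenger_rate: float = 0.02
    signature_size: int = 300
    signature_overlap_frac: float = 0.5
    platform_both_frac: float = 0.5  # probes present on both 450k and 27k
    missing_rate: float = 0.01
    tcell_driver_coupling: float = 0.6
    seed: int = 0
    structure_seed: int = 20450  # array design (probe layout) is fixed across seeds

    def validate(self) -> None:
        probs = [
            self.carrier_prob, self.mut_rate_in, self.mut_rate_out,
            self.del_rate_in, self.del_rate_out, self.deep_del_frac,
            self.silent_rate, self.passenger_rate, self.signature_overlap_frac,
            self.platform_both_frac, self.missing_rate,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all rates must lie in [0, 1]")
        need = (
            self.n_subtypes * (self.planted_hypo_per_subtype + self.planted_hyper_per_subtype)
            + self.n_hypo_driver_subtype
            - self.planted_hypo_per_subtype
        )
        if need + 1 > self.n_genes:  # +1 for the driver gene
            raise ValueError(
                f"infeasible config: {need} planted genes + driver > {self.n_genes} genes"
            )
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def n_hypo_driver_subtype(self) -> int:
        """Hypomethylated gene count in the driver subtype (boosted)."""
        return int(round(self.driver_hypo_boost * self.planted_hypo_per_subtype))


@dataclass
class TruthTable:
    """Ground truth emitted alongside the synthetic cohort."""

    samples: pd.DataFrame  # sample_id -> subtype, driver_mutations, driver_gistic
    genes: pd.DataFrame  # gene -> role, subtype, baseline_mean, abnormal_mean
    probes: pd.DataFrame  # probe_id -> gene, platform
    signature: list[str]
    config: GeneratorConfig

    def planted_hypo_genes(self, subtype: int = 0) -> list[str]:
        sel = (self.genes["role"] == "hypo") & (self.genes["subtype"] == subtype)
        return list(self.genes.index[sel])

    def planted_hypo_cpgs(self, subtype: int = 0) -> list[str]:
        genes = set(self.planted_hypo_genes(subtype))
        return list(self.probes.index[self.probes["gene"].isin(genes)])

    def subtype_of(self) -> pd.Series:
        return self.samples["subtype"]


@dataclass
class _Structure:
    """Gene/probe layout shared between paired cohorts (for transfer tests)."""

    genes: list[str]
    baseline_mean: np.ndarray
    probes_of: dict[str, list[str]]
    manifest: pd.DataFrame
    expr_baseline: np.ndarray


def _build_structure(cfg: GeneratorConfig, rng: np.random.Generator) -> _Structure:
    genes = [cfg.driver_gene] + [f"G{i:04d}" for i in range(1, cfg.n_genes)]
    baseline = rng.uniform(0.55, 0.8, size=cfg.n_genes)  # high enough to plant hypo
    lo, hi = cfg.probes_per_gene
    npro = rng.integers(lo, hi + 1, size=cfg.n_genes)
    probes_of = {}
    rows = []
    pid = 0
    for g, k in zip(genes, npro):
        ids = []
        for _ in range(k):
            pid += 1
            name = f"cg{pid:08d}"
            ids.append(name)
            platform = "both" if rng.random() < cfg.platform_both_frac else "450k"
            rows.append((f"chr{1 + pid % 22}", 1000 * pid, name, g, platform))
        probes_of[g] = ids
    manifest = pd.DataFrame(
        rows, columns=["chrom", "start", "probe_id", "gene", "platform"]
    ).set_index("probe_id")
    expr_baseline = rng.uniform(4.0, 9.0, size=cfg.n_genes)
    return _Structure(genes, baseline, probes_of, manifest, expr_baseline)


def _plant_genes(cfg: GeneratorConfig, structure: _Structure, rng, forced_hypo0=None):
    """Assign planted hypo/hyper gene sets per subtype; returns the truth gene table."""
    genes = structure.genes
    pool = [g for g in genes if g != cfg.driver_gene]
    role = pd.DataFrame(
        {"role": "background", "subtype": -1, "baseline_mean": structure.baseline_mean,
         "abnormal_mean": np.nan},
        index=pd.Index(genes, name="gene"),
    )
    taken: set[str] = set()
    n_hypo0 = cfg.n_hypo_driver_subtype
    if forced_hypo0 is not None:
        forced = list(forced_hypo0)[:n_hypo0]
        extra = [g for g in pool if g not in forced]
        rng.shuffle(extra)
        hypo0 = forced + extra[: n_hypo0 - len(forced)]
    else:
        cand = pool.copy()
        rng.shuffle(cand)
        hypo0 = cand[:n_hypo0]
    taken |= set(hypo0)
    assignments = {0: ("hypo", hypo0)}
    order = [(s, "hypo") for s in range(1, cfg.n_subtypes)] + [
        (s, "hyper") for s in range(cfg.n_subtypes)
    ]
    for s, r in order:
        count = cfg.planted_hypo_per_subtype if r == "hypo" else cfg.planted_hyper_per_subtype
        cand = [g for g in pool if g not in taken]
        rng.shuffle(cand)
        chosen = cand[:count]
        taken |= set(chosen)
        assignments[(s, r) if r == "hyper" else s] = (r, chosen)
        for g in chosen:
            i = genes.index(g)
            base = structure.baseline_mean[i]
            if r == "hypo":
                ab = max(base - cfg.hypo_shift, 0.05)
            else:
                ab = min(base + cfg.hyper_shift, 0.95)
            role.loc[g, ["role", "subtype", "abnormal_mean"]] = [r, s, ab]
    for g in hypo0:
        i = genes.index(g)
        base = structure.baseline_mean[i]
        role.loc[g, ["role", "subtype", "abnormal_mean"]] = [
            "hypo", 0, max(base - cfg.hypo_shift, 0.05),
        ]
    role.loc[cfg.driver_gene, "role"] = "driver"
    return role


def _draw_beta_block(mean, prec, size, rng):
    mean = np.clip(mean, 1e-3, 1 - 1e-3)
    return rng.beta(mean * prec, (1 - mean) * prec, size=size)


def _generate(cfg: GeneratorConfig, structure: _Structure, truth_genes: pd.DataFrame,
              rng: np.random.Generator, sample_prefix: str):
    genes = structure.genes
    tumor_ids = [f"{sample_prefix}T{i:04d}" for i in range(1, cfg.n_tumor + 1)]
    normal_ids = [f"{sample_prefix}N{i:04d}" for i in range(1, cfg.n_normal + 1)]
    subtype = rng.integers(0, cfg.n_subtypes, size=cfg.n_tumor)

    probe_ids = [p for g in genes for p in structure.probes_of[g]]
    beta = np.empty((len(probe_ids), cfg.n_tumor + cfg.n_normal))
    expr = np.empty((cfg.n_genes, cfg.n_tumor))
    carrier = np.zeros((cfg.n_genes, cfg.n_tumor), dtype=bool)

    row = 0
    for i, g in enumerate(genes):
        base = structure.baseline_mean[i]
        info = truth_genes.loc[g]
        means_t = np.full(cfg.n_tumor, base)
        if info["role"] in ("hypo", "hyper"):
            members = subtype == int(info["subtype"])
            is_carrier = members & (rng.random(cfg.n_tumor) < cfg.carrier_prob)
            carrier[i] = is_carrier
            means_t[is_carrier] = info["abnormal_mean"]
        latent_t = _draw_beta_block(means_t, cfg.precision, cfg.n_tumor, rng)
        latent_n = _draw_beta_block(
            np.full(cfg.n_normal, base), cfg.precision, cfg.n_normal, rng
        )
        latent = np.concatenate([latent_t, latent_n])
        k = len(structure.probes_of[g])
        lat = np.clip(latent, 1e-3, 1 - 1e-3)
        beta[row: row + k] = rng.beta(
            lat * cfg.probe_precision, (1 - lat) * cfg.probe_precision,
            size=(k, latent.size),
        )
        row += k
        noise = rng.normal(0.0, cfg.expression_noise_sd, size=cfg.n_tumor)
        if info["role"] in ("hypo", "hyper"):
            expr[i] = (
                structure.expr_baseline[i]
                - cfg.coupling * (latent_t - base)
                + noise
            )
        else:
            expr[i] = structure.expr_baseline[i] + noise

    # driver lesions, enriched in the planted subtype
    in0 = subtype == 0
    mut_p = np.where(in0, cfg.mut_rate_in, cfg.mut_rate_out)
    n_mut = rng.binomial(1, mut_p) + rng.binomial(1, 0.1 * mut_p)  # occasional double hit
    del_p = np.where(in0, cfg.del_rate_in, cfg.del_rate_out)
    deleted = rng.random(cfg.n_tumor) < del_p
    gistic = np.where(
        deleted, np.where(rng.random(cfg.n_tumor) < cfg.deep_del_frac, -2, -1), 0
    )
    lesion = n_mut - gistic

    # driver expression tracks lesion burden; T-cell signature tracks driver expression
    di = genes.index(cfg.driver_gene)
    expr[di] = (
        structure.expr_baseline[di]
        - 0.9 * lesion
        + rng.normal(0.0, cfg.expression_noise_sd, size=cfg.n_tumor)
    )
    from .stats import TCELL_SIGNATURE

    tcell_rows = {}
    for g in TCELL_SIGNATURE:
        tcell_rows[g] = (
            5.0
            + cfg.tcell_driver_coupling * (expr[di] - structure.expr_baseline[di])
            + rng.normal(0.0, 0.8, size=cfg.n_tumor)
        )

    # mutation table: driver + silent + passenger rows
    maf_rows = []
    for s, nm in zip(tumor_ids, n_mut):
        for _ in range(int(nm)):
            maf_rows.append((s, cfg.driver_gene, "Missense_Mutation"))
    for s in tumor_ids:
        if rng.random() < cfg.silent_rate:
            maf_rows.append((s, cfg.driver_gene, "Silent"))
        if rng.random() < cfg.passenger_rate:
            g = genes[int(rng.integers(0, cfg.n_genes))]
            maf_rows.append((s, g, "Missense_Mutation"))
    maf = pd.DataFrame(
        maf_rows, columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    )

    cn_wide = pd.DataFrame(
        np.zeros((1, cfg.n_tumor), dtype=int),
        index=pd.Index([cfg.driver_gene], name="Gene Symbol"),
        columns=tumor_ids,
    )
    cn_wide.loc[cfg.driver_gene] = gistic

    all_ids = tumor_ids + normal_ids
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=all_ids)
    # inject a sprinkle of missing values (restored later by KNN imputation)
    if cfg.missing_rate > 0:
        mask = rng.random(beta_df.shape) < cfg.missing_rate
        # keep every row partially observed
        mask[:, 0] = False
        beta_df = beta_df.mask(mask)
    expr_df = pd.DataFrame(expr, index=genes, columns=tumor_ids)
    expr_df = pd.concat([expr_df, pd.DataFrame(tcell_rows, index=tumor_ids).T])
    group = pd.Series(
        ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal, index=all_ids, name="group"
    )

    # CpG signature: a fraction overlaps the planted hypomethylated CpGs
    hypo_genes = [
        g for g in genes
        if truth_genes.loc[g, "role"] == "hypo" and truth_genes.loc[g, "subtype"] == 0
    ]
    hypo_cpgs = [p for g in hypo_genes for p in structure.probes_of[g]]
    # the configured fraction is guaranteed overlap; the remainder is drawn
    # uniformly from the rest of the universe, so a zero fraction gives a
    # purely random signature rather than one avoiding the planted CpGs
    n_from_planted = min(
        int(round(cfg.signature_overlap_frac * cfg.signature_size)), len(hypo_cpgs)
    )
    picked = list(rng.choice(hypo_cpgs, size=n_from_planted, replace=False))
    rest_pool = [p for p in probe_ids if p not in set(picked)]
    n_rest = min(cfg.signature_size - n_from_planted, len(rest_pool))
    picked += list(rng.choice(rest_pool, size=n_rest, replace=False))
    signature = sorted(picked)

    truth_samples = pd.DataFrame(
        {
            "subtype": subtype,
            "driver_mutations": n_mut,
            "driver_gistic": gistic,
            "driver_lesion_score": lesion,
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )
    probes_truth = structure.manifest[["gene", "platform"]].copy()
    truth = TruthTable(truth_samples, truth_genes.copy(), probes_truth, signature, cfg)

    platform = structure.manifest["platform"]
    cohort = Cohort(
        beta=BetaMatrix(beta_df, group, platform),
        expression=ExpressionMatrix(expr_df),
        mutations=MutationTable(
            pd.DataFrame(
                {
                    "sample_id": maf["Tumor_Sample_Barcode"],
                    "gene": maf["Hugo_Symbol"],
                    "variant_classification": maf["Variant_Classification"],
                    "is_silent": maf["Variant_Classification"].isin(["Silent"]),
                }
            )
        ),
        copy_number=CopyNumberTable(
            cn_wide.stack().reset_index().set_axis(
                ["gene", "sample_id", "gistic_score"], axis=1
            )[["sample_id", "gene", "gistic_score"]].assign(
                gistic_score=lambda d: d["gistic_score"].astype(int)
            )
        ),
        manifest=ProbeManifest(structure.manifest.copy()),
    )
    return cohort, truth, maf, cn_wide


def generate_cohort(config: GeneratorConfig, outdir: str | Path | None = None):
    """Generate one synthetic cohort; optionally write all tables to *outdir*.

    Returns ``(cohort, truth)``. Outputs are byte-identical for identical
    seeds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    structure = _build_structure(config, np.random.default_rng(config.structure_seed))
    truth_genes = _plant_genes(config, structure, rng)
    cohort, truth, maf, cn_wide = _generate(config, structure, truth_genes, rng, "S")
    if outdir is not None:
        _write_cohort(cohort, truth, maf, cn_wide, Path(outdir))
    return cohort, truth


def generate_second_cohort(
    config: GeneratorConfig,
    first_truth: TruthTable,
    share_frac: float = 1.0,
    outdir: str | Path | None = None,
):
    """Generate an independent cohort over the same probe space.

    Its planted subtype hypomethylates a gene set sharing ``share_frac`` of
    the first cohort's planted hypomethylated genes, emulating a cross-cancer
    transfer design.
    """
    config.validate()
    if not 0 <= share_frac <= 1:
        raise ValueError("share_frac must lie in [0, 1]")
    # identical probe space as the first cohort (same array design)
    rng0 = np.random.default_rng(first_truth.config.structure_seed)
    structure = _build_structure(first_truth.config, rng0)
    rng = np.random.default_rng(config.seed + 101)
    n_share = int(round(share_frac * config.n_hypo_driver_subtype))
    shared = first_truth.planted_hypo_genes(0)[:n_share]
    forced = shared if share_frac > 0 else []
    if share_frac == 0:
        # explicitly avoid the first cohort's genes
        avoid = set(first_truth.planted_hypo_genes(0))
        pool = [g for g in structure.genes if g not in avoid and g != config.driver_gene]
        rng.shuffle(pool)
        forced = pool[: config.n_hypo_driver_subtype]
    truth_genes = _plant_genes(config, structure, rng, forced_hypo0=forced)
    cohort, truth, maf, cn_wide = _generate(config, structure, truth_genes, rng, "V")
    if outdir is not None:
        _write_cohort(cohort, truth, maf, cn_wide, Path(outdir))
    return cohort, truth


def _write_cohort(cohort: Cohort, truth: TruthTable, maf, cn_wide, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.beta.values, outdir / "beta.tsv")
    cohort.beta.group.to_frame().to_csv(outdir / "groups.tsv", sep="\t")
    write_matrix(cohort.expression.values, outdir / "expression.tsv")
    maf.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    cn_wide.to_csv(outdir / "copy_number.tsv", sep="\t", na_rep=MISSING_TOKEN)
    man = cohort.manifest.table.reset_index()[
        ["chrom", "start", "probe_id", "gene", "platform"]
    ]
    man.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    (outdir / "signature_cpgs.txt").write_text("\n".join(truth.signature) + "\n")
    truth.samples.to_csv(outdir / "truth_samples.tsv", sep="\t")
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
    cfg = asdict(truth.config)
    cfg["probes_per_gene"] = list(cfg["probes_per_gene"])
    with open(outdir / "generator_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    with open(outdir / "cohort.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "beta": "beta.tsv",
                "groups": "groups.tsv",
                "expression": "expression.tsv",
                "mutations": "mutations.tsv",
                "copy_number": "copy_number.tsv",
                "manifest": "manifest.tsv",
            },
            fh,
        )
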