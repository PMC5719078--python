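"""End-to-end orchestration: load -> impute -> cluster -> call states ->
consensus subtype -> classify -> transfer -> signature scores.

Each stage is a plain function over the library modules so drivers, tests and
the CLI can run any prefix of the pipeline; :func:`run_pipeline` chains them
from a validated YAML config and writes a machine-readable run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import Cohort, filter_missing, knn_impute, load_cohort, drop_silent_mutations
from .consensus import ConsensusResult, consensus_cluster, enrichment_test, pac_table
from .mixture import MethylationStateMatrix, call_states, count_hypo_per_patient
from .nsc import CVReport, ShrunkenCentroidModel, cross_validate, train_nsc, transfer_classify
from .probe_clustering import ProbeClusterMap, cluster_mean_beta, cluster_probes
from .simulate import GeneratorConfig, TruthTable, generate_cohort, generate_second_cohort
from .stats import (
    lesion_overlap_association,
    lesion_scores,
    signature_overlap,
    tcell_score,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected."""

    cohort: str | None = None  # cohort.yaml path (mutually exclusive with simulate)
    simulate: dict | None = None  # GeneratorConfig overrides
    second_cohort: str | None = None
    simulate_second: dict | None = None
    out: str = "results"
    seed: int = 0
    beta_max_missing: float = 0.2
    expr_max_missing: float = 0.1
    knn_k: int = 15
    cut_height: float = 0.4
    dm_min: float = 0.10
    coupling_r: float = -0.3
    coupling_p: float = 0.05
    k_max: int = 6
    n_reps: int = 1000
    subsample_frac: float = 0.8
    consensus_encoding: str = "dm"  # or "state"
    n_folds: int = 10
    conf_low: float = 0.40
    conf_high: float = 0.60
    n_draws: int = 10
    driver_gene: str = "DRV1"
    stages: list = field(
        default_factory=lambda: ["states", "subtype", "classify", "transfer", "scores"]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"missing config file: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if (cfg.cohort is None) == (cfg.simulate is None):
            raise ConfigError("exactly one of 'cohort' or 'simulate' is required")
        if not 0 <= cfg.beta_max_missing < 1 or not 0 <= cfg.expr_max_missing < 1:
            raise ConfigError("missingness thresholds must lie in [0, 1)")
        if not (0 <= cfg.conf_low <= cfg.conf_high <= 1):
            raise ConfigError("need 0 <= conf_low <= conf_high <= 1")
        if cfg.consensus_encoding not in ("dm", "state"):
            raise ConfigError("consensus_encoding must be 'dm' or 'state'")
        if base is not None:
            if cfg.cohort:
                cfg.cohort = str(base / cfg.cohort)
            if cfg.second_cohort:
                cfg.second_cohort = str(base / cfg.second_cohort)
        return cfg


# ---------------------------------------------------------------------------
# stages


def preprocess_cohort(
    cohort: Cohort,
    beta_max_missing: float = 0.2,
    expr_max_missing: float = 0.1,
    knn_k: int = 15,
) -> Cohort:
    """Missingness filtering (rows then columns) and KNN imputation, per table."""
    beta_df = filter_missing(cohort.beta.values, beta_max_missing)
    beta_df = knn_impute(beta_df, k=knn_k).clip(0.0, 1.0)
    expr_df = filter_missing(cohort.expression.values, expr_max_missing)
    expr_df = knn_impute(expr_df, k=knn_k)
    cohort.beta.values = beta_df
    cohort.beta.group = cohort.beta.group.reindex(beta_df.columns)
    cohort.beta.platform = cohort.beta.platform.reindex(beta_df.index)
    cohort.expression.values = expr_df
    cohort.mutations = drop_silent_mutations(cohort.mutations)
    return cohort


def state_stage(
    cohort: Cohort,
    cut_height: float = 0.4,
    dm_min: float = 0.10,
    coupling_r: float = -0.3,
    coupling_p: float = 0.05,
    seed: int = 0,
):
    """Probe clustering plus beta-mixture state calling."""
    cmap = cluster_probes(cohort.beta, cohort.manifest, cut_height=cut_height)
    cluster_beta = cluster_mean_beta(cohort.beta, cmap)
    states, calls = call_states(
        cluster_beta,
        cohort.beta.group,
        cohort.expression.values,
        cmap.gene_of,
        dm_min=dm_min,
        r_threshold=coupling_r,
        p_threshold=coupling_p,
        seed=seed,
    )
    return cmap, cluster_beta, states, calls


def consensus_features(states: MethylationStateMatrix, encoding: str = "dm") -> pd.DataFrame:
    """Samples x abnormal-cluster feature matrix for consensus clustering."""
    if encoding == "dm":
        return states.dm.T.astype(float)
    codes = states.states.replace({"hypo": -1, "normal": 0, "hyper": 1}).astype(float)
    return codes.T


def subtype_stage(
    states: MethylationStateMatrix,
    k_max: int = 6,
    n_reps: int = 1000,
    subsample_frac: float = 0.8,
    encoding: str = "dm",
    seed: int = 0,
) -> ConsensusResult:
    feats = consensus_features(states, encoding)
    return consensus_cluster(
        feats, k_max=k_max, n_reps=n_reps, subsample_frac=subsample_frac, seed=seed
    )


def hypomethylated_subtype(result: ConsensusResult, states: MethylationStateMatrix):
    """The subtype with the highest mean hypomethylated-gene count per patient."""
    counts = count_hypo_per_patient(states)
    assign = result.assignment_series()
    means = counts.groupby(assign.reindex(counts.index)).mean()
    return means.idxmax(), means


def classifier_features(cohort: Cohort, cmap: ProbeClusterMap, states) -> pd.DataFrame:
    """Samples x CpG beta features over probes of abnormal clusters (tumors only)."""
    probes = sorted({p for cid in states.states.index for p in cmap.clusters[cid]})
    tumor = cohort.beta.tumor_samples
    return cohort.beta.values.loc[probes, tumor].T


def hypo_cpg_sets(states: MethylationStateMatrix, cmap: ProbeClusterMap) -> dict[str, set]:
    """Per patient, all CpG probes inside gene-clusters called hypomethylated."""
    out: dict[str, set] = {s: set() for s in states.states.columns}
    for cid in states.states.index:
        probes = set(cmap.clusters[cid])
        hypo_samples = states.states.columns[(states.states.loc[cid] == "hypo")]
        for s in hypo_samples:
            out[s] |= probes
    return out


# ---------------------------------------------------------------------------
# full run


def run_pipeline(config: PipelineConfig, truth: TruthTable | None = None) -> dict:
    """Execute the configured stages; returns (and writes) the run report."""
    t0 = time.time()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "stages": {},
    }

    def stage_done(name, **counts):
        report["stages"][name] = {"elapsed_s": round(time.time() - t0, 2), **counts}
        logger.info("stage %s done: %s", name, counts)

    truth2 = None
    if config.simulate is not None:
        gen = GeneratorConfig(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
        cohort, truth = generate_cohort(gen)
        stage_done("simulate", n_tumor=gen.n_tumor, n_genes=gen.n_genes)
    else:
        cohort = load_cohort(config.cohort)
        stage_done("load", n_samples=cohort.beta.values.shape[1])

    cohort = preprocess_cohort(
        cohort, config.beta_max_missing, config.expr_max_missing, config.knn_k
    )
    stage_done(
        "preprocess",
        n_probes=cohort.beta.values.shape[0],
        n_samples=cohort.beta.values.shape[1],
    )

    cmap, cluster_beta, states, calls = state_stage(
        cohort,
        cut_height=config.cut_height,
        dm_min=config.dm_min,
        coupling_r=config.coupling_r,
        coupling_p=config.coupling_p,
        seed=config.seed,
    )
    states.to_long().to_csv(out / "states.tsv", sep="\t", index=False)
    calls.to_csv(out / "abnormal_calls.tsv", sep="\t")
    stage_done(
        "states",
        n_clusters=int(cluster_beta.shape[0]),
        n_abnormal=int(calls["is_abnormal"].sum()),
    )

    result = None
    if "subtype" in config.stages and len(states.states):
        result = subtype_stage(
            states,
            k_max=config.k_max,
            n_reps=config.n_reps,
            subsample_frac=config.subsample_frac,
            encoding=config.consensus_encoding,
            seed=config.seed,
        )
        result.assignment_series().to_csv(out / "subtypes.tsv", sep="\t")
        pac_table(result).to_csv(out / "pac.tsv", sep="\t", index=False)
        from .plots import consensus_cdf_plot, consensus_heatmap

        consensus_heatmap(result, result.chosen_k, out / "consensus_heatmap.png")
        consensus_cdf_plot(result, out / "consensus_cdf.png")
        focal, hypo_means = hypomethylated_subtype(result, states)
        report["chosen_k"] = int(result.chosen_k)
        report["hypomethylated_subtype"] = int(focal)
        assign = result.assignment_series()
        lesions = lesion_scores(
            cohort.mutations, cohort.copy_number, config.driver_gene, list(assign.index)
        )
        try:
            chi2, p = enrichment_test(
                assign.to_numpy(), (lesions["lesion_score"] > 0).to_numpy(), focal_subtype=focal
            )
            report["driver_enrichment"] = {"chi2": chi2, "p": p}
        except ValueError as exc:
            report["driver_enrichment"] = {"error": str(exc)}
        if truth is not None:
            from sklearn.metrics import adjusted_rand_score

            ari = adjusted_rand_score(
                truth.subtype_of().reindex(assign.index), assign
            )
            report["ari_vs_truth"] = float(ari)
        stage_done("subtype", chosen_k=int(result.chosen_k))

    model = cv = None
    if "classify" in config.stages and result is not None and len(states.states):
        focal = report["hypomethylated_subtype"]
        feats = classifier_features(cohort, cmap, states)
        labels = result.assignment_series().reindex(feats.index)
        binary = labels.map(lambda s: "pos" if s == focal else "other")
        cv = cross_validate(feats, binary, "pos", n_folds=config.n_folds, seed=config.seed)
        model = train_nsc(feats, binary, seed=config.seed)
        pd.DataFrame(
            {"score": cv.scores, "truth": cv.truth, "fold": cv.fold}
        ).to_csv(out / "cv_scores.tsv", sep="\t")
        report["classifier"] = {
            "auc_pooled": cv.auc_pooled,
            "auc_fold_mean": cv.auc_fold_mean,
            "auc_ci": list(cv.auc_ci),
            "n_features": len(model.selected_features),
        }
        stage_done("classify", auc=round(cv.auc_pooled, 4))

    if "transfer" in config.stages and model is not None and (
        config.second_cohort or config.simulate_second
    ):
        if config.simulate_second is not None:
            overrides = dict(config.simulate_second)
            share = overrides.pop("share_frac", 1.0)
            gen2 = GeneratorConfig(**{**overrides, "seed": overrides.get("seed", config.seed + 1)})
            cohort2, truth2 = generate_second_cohort(gen2, truth, share_frac=share)
        else:
            cohort2 = load_cohort(config.second_cohort)
        cohort2 = preprocess_cohort(
            cohort2, config.beta_max_missing, config.expr_max_missing, config.knn_k
        )
        tumor2 = cohort2.beta.tumor_samples
        feats2 = cohort2.beta.values.loc[:, tumor2].T
        calls2 = transfer_classify(
            model, feats2, "pos", conf_low=config.conf_low, conf_high=config.conf_high
        )
        calls2.to_csv(out / "transfer_calls.tsv", sep="\t")
        report["transfer"] = {
            "n_positive": int((calls2["call"] == "positive").sum()),
            "n_abstain": int((calls2["call"] == "abstain").sum()),
        }
        if truth2 is not None:
            try:
                chi2, p = enrichment_test(
                    truth2.subtype_of().reindex(calls2.index).to_numpy(),
                    (calls2["call"] == "positive").to_numpy(),
                    focal_subtype=0,
                )
                report["transfer"]["enrichment_chi2"] = chi2
                report["transfer"]["enrichment_p"] = p
            except ValueError as exc:
                report["transfer"]["enrichment_error"] = str(exc)
        stage_done("transfer", n_positive=report["transfer"]["n_positive"])

    if "scores" in config.stages and len(states.states):
        hypo_sets = hypo_cpg_sets(states, cmap)
        universe = list(cohort.beta.values.index)
        signature = truth.signature if truth is not None else universe[: config.n_draws]
        overlap = signature_overlap(
            hypo_sets, signature, universe, n_draws=config.n_draws, seed=config.seed
        )
        overlap.to_csv(out / "overlap_indices.tsv", sep="\t")
        lesions = lesion_scores(
            cohort.mutations, cohort.copy_number, config.driver_gene, list(overlap.index)
        )
        merged = overlap.join(lesions)
        try:
            slope, p = lesion_overlap_association(
                merged["lesion_score"], merged["index"]
            )
            report["lesion_overlap"] = {"slope": slope, "p": p}
        except ValueError as exc:
            report["lesion_overlap"] = {"error": str(exc)}
        tc = tcell_score(cohort.expression.values)
        tc.to_csv(out / "tcell_scores.tsv", sep="\t")
        stage_done("scores", n_scored=int(len(overlap)))

    report["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
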