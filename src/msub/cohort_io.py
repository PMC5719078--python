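"""Cohort table I/O, missingness filtering, KNN imputation and mutation/CNV normalisation.

All tables are plain TSV with a header row; the first column holds feature
(probe/gene) identifiers and missing values are written as ``NA``. Beta
matrices are probes x samples in [0, 1]; expression matrices are genes x
samples on a log2(x+1) scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics.pairwise import nan_euclidean_distances

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
FLOAT_FORMAT = "%.6g"

#: silent variant classes in MAF-style tables (besides an explicit is_silent column)
SILENT_CLASSES = frozenset({"Silent", "silent"})


class CohortError(ValueError):
    """Fatal cohort-loading problem (missing file, malformed values, no overlap)."""


@dataclass
class BetaMatrix:
    """Probes x samples methylation beta values with tumor/normal labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns are sample ids; entries in
        [0, 1] or NaN.
    group
        Per-sample label, ``"tumor"`` or ``"normal"``, aligned to columns.
    platform
        Per-probe platform membership, one of ``{"450k", "27k", "both"}``.
    """

    values: pd.DataFrame
    group: pd.Series
    platform: pd.Series

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        bad = np.argwhere((vals < 0) | (vals > 1))
        if bad.size:
            i, j = bad[0]
            raise CohortError(
                f"beta value {vals[i, j]:g} outside [0,1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        if self.values.index.has_duplicates:
            raise CohortError("duplicate probe ids")
        if self.values.columns.has_duplicates:
            raise CohortError("duplicate sample ids")
        self.group = self.group.reindex(self.values.columns)
        self.platform = self.platform.reindex(self.values.index)

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.values.columns[self.group == "tumor"])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.values.columns[self.group == "normal"])


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (log2-scale convention)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise CohortError("duplicate gene ids")


@dataclass
class MutationTable:
    """Long-format somatic mutations: sample_id, gene, variant_classification, is_silent."""

    rows: pd.DataFrame

    REQUIRED = ("sample_id", "gene", "variant_classification", "is_silent")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise CohortError(f"mutation table missing columns: {missing}")

    def nonsilent_counts(self, gene: str) -> pd.Series:
        """Per-sample count of non-silent mutations in *gene*."""
        sub = self.rows[(self.rows["gene"] == gene) & (~self.rows["is_silent"])]
        return sub.groupby("sample_id").size()


@dataclass
class CopyNumberTable:
    """GISTIC-thresholded calls: sample_id, gene, gistic_score in {-2..2}."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        scores = self.rows["gistic_score"].to_numpy()
        if not np.isin(scores, [-2, -1, 0, 1, 2]).all():
            bad = scores[~np.isin(scores, [-2, -1, 0, 1, 2])][0]
            raise CohortError(f"gistic score {bad} outside {{-2..2}}")

    def score(self, gene: str) -> pd.Series:
        sub = self.rows[self.rows["gene"] == gene]
        return sub.set_index("sample_id")["gistic_score"]


@dataclass
class ProbeManifest:
    """Probe annotation: probe_id -> gene(s), chromosome, 0-based position, platform.

    Probes mapping to several genes carry a comma-separated gene field and are
    expanded on demand by :meth:`genes_for`.
    """

    table: pd.DataFrame  # index probe_id; columns chrom, start, gene, platform

    def __post_init__(self) -> None:
        if (self.table["start"] < 0).any():
            raise CohortError("negative probe position in manifest")

    def genes_for(self, probe_id: str) -> list[str]:
        gene = self.table.at[probe_id, "gene"]
        if pd.isna(gene) or gene == "":
            return []
        return str(gene).split(",")

    def gene_to_probes(self) -> dict[str, list[str]]:
        """Invert the manifest; multi-gene probes appear under every gene."""
        out: dict[str, list[str]] = {}
        for pid, gene in self.table["gene"].items():
            for g in ([] if pd.isna(gene) else str(gene).split(",")):
                if g:
                    out.setdefault(g, []).append(pid)
        return out


@dataclass
class Cohort:
    """Aligned bundle of all cohort tables."""

    beta: BetaMatrix
    expression: ExpressionMatrix
    mutations: MutationTable
    copy_number: CopyNumberTable
    manifest: ProbeManifest
    dropped_samples: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers / writers


def read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format=FLOAT_FORMAT)


def read_maf(path: str | Path) -> MutationTable:
    """Read a MAF-like TSV (Tumor_Sample_Barcode, Hugo_Symbol, Variant_Classification)."""
    path = Path(path)
    if not path.exists():
        raise CohortError(f"missing file: {path}")
    raw = pd.read_csv(path, sep="\t")
    rows = pd.DataFrame(
        {
            "sample_id": raw["Tumor_Sample_Barcode"].astype(str),
            "gene": raw["Hugo_Symbol"].astype(str),
            "variant_classification": raw["Variant_Classification"].astype(str),
        }
    )
    rows["is_silent"] = rows["variant_classification"].isin(SILENT_CLASSES)
    return MutationTable(rows)


def read_gistic(path: str | Path) -> CopyNumberTable:
    """Read an ``all_thresholded.by_genes``-style TSV (genes x samples of calls)."""
    wide = read_matrix(path)
    long = wide.stack().reset_index()
    long.columns = ["gene", "sample_id", "gistic_score"]
    long["gistic_score"] = long["gistic_score"].astype(int)
    return CopyNumberTable(long[["sample_id", "gene", "gistic_score"]])


def read_manifest(path: str | Path) -> ProbeManifest:
    """Read a BED-like manifest: chrom, start (0-based), probe_id, gene, platform."""
    path = Path(path)
    if not path.exists():
        raise CohortError(f"missing file: {path}")
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "probe_id", "gene", "platform"],
        header=0,
    )
    df = df.set_index("probe_id")
    return ProbeManifest(df[["chrom", "start", "gene", "platform"]])


def load_cohort(config: str | Path | dict) -> Cohort:
    """Load and align all cohort tables from a path-set descriptor.

    *config* is a YAML file (or pre-parsed dict) with keys ``beta``,
    ``groups``, ``expression``, ``mutations``, ``copy_number``, ``manifest``.
    Samples absent from either the beta or the expression matrix are dropped
    from both (with a logged warning); zero overlap is fatal.
    """
    if not isinstance(config, dict):
        cfg_path = Path(config)
        if not cfg_path.exists():
            raise CohortError(f"missing config: {cfg_path}")
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh)
        base = cfg_path.parent
        config = {k: (base / v if isinstance(v, str) else v) for k, v in config.items()}

    beta_df = read_matrix(config["beta"])
    groups = pd.read_csv(config["groups"], sep="\t", index_col=0)["group"]
    groups.index = groups.index.astype(str)
    expr_df = read_matrix(config["expression"])
    manifest = read_manifest(config["manifest"])
    mutations = read_maf(config["mutations"])
    copy_number = read_gistic(config["copy_number"])

    platform = manifest.table["platform"].reindex(beta_df.index).fillna("both")

    tumor_beta = [s for s in beta_df.columns if groups.get(s) == "tumor"]
    shared = [s for s in tumor_beta if s in set(expr_df.columns)]
    if not shared:
        raise CohortError("zero tumor-sample overlap between beta and expression")
    dropped = {
        "beta_only": sorted(set(tumor_beta) - set(shared)),
        "expression_only": sorted(set(expr_df.columns) - set(beta_df.columns)),
    }
    for key, ids in dropped.items():
        if ids:
            logger.warning("dropping %d %s sample(s): %s", len(ids), key, ids)

    keep_beta = [s for s in beta_df.columns if groups.get(s) == "normal" or s in set(shared)]
    beta = BetaMatrix(beta_df[keep_beta], groups.reindex(keep_beta), platform)
    expression = ExpressionMatrix(expr_df[shared])
    return Cohort(beta, expression, mutations, copy_number, manifest, dropped)


# ---------------------------------------------------------------------------
# preprocessing


def filter_missing(df: pd.DataFrame, max_missing_fraction: float) -> pd.DataFrame:
    """Drop rows, then columns, whose missing fraction strictly exceeds the threshold.

    Mirrors the 10% (expression) / 20% (methylation) preprocessing filters.
    Row-first order: a row is judged on all original columns, a column on the
    surviving rows.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    out = df
    while True:
        row_frac = out.isna().mean(axis=1)
        out = out.loc[row_frac <= max_missing_fraction]
        if out.empty:
            raise CohortError("empty matrix after missingness filtering")
        col_frac = out.isna().mean(axis=0)
        out = out.loc[:, col_frac <= max_missing_fraction]
        if out.shape[1] == 0:
            raise CohortError("empty matrix after missingness filtering")
        # dropping columns can push surviving rows back over the threshold;
        # repeat (row-first) until stable so the output satisfies both bounds
        if (out.isna().mean(axis=1) <= max_missing_fraction).all():
            return out


def knn_impute(df: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Impute missing cells by the mean of the *k* nearest rows at that column.

    Distances are Euclidean over co-observed columns, rescaled for the number
    of co-observed entries (the Troyanskaya KNNimpute convention); candidate
    neighbours must themselves observe the target column. Observed cells are
    returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if df.isna().all(axis=1).any():
        raise CohortError("row with no observed values cannot be imputed")
    X = df.to_numpy(dtype=float)
    if not np.isnan(X).any():
        return df.copy()
    if k > X.shape[0] - 1:
        warnings.warn(
            f"k={k} exceeds available rows ({X.shape[0] - 1}); using all rows",
            stacklevel=2,
        )
        k = X.shape[0] - 1
    D = nan_euclidean_distances(X)
    np.fill_diagonal(D, np.inf)
    out = X.copy()
    miss_rows, miss_cols = np.where(np.isnan(X))
    for i, j in zip(miss_rows, miss_cols):
        cand = np.where(~np.isnan(X[:, j]) & np.isfinite(D[i]))[0]
        if cand.size == 0:
            raise CohortError(f"no neighbour observes column {df.columns[j]!r}")
        order = cand[np.argsort(D[i, cand], kind="stable")]
        out[i, j] = X[order[:k], j].mean()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def drop_silent_mutations(table: MutationTable) -> MutationTable:
    """Remove rows flagged silent (MutSig-style preprocessing)."""
    keep = ~table.rows["is_silent"].astype(bool)
    return MutationTable(table.rows.loc[keep].reset_index(drop=True))


def batch_correct(df: pd.DataFrame, batch_column=None):
    """Placeholder hook for ComBat-style batch correction."""
    if batch_column is not None:
        raise NotImplementedError("batch correction is not implemented")
    return df
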