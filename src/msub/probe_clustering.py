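"""Collapse correlated CpG probes of each gene into clusters.

Probes of one gene are clustered by complete-linkage hierarchical clustering
on the distance 1 - Pearson correlation across samples, and the tree is cut
at a fixed height; per-cluster methylation is the unweighted mean beta of the
member probes. This reduces multiple testing over strongly co-methylated
probes before mixture modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort_io import BetaMatrix, ProbeManifest

logger = logging.getLogger(__name__)

DEFAULT_CUT_HEIGHT = 0.4


@dataclass
class ProbeClusterMap:
    """gene -> clusters -> probes; cluster ids are ``GENE--cluster--k``."""

    clusters: dict[str, list[str]] = field(default_factory=dict)
    gene_of: dict[str, str] = field(default_factory=dict)

    def add(self, gene: str, members: list[str]) -> str:
        k = sum(1 for g in self.gene_of.values() if g == gene) + 1
        cid = f"{gene}--cluster--{k}"
        self.clusters[cid] = list(members)
        self.gene_of[cid] = gene
        return cid

    def clusters_of_gene(self, gene: str) -> list[str]:
        return [cid for cid, g in self.gene_of.items() if g == gene]

    def to_frame(self) -> pd.DataFrame:
        rows = [(cid, p) for cid, probes in self.clusters.items() for p in probes]
        return pd.DataFrame(rows, columns=["cluster_id", "probe_id"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeClusterMap":
        out = cls()
        for cid, sub in df.groupby("cluster_id", sort=False):
            out.clusters[cid] = list(sub["probe_id"])
            out.gene_of[cid] = cid.split("--cluster--")[0]
        return out


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows; zero-variance rows get distance 2."""
    sd = X.std(axis=1)
    ok = sd > 0
    D = np.full((X.shape[0], X.shape[0]), 2.0)
    if ok.sum() >= 2:
        r = np.corrcoef(X[ok])
        D[np.ix_(np.where(ok)[0], np.where(ok)[0])] = 1.0 - r
    np.fill_diagonal(D, 0.0)
    # guard tiny negative values from float error
    return np.clip(D, 0.0, 2.0)


def cluster_probes(
    beta: BetaMatrix | pd.DataFrame,
    manifest: ProbeManifest,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> ProbeClusterMap:
    """Cluster each gene's probes at ``1 - r`` distance, cut at *cut_height*.

    Probes without a gene in the manifest are dropped with a warning;
    probes annotated to several genes enter each gene's pool. Zero-variance
    probes cannot enter a correlation and are isolated into singleton
    clusters.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    if values.isna().any().any():
        raise ValueError("beta matrix must be complete (impute first)")
    gene_probes = manifest.gene_to_probes()
    present = set(values.index)
    mapped = {p for probes in gene_probes.values() for p in probes}
    unmapped = present - mapped
    if unmapped:
        logger.warning("dropping %d probe(s) with no gene annotation", len(unmapped))

    cmap = ProbeClusterMap()
    for gene in sorted(gene_probes):
        probes = sorted(p for p in gene_probes[gene] if p in present)
        if not probes:
            continue
        if len(probes) == 1:
            cmap.add(gene, probes)
            continue
        X = values.loc[probes].to_numpy(dtype=float)
        sd = X.std(axis=1)
        flat = [p for p, s in zip(probes, sd) if s == 0]
        variable = [p for p, s in zip(probes, sd) if s > 0]
        if flat:
            logger.warning(
                "gene %s: %d zero-variance probe(s) placed in singleton clusters",
                gene,
                len(flat),
            )
            for p in flat:
                cmap.add(gene, [p])
        if len(variable) == 1:
            cmap.add(gene, variable)
            continue
        if not variable:
            continue
        D = _correlation_distance(values.loc[variable].to_numpy(dtype=float))
        Z = linkage(squareform(D, checks=False), method="complete")
        labels = fcluster(Z, t=cut_height, criterion="distance")
        for lab in np.unique(labels):
            cmap.add(gene, [p for p, l in zip(variable, labels) if l == lab])
    return cmap


def cluster_mean_beta(
    beta: BetaMatrix | pd.DataFrame, cmap: ProbeClusterMap
) -> pd.DataFrame:
    """Cluster x sample matrix of unweighted mean beta over member probes."""
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    rows = {}
    for cid, probes in cmap.clusters.items():
        absent = [p for p in probes if p not in values.index]
        if absent:
            raise KeyError(f"cluster {cid} references absent probe(s) {absent}")
        rows[cid] = values.loc[probes].mean(axis=0)
    return pd.DataFrame(rows).T.reindex(list(cmap.clusters))
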