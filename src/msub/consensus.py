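"""Consensus k-means subtyping of methylation profiles.

Repeated k-means on subsampled cohorts builds, for each candidate k, a
consensus matrix of co-clustering frequencies; stable subtypes appear as
clean blocks. The number of clusters is chosen automatically by minimising
the proportion of ambiguous clustering (PAC) — the fraction of consensus
entries far from both 0 and 1 — as a reproducible surrogate for visual
inspection of consensus CDF plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans

DEFAULT_N_REPS = 1000
DEFAULT_SUBSAMPLE = 0.8
DEFAULT_KMAX = 10
PAC_LOWER = 0.1
PAC_UPPER = 0.9
KMEANS_RESTARTS = 10


@dataclass
class ConsensusResult:
    """Consensus matrices, assignments and PAC per k, plus the chosen k."""

    sample_ids: list[str]
    matrices: dict[int, np.ndarray] = field(default_factory=dict)
    assignments: dict[int, np.ndarray] = field(default_factory=dict)
    pac: dict[int, float] = field(default_factory=dict)
    chosen_k: int = 2
    flat_warning: bool = False

    def assignment_series(self, k: int | None = None) -> pd.Series:
        k = self.chosen_k if k is None else k
        return pd.Series(self.assignments[k], index=self.sample_ids, name="subtype")


def _pac(M: np.ndarray, lower: float = PAC_LOWER, upper: float = PAC_UPPER) -> float:
    iu = np.triu_indices_from(M, k=1)
    vals = M[iu]
    return float(((vals > lower) & (vals < upper)).mean())


def consensus_cluster(
    features: pd.DataFrame,
    k_max: int = DEFAULT_KMAX,
    n_reps: int = DEFAULT_N_REPS,
    subsample_frac: float = DEFAULT_SUBSAMPLE,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus k-means over *features* (samples x features).

    For each k in 2..k_max, runs ``n_reps`` k-means fits on random
    ``subsample_frac`` subsets of samples; the consensus entry for a sample
    pair is the co-clustering count divided by the co-sampling count. Final
    assignments cut an average-linkage tree on 1 - consensus. Deterministic
    given *seed*.
    """
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n < 3 * k_max:
        raise ValueError(f"need at least {3 * k_max} samples for k_max={k_max}")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_frac * n)))
    result = ConsensusResult(sample_ids=list(features.index))
    for k in range(2, k_max + 1):
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(n_reps):
            idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
            km = KMeans(
                n_clusters=k,
                n_init=KMEANS_RESTARTS,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(X[idx])
            lab = km.labels_
            sampled[np.ix_(idx, idx)] += 1
            same = lab[:, None] == lab[None, :]
            together[np.ix_(idx, idx)] += same
        if ((sampled == 0) & ~np.eye(n, dtype=bool)).any():
            raise ValueError("some sample pair never co-sampled; increase n_reps")
        np.fill_diagonal(sampled, 1.0)
        M = together / sampled
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2
        Z = linkage(squareform(1 - M, checks=False), method="average")
        result.matrices[k] = M
        result.assignments[k] = fcluster(Z, t=k, criterion="maxclust") - 1
        result.pac[k] = _pac(M)
    result.chosen_k = select_k(result)
    return result


def select_k(result: ConsensusResult) -> int:
    """Choose the largest k whose PAC ties the minimum (within 0.01).

    Minimising PAC alone under-segments: merging two true clusters
    consistently is also "stable" (PAC 0), so among equally unambiguous k we
    keep the finest partition — the automated surrogate for reading the
    consensus CDF plots. A near-flat PAC profile (no structure) is flagged
    and falls back to k = 2 for manual inspection.
    """
    pac = result.pac
    best = min(pac.values())
    spread = max(pac.values()) - best
    if spread < 0.05:
        result.flat_warning = True
        return min(pac)
    eligible = [k for k in sorted(pac) if pac[k] <= best + 0.01]
    return max(eligible)


def pac_table(result: ConsensusResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"k": sorted(result.pac), "pac": [result.pac[k] for k in sorted(result.pac)]}
    )


def consensus_cdf(result: ConsensusResult, k: int, grid: int = 101) -> pd.DataFrame:
    """Empirical CDF of the upper-triangle consensus entries (for inspection plots)."""
    M = result.matrices[k]
    vals = M[np.triu_indices_from(M, k=1)]
    xs = np.linspace(0, 1, grid)
    cdf = np.searchsorted(np.sort(vals), xs, side="right") / vals.size
    return pd.DataFrame({"consensus": xs, "cdf": cdf})


def enrichment_test(subtype_labels, binary_trait, focal_subtype=None):
    """Pearson chi-squared (no continuity correction) of a binary trait vs subtype.

    With *focal_subtype* given, tests the 2x2 in-subtype/out-of-subtype table;
    otherwise the full subtype x trait contingency table.
    """
    labels = np.asarray(subtype_labels)
    trait = np.asarray(binary_trait, dtype=bool)
    if labels.size != trait.size:
        raise ValueError("labels and trait must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 subtypes")
    if trait.all() or not trait.any():
        raise ValueError("degenerate table: trait is constant")
    if focal_subtype is not None:
        labels = np.where(labels == focal_subtype, "in", "out")
    table = pd.crosstab(pd.Series(labels), pd.Series(trait)).to_numpy()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero margin")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)
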