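"""Differential and signature-overlap statistics.

Covers the SAM-style moderated statistic with permutation q-values, Wilcoxon
rank-sum comparisons, cross-cohort patient correlation matrices, the driver
lesion score (nonsilent mutation count plus the additive inverse of the
GISTIC call), the per-patient signature overlap index with its resampled
random null, the linear lesion-overlap association, the 13-gene T-cell
expression score, and half-up percentage rounding for contingency summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import linregress, mannwhitneyu, pearsonr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_N_DRAWS = 10

#: 13-transcript T-cell signature used to infer relative T-cell infiltration
TCELL_SIGNATURE = (
    "CD8A", "CCL2", "CCL3", "CCL4", "CXCL9", "CXCL10", "ICOS",
    "GZMK", "IRF1", "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB",
)


def load_tcell_signature() -> list[str]:
    """Signature gene list from the packaged text file."""
    text = resources.files("msub").joinpath("data/tcell_signature.txt").read_text()
    return [g.strip() for g in text.splitlines() if g.strip() and not g.startswith("#")]


# ---------------------------------------------------------------------------
# SAM


@dataclass
class SamResult:
    table: pd.DataFrame  # per feature: d, s, mean_diff, q
    s0: float
    n_permutations: int


def _sam_d(X: np.ndarray, g1: np.ndarray, g2: np.ndarray, s0: float | None):
    x1, x2 = X[:, g1], X[:, g2]
    n1, n2 = x1.shape[1], x2.shape[1]
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    pooled = (
        ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / (n1 + n2 - 2)
    s = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    if s0 is None:
        s0 = float(np.median(s))
    return diff / (s + s0), s, diff, s0


def sam_test(
    matrix: pd.DataFrame,
    group_labels,
    n_permutations: int = 200,
    seed: int = 0,
    s0: float | None = None,
) -> SamResult:
    """SAM moderated statistic with permutation-based q-values.

    ``d_i = (mean_1 - mean_2) / (s_i + s0)`` with ``s0`` the median of the
    per-feature standard errors (configurable). The q-value for feature *i*
    follows the SAM median-false-positive convention: the median, over label
    permutations, of the number of null |d*| at least |d_i|, divided by the
    observed count of |d| at least |d_i|.
    """
    labels = np.asarray(group_labels)
    groups = sorted(pd.unique(labels))  # sorted: d's sign does not depend on row order
    if len(groups) != 2:
        raise ValueError("sam_test needs exactly two groups")
    g1 = np.where(labels == groups[0])[0]
    g2 = np.where(labels == groups[1])[0]
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("each group needs n >= 3")
    if n_permutations < 50:
        warnings.warn("fewer than 50 permutations: unstable q-values", stacklevel=2)
    X = matrix.to_numpy(dtype=float)
    d, s, diff, s0 = _sam_d(X, g1, g2, s0)

    rng = np.random.default_rng(seed)
    abs_d = np.abs(d)
    order = np.argsort(-abs_d, kind="stable")
    thresholds = abs_d[order]
    observed_ge = np.arange(1, len(d) + 1)  # count of |d| >= each sorted threshold
    null_counts = np.empty((n_permutations, len(d)))
    idx = np.arange(labels.size)
    for b in range(n_permutations):
        perm = rng.permutation(idx)
        pd_, _, _, _ = _sam_d(X, perm[: len(g1)], perm[len(g1):], s0)
        null_sorted = np.sort(np.abs(pd_))
        null_counts[b] = len(d) - np.searchsorted(null_sorted, thresholds, side="left")
    med_fp = np.median(null_counts, axis=0)
    q_sorted = np.clip(med_fp / observed_ge, 0, 1)
    # enforce monotonicity in |d|: smaller |d| cannot have smaller q
    q_sorted = np.maximum.accumulate(q_sorted)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    table = pd.DataFrame(
        {"d": d, "s": s, "mean_diff": diff, "q": q}, index=matrix.index
    )
    return SamResult(table=table, s0=s0, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# rank / correlation statistics


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null for small samples (n <= 20 per group, no ties), normal
    approximation with tie correction otherwise; all values tied gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def patient_correlation_matrix(
    beta_a: pd.DataFrame, beta_b: pd.DataFrame, shared_feature_ids=None
) -> pd.DataFrame:
    """Pearson r between every cross-cohort sample pair over shared features.

    Rows are cohort-B samples, columns cohort-A samples (heatmap convention);
    no clustering is applied. Zero-variance profiles give NaN with a warning.
    """
    if shared_feature_ids is None:
        shared_feature_ids = [f for f in beta_a.index if f in set(beta_b.index)]
    shared = list(shared_feature_ids)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared features")
    A = beta_a.loc[shared].to_numpy(dtype=float)  # features x samples_a
    B = beta_b.loc[shared].to_numpy(dtype=float)
    Ac = A - A.mean(axis=0, keepdims=True)
    Bc = B - B.mean(axis=0, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=0))
    sb = np.sqrt((Bc**2).sum(axis=0))
    if (sa == 0).any() or (sb == 0).any():
        warnings.warn("zero-variance profile(s); correlations set to NaN", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Bc.T @ Ac) / np.outer(np.where(sb == 0, np.nan, sb), np.where(sa == 0, np.nan, sa))
    return pd.DataFrame(R, index=beta_b.columns, columns=beta_a.columns)


# ---------------------------------------------------------------------------
# lesion and overlap scores


def lesion_score(n_mut: int, gistic: int) -> int:
    """Driver lesion score: nonsilent mutation count + (-GISTIC call).

    Approximates the number of inactivated alleles. The literal formula is
    applied; an amplification (gistic > 0) therefore contributes negatively
    and triggers a warning.
    """
    if gistic not in (-2, -1, 0, 1, 2):
        raise ValueError(f"gistic score {gistic} outside {{-2..2}}")
    if n_mut < 0:
        raise ValueError("n_mut must be >= 0")
    if gistic > 0:
        warnings.warn(
            "amplification contributes negatively to the lesion score", stacklevel=2
        )
    return int(n_mut) + (-int(gistic))


def lesion_scores(
    mutations, copy_number, gene: str, sample_ids
) -> pd.DataFrame:
    """Per-sample lesion table for *gene*: n_mut, gistic, lesion_score."""
    counts = mutations.nonsilent_counts(gene)
    gis = copy_number.score(gene)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in sample_ids:
            n_mut = int(counts.get(s, 0))
            g = int(gis.get(s, 0))
            rows.append((s, n_mut, g, lesion_score(n_mut, g)))
    return pd.DataFrame(
        rows, columns=["sample_id", "n_mut", "gistic", "lesion_score"]
    ).set_index("sample_id")


def overlap_index(hypo_cpgs, signature) -> float:
    """|hypo ∩ signature| / |hypo| for one patient's hypomethylated CpG set."""
    hypo = set(hypo_cpgs)
    if not hypo:
        raise ValueError("empty hypomethylated CpG set: index undefined")
    return len(hypo & set(signature)) / len(hypo)


def random_overlap_index(
    hypo_cpgs, universe, m: int, n_draws: int = DEFAULT_N_DRAWS, seed: int = 0
) -> float:
    """Mean overlap index against *n_draws* random signatures of size *m*.

    Signatures are sampled uniformly without replacement from *universe*;
    the expectation is m/|universe|.
    """
    universe = list(universe)
    hypo = set(hypo_cpgs)
    if m > len(universe):
        raise ValueError("signature size exceeds universe")
    if not hypo <= set(universe):
        raise ValueError("hypomethylated CpGs must lie in the universe")
    if m == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_draws):
        sig = rng.choice(len(universe), size=m, replace=False)
        sig_ids = {universe[i] for i in sig}
        vals.append(overlap_index(hypo, sig_ids))
    return float(np.mean(vals))


@dataclass
class SignatureOverlapResult:
    sample_id: str
    n_hypo_cpgs: int
    n_overlap: int
    index: float
    random_index: float
    n_draws: int


def signature_overlap(
    hypo_cpgs_per_sample: dict[str, set],
    signature,
    universe,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-patient overlap and random-null indices against a CpG signature.

    Patients with an empty hypomethylated set are excluded with a warning.
    """
    signature = set(signature)
    rows = []
    for i, (sid, hypo) in enumerate(sorted(hypo_cpgs_per_sample.items())):
        if not hypo:
            logger.warning("sample %s has no hypomethylated CpGs; excluded", sid)
            continue
        idx = overlap_index(hypo, signature)
        rnd = random_overlap_index(
            hypo, universe, m=len(signature), n_draws=n_draws, seed=seed + i
        )
        rows.append(
            SignatureOverlapResult(sid, len(hypo), int(round(idx * len(hypo))), idx, rnd, n_draws)
        )
    return pd.DataFrame(
        [(r.sample_id, r.n_hypo_cpgs, r.n_overlap, r.index, r.random_index) for r in rows],
        columns=["sample_id", "n_hypo_cpgs", "n_overlap", "index", "random_index"],
    ).set_index("sample_id")


def lesion_overlap_association(lesion_scores_vec, overlap_indices) -> tuple[float, float]:
    """OLS of overlap index on lesion score: (slope, two-sided p for the slope)."""
    x = np.asarray(lesion_scores_vec, dtype=float)
    y = np.asarray(overlap_indices, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) == 0:
        raise ValueError("constant lesion score")
    res = linregress(x, y)
    return float(res.slope), float(res.pvalue)


# ---------------------------------------------------------------------------
# expression signatures and plumbing


def tcell_score(expression: pd.DataFrame, signature=None) -> pd.Series:
    """Per-sample mean expression over the available T-cell signature genes."""
    genes = list(signature) if signature is not None else list(TCELL_SIGNATURE)
    present = [g for g in genes if g in expression.index]
    missing = [g for g in genes if g not in expression.index]
    if missing:
        logger.warning("%d signature gene(s) absent: %s", len(missing), missing)
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    return expression.loc[present].mean(axis=0).rename("tcell_score")


def score_gene_correlation(score: pd.Series, expression_row: pd.Series):
    """Pearson r and p between a per-sample score and one gene's expression."""
    shared = [s for s in score.index if s in expression_row.index]
    r, p = pearsonr(score.loc[shared], expression_row.loc[shared])
    return float(r), float(p)


def fraction_percent(numerator: int, denominator: int) -> int:
    """Percentage rounded half-up to the nearest integer (57 for 24/42)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return int(np.floor(100.0 * numerator / denominator + 0.5))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for panels of rank tests."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
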