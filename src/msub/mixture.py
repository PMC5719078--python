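"""Beta-mixture calling of abnormal DNA methylation states.

For each gene's CpG cluster, tumor beta values are modelled as a mixture of
beta distributions (K = 1..3 components, chosen by BIC). Each component mean
is compared with the matched normal-tissue mean to give a differential
methylation (DM) value, and each tumor sample is assigned to its
maximum-posterior component. A cluster is called *abnormal* when at least one
component deviates from normal tissue by ``dm_min`` and the cluster's
methylation is inversely coupled with the expression of its gene across
tumors — the MethylMix-style integration of methylation and expression.

The EM uses an exact E-step and a Newton ascent M-step on the weighted beta
log-likelihood (a generalized EM), so the observed-data log-likelihood is
non-decreasing across iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp, polygamma, psi
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

EPS_CLAMP = 1e-6
MIN_SAMPLES = 10
DEFAULT_DM_MIN = 0.10
DEFAULT_COUPLING_R = -0.3
DEFAULT_COUPLING_P = 0.05
MERGE_MEAN_TOL = 0.05
MAX_ITER = 500
LL_TOL = 1e-6
N_RESTARTS = 3


@dataclass
class BetaMixtureFit:
    """Fitted beta mixture: shape parameters, weights and model scores."""

    alpha: np.ndarray
    beta: np.ndarray
    pi: np.ndarray
    loglik: float
    n: int
    converged: bool = True

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def means(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)

    @property
    def bic(self) -> float:
        p = 3 * self.K - 1
        return -2.0 * self.loglik + p * np.log(self.n)

    def log_responsibilities(self, values: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(values, dtype=float), EPS_CLAMP, 1 - EPS_CLAMP)
        lx, l1x = np.log(x), np.log1p(-x)
        comp = (
            (self.alpha[:, None] - 1) * lx[None, :]
            + (self.beta[:, None] - 1) * l1x[None, :]
            - betaln(self.alpha, self.beta)[:, None]
            + np.log(self.pi)[:, None]
        )
        return comp - logsumexp(comp, axis=0, keepdims=True)

    def posterior(self, values: np.ndarray) -> np.ndarray:
        """Component responsibilities, shape (K, n)."""
        return np.exp(self.log_responsibilities(values))

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Maximum-posterior component index per value."""
        return np.argmax(self.log_responsibilities(values), axis=0)


def _moments_to_shapes(mean: float, var: float, default_prec: float = 30.0):
    mean = float(np.clip(mean, 1e-3, 1 - 1e-3))
    cap = mean * (1 - mean)
    if var <= 0 or var >= cap:
        prec = default_prec
    else:
        prec = cap / var - 1.0
    prec = float(np.clip(prec, 0.1, 1e4))
    return mean * prec, (1 - mean) * prec


def _newton_update(a, b, T1, T2, n_steps=8):
    """Vectorised Newton ascent of the per-component weighted beta likelihood.

    Maximises g_c(a, b) = (a-1) T1_c + (b-1) T2_c - betaln(a, b) for every
    component at once, backtracking per component so the objective never
    decreases (partial maximisation: the EM stays a monotone generalized EM).
    """

    def obj(aa, bb):
        return (aa - 1) * T1 + (bb - 1) * T2 - betaln(aa, bb)

    f = obj(a, b)
    for _ in range(n_steps):
        dab = psi(a + b)
        ga = T1 - psi(a) + dab
        gb = T2 - psi(b) + dab
        if max(np.abs(ga).max(), np.abs(gb).max()) < 1e-9:
            break
        t = polygamma(1, a + b)
        haa = -polygamma(1, a) + t
        hbb = -polygamma(1, b) + t
        det = haa * hbb - t * t
        det = np.where(np.abs(det) < 1e-30, np.nan, det)
        # solve H @ step = g; ascent direction is -step for negative-definite H
        sa = -(hbb * ga - t * gb) / det
        sb = -(haa * gb - t * ga) / det
        bad = ~np.isfinite(sa) | ~np.isfinite(sb)
        sa = np.where(bad, 0.0, sa)
        sb = np.where(bad, 0.0, sb)
        accepted = np.zeros_like(a, dtype=bool)
        lam = 1.0
        for _ in range(8):
            na = np.where(accepted, a, a + lam * sa)
            nb = np.where(accepted, b, b + lam * sb)
            # upper cap prevents the likelihood blow-up of a near-singular
            # component collapsing onto a handful of identical values
            valid = (na > 1e-4) & (nb > 1e-4) & (na < 1e4) & (nb < 1e4)
            na = np.where(valid, na, a)
            nb = np.where(valid, nb, b)
            nf = obj(na, nb)
            take = ~accepted & valid & (nf >= f)
            a = np.where(take, na, a)
            b = np.where(take, nb, b)
            f = np.where(take, nf, f)
            accepted |= take
            if accepted.all():
                break
            lam *= 0.5
        if not accepted.any():
            break
    return a, b


def _em(x, lx, l1x, alpha, beta, pi, max_iter=MAX_ITER, tol=LL_TOL, trace=None):
    n = x.size
    ll_prev = -np.inf
    converged = False
    prev_a = alpha.copy()
    prev_b = beta.copy()
    for it in range(max_iter):
        comp = (
            (alpha[:, None] - 1) * lx[None, :]
            + (beta[:, None] - 1) * l1x[None, :]
            - betaln(alpha, beta)[:, None]
            + np.log(pi)[:, None]
        )
        cmax = comp.max(axis=0)
        norm = cmax + np.log(np.exp(comp - cmax[None, :]).sum(axis=0))
        ll = float(norm.sum())
        if trace is not None:
            trace.append(ll)
        r = np.exp(comp - norm[None, :])
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
        W = r.sum(axis=1)
        pi = np.clip(W / n, 1e-10, None)
        pi = pi / pi.sum()
        Ws = np.maximum(W, 1e-12)
        T1 = (r @ lx) / Ws
        T2 = (r @ l1x) / Ws
        alpha, beta = _newton_update(alpha, beta, T1, T2, n_steps=3)
        # secondary stop: parameters stalled while the likelihood creeps
        rel = max(
            np.max(np.abs(alpha - prev_a) / (1 + np.abs(prev_a))),
            np.max(np.abs(beta - prev_b) / (1 + np.abs(prev_b))),
        )
        if it > 10 and rel < 1e-6:
            converged = True
            break
        # collapsing components converge extremely slowly along a degenerate
        # ridge; once two means are inside the merge tolerance the fit will
        # be merged and refit at lower K anyway, so stop here
        if it >= 20 and it % 5 == 0 and len(pi) > 1:
            mu = np.sort(alpha / (alpha + beta))
            if np.min(np.diff(mu)) < MERGE_MEAN_TOL:
                converged = True
                break
        prev_a = alpha.copy()
        prev_b = beta.copy()
    return alpha, beta, pi, ll_prev, converged


def _quantile_init(xs, K):
    """Deterministic init: contiguous quantile blocks of the sorted values."""
    groups = np.array_split(np.sort(xs), K)
    alpha = np.empty(K)
    beta = np.empty(K)
    pi = np.array([len(g) for g in groups], dtype=float)
    pi /= pi.sum()
    for c, g in enumerate(groups):
        alpha[c], beta[c] = _moments_to_shapes(g.mean(), g.var())
    return alpha, beta, pi


def _random_init(xs, K, rng):
    lab = rng.integers(0, K, size=xs.size)
    alpha = np.empty(K)
    beta = np.empty(K)
    pi = np.full(K, 1.0 / K)
    for c in range(K):
        g = xs[lab == c]
        if g.size < 2:
            g = xs
        alpha[c], beta[c] = _moments_to_shapes(g.mean(), g.var())
    return alpha, beta, pi


def _fit_single_k(x, K, seed, n_restarts=N_RESTARTS):
    x = np.clip(x, EPS_CLAMP, 1 - EPS_CLAMP)
    lx, l1x = np.log(x), np.log1p(-x)
    rng = np.random.default_rng(seed)
    best = None
    inits = [_quantile_init(x, K)]
    if K > 1:
        inits += [_random_init(x, K, rng) for _ in range(n_restarts)]
    for alpha, beta, pi in inits:
        a, b, p, ll, conv = _em(x, lx, l1x, alpha.copy(), beta.copy(), pi.copy())
        if best is None or ll > best.loglik:
            best = BetaMixtureFit(a, b, p, ll, n=x.size, converged=conv)
    order = np.argsort(best.means)
    return BetaMixtureFit(
        best.alpha[order], best.beta[order], best.pi[order], best.loglik,
        best.n, best.converged,
    )


def _merge_close_components(fit: BetaMixtureFit, x: np.ndarray) -> BetaMixtureFit:
    """Merge components whose means differ by < MERGE_MEAN_TOL, then refit shapes."""
    mu = fit.means
    keep = [0]
    groups = [[0]]
    for c in range(1, fit.K):
        if mu[c] - mu[keep[-1]] < MERGE_MEAN_TOL:
            groups[-1].append(c)
        else:
            keep.append(c)
            groups.append([c])
    if len(groups) == fit.K:
        return fit
    x = np.clip(x, EPS_CLAMP, 1 - EPS_CLAMP)
    lx, l1x = np.log(x), np.log1p(-x)
    r = fit.posterior(x)
    K = len(groups)
    alpha = np.empty(K)
    beta = np.empty(K)
    pi = np.empty(K)
    T1 = np.empty(K)
    T2 = np.empty(K)
    for c, grp in enumerate(groups):
        w = r[grp].sum(axis=0)
        pi[c] = fit.pi[grp].sum()
        W = max(w.sum(), 1e-12)
        m = float(w @ x) / W
        alpha[c], beta[c] = _moments_to_shapes(m, 0.01)
        T1[c] = float(w @ lx) / W
        T2[c] = float(w @ l1x) / W
    alpha, beta = _newton_update(alpha, beta, T1, T2, n_steps=20)
    pi /= pi.sum()
    a, b, p, ll, conv = _em(x, lx, l1x, alpha, beta, pi)
    order = np.argsort(a / (a + b))
    return BetaMixtureFit(a[order], b[order], p[order], ll, x.size, conv)


def fit_beta_mixture(values, k_max: int = 3, seed: int = 0) -> BetaMixtureFit:
    """Fit beta mixtures for K = 1..k_max and return the BIC-minimising fit.

    Components closer than ``MERGE_MEAN_TOL`` in mean are merged before model
    selection. Deterministic given *seed* (quantile init + seeded restarts).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_SAMPLES:
        raise ValueError(f"insufficient samples: n={x.size} < {MIN_SAMPLES}")
    fits = []
    for K in range(1, k_max + 1):
        fit = _fit_single_k(x, K, seed=seed + K)
        while fit.K > 1:  # merge until component means stay separated
            merged = _merge_close_components(fit, x)
            if merged.K == fit.K:
                break
            fit = merged
        fits.append(fit)
    best = min(fits, key=lambda f: (f.bic, f.K))
    if not best.converged:
        logger.warning("EM did not converge within %d iterations", MAX_ITER)
    return best


def compute_dm(fit: BetaMixtureFit, normal_values) -> np.ndarray:
    """Per-component DM value: component mean minus the normal-tissue mean."""
    normal = np.asarray(normal_values, dtype=float)
    normal = normal[np.isfinite(normal)]
    if normal.size == 0:
        raise ValueError("empty normal vector")
    return fit.means - normal.mean()


def expression_coupling(
    cluster_beta_row,
    expression_row,
    r_threshold: float = DEFAULT_COUPLING_R,
    p_threshold: float = DEFAULT_COUPLING_P,
):
    """Pearson association between cluster methylation and gene expression.

    Returns ``(r, p, passes)`` where ``passes`` requires r <= r_threshold and
    p < p_threshold over paired tumor samples (inverse coupling).
    """
    x = np.asarray(cluster_beta_row, dtype=float)
    y = np.asarray(expression_row, dtype=float)
    if x.size != y.size:
        raise ValueError("unpaired vectors")
    if x.size < MIN_SAMPLES:
        raise ValueError(f"insufficient paired samples: n={x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; coupling undefined", stacklevel=2)
        return np.nan, np.nan, False
    r, p = pearsonr(x, y)
    return float(r), float(p), bool(r <= r_threshold and p < p_threshold)


@dataclass
class MethylationStateMatrix:
    """Per abnormal gene-cluster x tumor sample: state, DM value, component index."""

    states: pd.DataFrame  # entries in {"hypo", "normal", "hyper"}
    dm: pd.DataFrame  # DM value of the assigned component
    component: pd.DataFrame
    fits: dict[str, BetaMixtureFit] = field(default_factory=dict)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for cid in self.states.index:
            for s in self.states.columns:
                rows.append((cid, s, self.states.at[cid, s], self.dm.at[cid, s]))
        return pd.DataFrame(rows, columns=["cluster_id", "sample_id", "state", "dm"])

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "MethylationStateMatrix":
        states = df.pivot(index="cluster_id", columns="sample_id", values="state")
        dm = df.pivot(index="cluster_id", columns="sample_id", values="dm").astype(float)
        comp = pd.DataFrame(0, index=states.index, columns=states.columns)
        return cls(states=states, dm=dm, component=comp)


def call_states(
    cluster_beta: pd.DataFrame,
    group: pd.Series,
    expression: pd.DataFrame,
    gene_of: dict[str, str],
    dm_min: float = DEFAULT_DM_MIN,
    r_threshold: float = DEFAULT_COUPLING_R,
    p_threshold: float = DEFAULT_COUPLING_P,
    k_max: int = 3,
    seed: int = 0,
) -> tuple[MethylationStateMatrix, pd.DataFrame]:
    """Call methylation states for every gene cluster in *cluster_beta*.

    Parameters
    ----------
    cluster_beta
        Cluster x sample mean-beta matrix (tumor and normal columns).
    group
        Per-sample "tumor"/"normal" labels aligned to columns.
    expression
        Gene x tumor-sample expression matrix (for coupling).
    gene_of
        cluster_id -> gene symbol.

    Returns the state matrix over abnormal clusters and a per-cluster call
    table (is_abnormal, direction, coupling r and p). Per-cluster fit
    failures are logged and skipped, never fatal.
    """
    tumor = [s for s in cluster_beta.columns if group.get(s) == "tumor"]
    normal = [s for s in cluster_beta.columns if group.get(s) == "normal"]
    expr_samples = [s for s in tumor if s in set(expression.columns)]

    calls = []
    state_rows = {}
    dm_rows = {}
    comp_rows = {}
    fits = {}
    for ci, cid in enumerate(cluster_beta.index):
        gene = gene_of.get(cid, cid.split("--cluster--")[0])
        tvals = cluster_beta.loc[cid, tumor].to_numpy(dtype=float)
        nvals = cluster_beta.loc[cid, normal].to_numpy(dtype=float)
        try:
            fit = fit_beta_mixture(tvals, k_max=k_max, seed=seed + ci)
            dm = compute_dm(fit, nvals)
        except (ValueError, FloatingPointError) as exc:
            logger.warning("cluster %s skipped: %s", cid, exc)
            continue
        abnormal_components = np.where(np.abs(dm) >= dm_min)[0]
        direction = ""
        if (dm[abnormal_components] < 0).any():
            direction += "hypo"
        if (dm[abnormal_components] > 0).any():
            direction += "+hyper" if direction else "hyper"
        r = p = np.nan
        passes = False
        if gene in expression.index and len(expr_samples) >= MIN_SAMPLES:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, p, passes = expression_coupling(
                    cluster_beta.loc[cid, expr_samples].to_numpy(dtype=float),
                    expression.loc[gene, expr_samples].to_numpy(dtype=float),
                    r_threshold,
                    p_threshold,
                )
        is_abnormal = bool(len(abnormal_components) and passes)
        calls.append((cid, gene, is_abnormal, direction, r, p, fit.K))
        if not is_abnormal:
            continue
        fits[cid] = fit
        comp = fit.assign(tvals)
        dm_assigned = dm[comp]
        states = np.where(
            dm_assigned <= -dm_min, "hypo", np.where(dm_assigned >= dm_min, "hyper", "normal")
        )
        state_rows[cid] = pd.Series(states, index=tumor)
        dm_rows[cid] = pd.Series(np.where(states == "normal", 0.0, dm_assigned), index=tumor)
        comp_rows[cid] = pd.Series(comp, index=tumor)

    call_table = pd.DataFrame(
        calls,
        columns=["cluster_id", "gene", "is_abnormal", "direction", "r", "p", "K"],
    ).set_index("cluster_id")
    idx = list(state_rows)
    matrix = MethylationStateMatrix(
        states=pd.DataFrame(state_rows).T.reindex(idx),
        dm=pd.DataFrame(dm_rows).T.reindex(idx),
        component=pd.DataFrame(comp_rows).T.reindex(idx),
        fits=fits,
    )
    return matrix, call_table


def count_hypo_per_patient(states: MethylationStateMatrix | pd.DataFrame) -> pd.Series:
    """Number of gene-clusters in the hypomethylated state, per tumor sample."""
    df = states.states if isinstance(states, MethylationStateMatrix) else states
    if df.empty:
        return pd.Series(dtype=int)
    return (df == "hypo").sum(axis=0).astype(int)
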