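"""Nearest shrunken centroids (PAM-style) subtype classification.

Class centroids are shrunk toward the overall centroid by soft-thresholding
the standardised centroid differences (Tibshirani et al. 2002), which selects
features and classifies jointly. Used here to learn a methylation classifier
for a subtype in one cohort, evaluate it by stratified 10-fold
cross-validated AUC, and transfer it to a second cohort over the shared
features with a confidence-abstention rule (call only when the subtype
probability is above ``conf_high`` or below ``conf_low``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

CONF_LOW = 0.40
CONF_HIGH = 0.60


@dataclass
class ShrunkenCentroidModel:
    """Fitted NSC model (shrunken centroids in standardised d-score space)."""

    feature_ids: list[str]
    classes: list
    overall_centroid: np.ndarray  # x̄_i
    centroids: np.ndarray  # x̄_ik, shape (K, p)
    d_shrunk: np.ndarray  # d'_ik after soft threshold, shape (K, p)
    s: np.ndarray  # pooled within-class SD per feature
    s0: float
    mk: np.ndarray  # sqrt(1/n_k - 1/n)
    priors: np.ndarray
    delta: float

    @property
    def shrunken_centroids(self) -> np.ndarray:
        return self.overall_centroid + self.mk[:, None] * (self.s + self.s0) * self.d_shrunk

    @property
    def selected_features(self) -> list[str]:
        mask = (self.d_shrunk != 0).any(axis=0)
        return [f for f, m in zip(self.feature_ids, mask) if m]

    def discriminant(self, X: np.ndarray) -> np.ndarray:
        """delta_k(x) = sum_i (x_i - x̄'_ik)^2 / (s_i+s0)^2 - 2 log pi_k; shape (n, K)."""
        cent = self.shrunken_centroids
        denom = np.maximum(self.s + self.s0, 1e-12) ** 2
        d = ((X[:, None, :] - cent[None, :, :]) ** 2 / denom[None, None, :]).sum(axis=2)
        return d - 2.0 * np.log(self.priors)[None, :]

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Class posteriors exp(-delta_k/2), normalised; shape (n, K)."""
        X = self._align(X)
        d = self.discriminant(X)
        d = d - d.min(axis=1, keepdims=True)
        w = np.exp(-0.5 * d)
        return w / w.sum(axis=1, keepdims=True)

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_ids if f not in X.columns]
            if missing:
                raise KeyError(f"missing features: {missing[:5]}...")
            return X[self.feature_ids].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)


def soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def _fit_at_delta(X, y, classes, delta, priors) -> ShrunkenCentroidModel:
    n, p = X.shape
    K = len(classes)
    overall = X.mean(axis=0)
    cent = np.vstack([X[y == c].mean(axis=0) for c in classes])
    nk = np.array([(y == c).sum() for c in classes])
    within = np.zeros(p)
    for c, n_c in zip(classes, nk):
        within += ((X[y == c] - X[y == c].mean(axis=0)) ** 2).sum(axis=0)
    s = np.sqrt(within / (n - K))
    s0 = float(np.median(s))
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    denom = np.maximum(s + s0, 1e-12)  # s0 guards all-constant features
    d = (cent - overall[None, :]) / (mk[:, None] * denom[None, :])
    return ShrunkenCentroidModel(
        feature_ids=[],
        classes=list(classes),
        overall_centroid=overall,
        centroids=cent,
        d_shrunk=soft_threshold(d, delta),
        s=s,
        s0=s0,
        mk=mk,
        priors=priors,
        delta=delta,
    )


def _delta_for_max_features(d_unshrunk: np.ndarray, max_features: int) -> float:
    """Smallest delta keeping at most *max_features* nonzero feature rows."""
    if int((np.abs(d_unshrunk) > 0).any(axis=0).sum()) <= max_features:
        return 0.0
    lo, hi = 0.0, float(np.abs(d_unshrunk).max())
    for _ in range(60):
        mid = (lo + hi) / 2
        k = int((np.abs(soft_threshold(d_unshrunk, mid)) > 0).any(axis=0).sum())
        if k > max_features:
            lo = mid
        else:
            hi = mid
    return hi


def train_nsc(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    delta_grid=None,
    priors: str = "equal",
    inner_folds: int = 5,
    seed: int = 0,
    max_features: int | None = None,
) -> ShrunkenCentroidModel:
    """Fit an NSC model, choosing the shrinkage delta by inner cross-validation.

    *features* is samples x features; *labels* the class per sample. The
    delta grid defaults to 30 evenly spaced values spanning [0, max |d|].
    Equal class priors by default ("empirical" uses class frequencies).
    With *max_features* set, delta is instead raised on these training data
    until at most that many features survive the soft threshold.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = np.array([(y == c).sum() for c in classes])
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 samples")
    pr = (
        np.full(len(classes), 1.0 / len(classes))
        if priors == "equal"
        else counts / counts.sum()
    )
    if max_features is not None:
        probe = _fit_at_delta(X, y, classes, 0.0, pr)
        delta_grid = [_delta_for_max_features(probe.d_shrunk, max_features)]
    elif delta_grid is None:
        probe = _fit_at_delta(X, y, classes, 0.0, pr)
        delta_grid = np.linspace(0.0, np.abs(probe.d_shrunk).max(), 30)
    delta_grid = np.asarray(delta_grid, dtype=float)

    if len(delta_grid) > 1:
        n_splits = min(inner_folds, counts.min())
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        errors = np.zeros(len(delta_grid))
        for tr, te in skf.split(X, y):
            for j, delta in enumerate(delta_grid):
                m = _fit_at_delta(X[tr], y[tr], classes, delta, pr)
                pred = np.asarray(classes, dtype=object)[
                    np.argmin(m.discriminant(X[te]), axis=1)
                ]
                errors[j] += (pred != y[te]).sum()
        # smallest error; among ties prefer the largest delta (fewest features)
        best = len(delta_grid) - 1 - int(np.argmin(errors[::-1]))
        delta = float(delta_grid[best])
    else:
        delta = float(delta_grid[0])

    model = _fit_at_delta(X, y, classes, delta, pr)
    model.feature_ids = list(features.columns)
    return model


@dataclass
class CVReport:
    """Cross-validation outcome for the positive class."""

    scores: pd.Series  # held-out posterior of the positive class per sample
    truth: pd.Series
    fold: pd.Series
    auc_pooled: float
    auc_fold_mean: float
    auc_ci: tuple[float, float]
    n_features_used: int


def cross_validate(
    features: pd.DataFrame,
    labels: pd.Series,
    positive_class,
    n_folds: int = 10,
    seed: int = 0,
    delta_grid=None,
    n_boot: int = 2000,
    max_features: int | None = None,
) -> CVReport:
    """Stratified n-fold CV; pooled trapezoid AUC plus per-fold mean AUC.

    The bootstrap CI resamples the pooled held-out scores (2000 draws).
    """
    X = features
    y = labels.reindex(features.index) if isinstance(labels, pd.Series) else pd.Series(
        np.asarray(labels), index=features.index
    )
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n_folds_eff = min(n_folds, int((y == positive_class).sum()), int((y != positive_class).sum()))
    if n_folds_eff < n_folds:
        logger.warning("reducing folds to %d to keep both classes per fold", n_folds_eff)
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    ybin = (y == positive_class).astype(int)
    scores = pd.Series(index=X.index, dtype=float)
    fold_of = pd.Series(index=X.index, dtype=int)
    fold_aucs = []
    nfeat = []
    for f, (tr, te) in enumerate(skf.split(X, ybin)):
        model = train_nsc(
            X.iloc[tr], y.iloc[tr], delta_grid=delta_grid, seed=seed + f,
            max_features=max_features,
        )
        pos = model.classes.index(positive_class)
        proba = model.predict_proba(X.iloc[te])[:, pos]
        scores.iloc[te] = proba
        fold_of.iloc[te] = f
        nfeat.append(len(model.selected_features))
        if ybin.iloc[te].nunique() == 2:
            fold_aucs.append(roc_auc_score(ybin.iloc[te], proba))
    auc_pooled = float(roc_auc_score(ybin, scores))
    rng = np.random.default_rng(seed)
    boots = []
    yv = ybin.to_numpy()
    sv = scores.to_numpy()
    for _ in range(n_boot):
        idx = rng.integers(0, len(sv), len(sv))
        if yv[idx].min() == yv[idx].max():
            continue
        boots.append(roc_auc_score(yv[idx], sv[idx]))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return CVReport(
        scores=scores,
        truth=ybin,
        fold=fold_of,
        auc_pooled=auc_pooled,
        auc_fold_mean=float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
        auc_ci=ci,
        n_features_used=int(np.median(nfeat)),
    )


def transfer_classify(
    model: ShrunkenCentroidModel,
    features: pd.DataFrame,
    positive_class,
    conf_low: float = CONF_LOW,
    conf_high: float = CONF_HIGH,
) -> pd.DataFrame:
    """Score another cohort over shared features and call with abstention.

    Calls: ``positive`` if p > conf_high, ``other`` if p < conf_low,
    ``abstain`` otherwise (strict inequalities). Model features absent from
    the new cohort are imputed at the overall centroid value.
    """
    shared = [f for f in model.feature_ids if f in features.columns]
    if not shared:
        raise ValueError("zero overlapping features between model and cohort")
    missing = [f for f in model.feature_ids if f not in features.columns]
    X = np.empty((features.shape[0], len(model.feature_ids)))
    for j, f in enumerate(model.feature_ids):
        if f in features.columns:
            X[:, j] = features[f].to_numpy(dtype=float)
        else:
            X[:, j] = model.overall_centroid[j]
    if missing:
        logger.warning(
            "%d/%d model features missing; imputed at overall centroid",
            len(missing),
            len(model.feature_ids),
        )
    pos = model.classes.index(positive_class)
    p = model.predict_proba(X)[:, pos]
    call = np.where(p > conf_high, "positive", np.where(p < conf_low, "other", "abstain"))
    return pd.DataFrame({"p": p, "call": call}, index=features.index)


def minimal_panel(
    features: pd.DataFrame,
    labels: pd.Series,
    positive_class,
    n_features: int,
    n_folds: int = 10,
    seed: int = 0,
):
    """Raise the shrinkage until at most *n_features* survive; report CV AUC.

    Returns ``(model, report, stability)`` where *stability* is, per selected
    feature, the fraction of CV folds whose refit model reused it.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    X = features
    y = labels
    model = train_nsc(X, y, max_features=n_features)
    # the cap is re-applied inside every training fold: shrinkage strong
    # enough to keep n features on the full cohort can zero them all on a
    # smaller fold, so each fold finds its own delta for the same panel size
    report = cross_validate(
        X, y, positive_class, n_folds=n_folds, seed=seed, max_features=n_features
    )
    sel = model.selected_features
    skf = StratifiedKFold(
        n_splits=min(n_folds, int((y == positive_class).sum())),
        shuffle=True,
        random_state=seed,
    )
    use = {f: 0 for f in sel}
    folds = 0
    for tr, _ in skf.split(X, (y == positive_class).astype(int)):
        m = train_nsc(X.iloc[tr], y.iloc[tr], max_features=n_features)
        folds += 1
        for f in m.selected_features:
            if f in use:
                use[f] += 1
    stability = pd.Series({f: use[f] / folds for f in sel}, name="fold_fraction")
    return model, report, stability
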