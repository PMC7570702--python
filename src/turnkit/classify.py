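"""PLS-DA two-group classification with VIP feature ranking.

Partial least squares regression on a dummy-coded class label (PD = +1,
control = -1) used as a discriminant classifier; prediction is the sign of
the regression output (ties at exactly 0 go to control). The number of
components is selected by the cumulated Q^2 index computed with
leave-one-out cross-validation: keep adding components while Q^2 increases
and stays positive.  Feature influence is ranked by the variable importance
in projection (VIP):

    VIP_j = sqrt( p * sum_k [ SSY_k * w_jk^2 ] / sum_k SSY_k )

with w_k the unit-norm X-weights and SSY_k the Y-variance explained by
component k; the mean squared VIP over features is identically 1.
Features are standardized inside every training fold only (no leakage);
remaining NaNs are mean-imputed per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "PlsdaModel",
    "ClassificationReport",
    "fit_plsda",
    "vip_scores",
    "evaluate_loo",
]


@dataclass
class PlsdaModel:
    n_components: int
    feature_ids: List[str]
    x_weights: np.ndarray   # (p, k), unit-norm columns
    x_loadings: np.ndarray  # (p, k)
    y_loadings: np.ndarray  # (k,)
    scores: np.ndarray      # (n, k)
    r2x_cum: np.ndarray     # per-component cumulated fractions
    r2y_cum: np.ndarray
    q2_cum: np.ndarray      # Q^2 at each component count 1..k_max evaluated
    vip: Dict[str, float] = field(default_factory=dict)
    class_threshold: float = 0.0
    flagged: bool = False   # True when no component had Q^2 > 0
    # prediction machinery
    x_mean: np.ndarray = None
    x_std: np.ndarray = None
    coef: np.ndarray = None  # (p,) on standardized X
    y_mean: float = 0.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        Xs = (X - self.x_mean) / self.x_std
        Xs = np.where(np.isnan(Xs), 0.0, Xs)  # imputed at the training mean
        return Xs @ self.coef + self.y_mean

    def predict(self, X) -> np.ndarray:
        """+1 (PD) where the decision value exceeds the threshold, else -1."""
        d = self.decision_function(np.asarray(X, float))
        return np.where(d > self.class_threshold, 1, -1)


@dataclass
class ClassificationReport:
    tp: int
    fn: int
    tn: int
    fp: int
    predictions: List[int] = field(default_factory=list)
    subject_ids: List[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else float("nan")

    def as_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "n": self.n,
        }


def encode_labels(y: Sequence) -> np.ndarray:
    """Dummy-code labels: PD (positive class) -> +1, control -> -1."""
    out = []
    for v in y:
        if isinstance(v, str):
            out.append(1 if v.upper() == "PD" else -1)
        else:
            out.append(1 if v > 0 else -1)
    return np.asarray(out, int)


def _clean_matrix(X: np.ndarray, feature_ids: List[str]
                  ) -> Tuple[np.ndarray, List[str]]:
    """Drop all-NaN and constant columns (with warning)."""
    keep = []
    for j in range(X.shape[1]):
        col = X[:, j]
        finite = col[np.isfinite(col)]
        if finite.size == 0 or np.nanstd(col) == 0:
            continue
        keep.append(j)
    dropped = X.shape[1] - len(keep)
    if dropped:
        warnings.warn(f"dropped {dropped} constant/all-NaN feature columns")
    return X[:, keep], [feature_ids[j] for j in keep]


def _standardize(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    return np.where(np.isnan(Xs), 0.0, Xs), mu, sd


def _truncated_coefs(pls: PLSRegression, k: int) -> np.ndarray:
    """Regression coefficients of the first-k-component sub-model.

    Valid because P'W is upper triangular in NIPALS, so truncating the
    rotations of the full fit reproduces the k-component fit.
    """
    R = pls.x_rotations_[:, :k]
    Q = pls.y_loadings_[:, :k]
    return (R @ Q.T).ravel()


def _press_by_component(X: np.ndarray, y: np.ndarray, k_max: int) -> np.ndarray:
    """LOO PRESS for each component count 1..k_max (per-fold standardization)."""
    n = X.shape[0]
    press = np.zeros(k_max)
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        Xs, mu, sd = _standardize(X[tr])
        k_fit = min(k_max, Xs.shape[0] - 1, Xs.shape[1])
        pls = PLSRegression(n_components=k_fit, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(Xs, y[tr].astype(float))
        xi = (X[i] - mu) / sd
        xi = np.where(np.isnan(xi), 0.0, xi) - pls._x_mean
        y_mean = float(np.ravel(pls._y_mean)[0])
        for k in range(1, k_max + 1):
            yhat = float(xi @ _truncated_coefs(pls, min(k, k_fit))) + y_mean
            press[k - 1] += (y[i] - yhat) ** 2
    return press


def select_n_components(X: np.ndarray, y: np.ndarray, max_components: int
                        ) -> Tuple[int, np.ndarray, bool]:
    """Largest k with Q^2 increasing and Q^2(k) > 0; flagged if none positive."""
    k_max = int(min(max_components, X.shape[0] - 2, X.shape[1]))
    k_max = max(k_max, 1)
    press = _press_by_component(X, y, k_max)
    ss = np.sum((y - y.mean()) ** 2)
    q2 = 1.0 - press / ss
    if q2[0] <= 0:
        return 1, q2, True
    k = 1
    while k < k_max and q2[k] > q2[k - 1] and q2[k] > 0:
        k += 1
    return k, q2, False


def fit_plsda(X, y, max_components: int = 10,
              feature_ids: Optional[List[str]] = None,
              n_components: Optional[int] = None) -> PlsdaModel:
    """Fit a PLS-DA model on a subjects-by-features matrix.

    ``X`` may be a DataFrame (column names become feature ids) or array;
    ``y`` any PD/control labelling accepted by :func:`encode_labels`.
    With ``n_components=None`` the count is chosen by the cumulated-Q^2
    rule; a fixed count skips that selection.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    yv = encode_labels(y).astype(float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    if len(np.unique(yv)) < 2:
        raise ValueError("y must contain both classes")

    X, feature_ids = _clean_matrix(X, feature_ids)
    flagged = False
    if n_components is None:
        n_components, q2, flagged = select_n_components(X, yv, max_components)
    else:
        k_max = int(max(min(n_components, X.shape[0] - 2, X.shape[1]), 1))
        n_components = k_max
        q2 = np.array([])  # not computed for a fixed component count

    Xs, mu, sd = _standardize(X)
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xs, yv)

    T = pls.x_scores_
    P = pls.x_loadings_
    W = pls.x_weights_
    q = pls.y_loadings_.ravel()
    ssx_total = np.sum((Xs - Xs.mean(axis=0)) ** 2)
    ssy_total = np.sum((yv - yv.mean()) ** 2)
    t_ss = np.sum(T**2, axis=0)
    r2x = np.cumsum(t_ss * np.sum(P**2, axis=0)) / ssx_total
    ssy_k = t_ss * q**2
    r2y = np.cumsum(ssy_k) / ssy_total

    model = PlsdaModel(
        n_components=n_components,
        feature_ids=feature_ids,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        r2x_cum=r2x,
        r2y_cum=r2y,
        q2_cum=np.asarray(q2),
        flagged=flagged,
        x_mean=mu,
        x_std=sd,
        coef=_truncated_coefs(pls, n_components),
        y_mean=float(np.ravel(pls._y_mean)[0]),
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PlsdaModel, per_component: bool = False):
    """Standard VIP per feature; with ``per_component=True`` also the
    per-component VIP profiles (p, k) used for 'VIP > 1.5 in any component'
    style screening."""
    W = model.x_weights
    T = model.scores
    q = model.y_loadings
    p, k = W.shape
    ssy = np.sum(T**2, axis=0) * q**2
    wnorm2 = W**2 / np.sum(W**2, axis=0)
    vip = np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())
    scores = dict(zip(model.feature_ids, vip))
    if per_component:
        cum = np.cumsum(ssy)
        per_comp = np.sqrt(p * np.cumsum(wnorm2 * ssy, axis=1) / cum)
        return scores, per_comp
    return scores


def evaluate_loo(X, y, n_components: Optional[int] = None,
                 max_components: int = 10,
                 subject_ids: Optional[List[str]] = None) -> ClassificationReport:
    """Leave-one-out evaluation: refit on n-1, predict the held-out subject.

    Standardization, NaN imputation and (if ``n_components`` is None)
    component selection all happen inside each training fold.
    """
    if isinstance(X, pd.DataFrame):
        subject_ids = subject_ids or [str(i) for i in X.index]
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    yv = encode_labels(y)
    n = X.shape[0]
    subject_ids = subject_ids or [str(i) for i in range(n)]
    preds = np.zeros(n, int)
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        if len(np.unique(yv[tr])) < 2:
            raise ValueError("LOO training fold with a single class")
        model = fit_plsda(X[tr], yv[tr], max_components=max_components,
                          n_components=n_components)
        # fold feature ids are generated f{j} names over the original columns;
        # select the surviving columns of the held-out row accordingly
        cols = [int(fid[1:]) for fid in model.feature_ids]
        preds[i] = model.predict(X[i, cols][None, :])[0]
    tp = int(np.sum((preds == 1) & (yv == 1)))
    fn = int(np.sum((preds == -1) & (yv == 1)))
    tn = int(np.sum((preds == -1) & (yv == -1)))
    fp = int(np.sum((preds == 1) & (yv == -1)))
    return ClassificationReport(tp=tp, fn=fn, tn=tn, fp=fp,
                                predictions=list(preds), subject_ids=subject_ids)
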