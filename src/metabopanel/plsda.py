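"""Partial least squares discriminant analysis (PLS-DA).

A NIPALS PLS2 implementation on a one-hot (or, for two classes, single
0/1 column) response, with:

* VIP scores — VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )
  where SS_a is the Y-variance explained by component a; mean(VIP^2) = 1;
* stratified k-fold cross-validated R²Y and Q² = 1 - PRESS/TSS, with the
  preprocessing chain refrozen inside each training fold when the raw
  concentration table is supplied;
* a label-permutation test of class separation with the standard
  add-one p-value (1 + #{perm >= observed}) / (1 + n_perm).

NIPALS iterates, per component: w = X'u (normalized), t = Xw,
q = Y't/(t't), u = Yq/(q'q) until t converges; X and Y are deflated by the
rank-one component contribution before the next component is extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .preprocess import MetaboliteTable, PreprocessPipeline, ProcessedMatrix


class PLSDAError(ValueError):
    pass


@dataclass
class PLSDAResult:
    n_components: int
    classes: list[str]
    x_scores: np.ndarray       # T, n × A
    x_weights: np.ndarray      # W (unit columns), p × A
    x_loadings: np.ndarray     # P, p × A
    y_loadings: np.ndarray     # Q, A × K
    x_mean: np.ndarray
    y_mean: np.ndarray
    ss_y: np.ndarray           # explained Y-variance per component
    vip: np.ndarray
    feature_ids: list[str]
    r2y: np.ndarray            # cumulative, per component count
    q2: np.ndarray | None = None
    permutation_p: float | None = None

    def _regression_coef(self, a: int | None = None) -> np.ndarray:
        a = self.n_components if a is None else a
        W, P, Q = self.x_weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, Q)

    def predict_y(self, x: np.ndarray | pd.DataFrame, n_components: int | None = None) -> np.ndarray:
        """Continuous predicted (one-hot) responses for new samples."""
        xa = np.asarray(x, dtype=float) - self.x_mean
        return xa @ self._regression_coef(n_components) + self.y_mean

    def predict_class(self, x) -> np.ndarray:
        yhat = self.predict_y(x)
        if yhat.shape[1] == 1:  # binary: threshold the single column
            idx = (yhat[:, 0] >= 0.5).astype(int)
        else:
            idx = yhat.argmax(axis=1)
        return np.asarray(self.classes)[idx]


def _encode_labels(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    classes = sorted(pd.Series(labels).unique())
    if len(classes) < 2:
        raise PLSDAError("need >= 2 classes")
    if len(classes) == 2:
        y = (pd.Series(labels) == classes[1]).to_numpy(dtype=float)[:, None]
    else:
        y = np.stack([(pd.Series(labels) == c).to_numpy(dtype=float) for c in classes], axis=1)
    return y, [str(c) for c in classes]


def fit_plsda(matrix, labels: pd.Series, n_components: int = 2,
              max_iter: int = 500, tol: float = 1e-10) -> PLSDAResult:
    """Fit a PLS-DA model on a processed matrix (deterministic NIPALS)."""
    x = matrix.values if isinstance(matrix, ProcessedMatrix) else pd.DataFrame(matrix)
    labels = pd.Series(labels).reindex(x.index) if isinstance(labels, pd.Series) else pd.Series(labels, index=x.index)
    n, p = x.shape
    if n_components >= min(n, p) + 1:
        raise PLSDAError("n_components must be < min(n_samples, n_metabolites) + 1")
    X = x.to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise PLSDAError("X is constant; nothing to fit")
    Y, classes = _encode_labels(labels)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    ss_y_total = float((Yc**2).sum())

    A = n_components
    K = Yc.shape[1]
    T = np.zeros((n, A)); W = np.zeros((p, A)); P = np.zeros((p, A)); Q = np.zeros((A, K))
    ss_y = np.zeros(A)
    r2y = np.zeros(A)
    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(A):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        t = np.zeros(n)
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise PLSDAError(f"degenerate deflated X at component {a + 1}")
            w /= nw
            t_new = Xd @ w
            q = Yd.T @ t_new / (t_new @ t_new)
            if K == 1:
                t, w_final, q_final = t_new, w, q
                break
            u = Yd @ q / (q @ q)
            if np.linalg.norm(t_new - t) < tol * max(1.0, np.linalg.norm(t_new)):
                t, w_final, q_final = t_new, w, q
                break
            t = t_new
        else:
            w_final, q_final = w, q
        tt = float(t @ t)
        p_load = Xd.T @ t / tt
        T[:, a], W[:, a], P[:, a], Q[a] = t, w_final, p_load, q_final
        ss_y[a] = tt * float(q_final @ q_final)
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, q_final)
        r2y[a] = 1.0 - float((Yd**2).sum()) / ss_y_total

    model = PLSDAResult(
        n_components=A, classes=classes, x_scores=T, x_weights=W,
        x_loadings=P, y_loadings=Q, x_mean=x_mean, y_mean=y_mean,
        ss_y=ss_y, vip=np.zeros(p), feature_ids=list(x.columns), r2y=r2y,
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PLSDAResult) -> np.ndarray:
    """Variable importance in projection; mean of VIP² over features is 1."""
    W = model.x_weights
    p = W.shape[0]
    ss = model.ss_y
    wnorm2 = (W**2) / np.maximum((W**2).sum(axis=0, keepdims=True), 1e-300)
    return np.sqrt(p * (wnorm2 @ ss) / ss.sum())


@dataclass
class CVResult:
    """Cumulative R²Y (full fit) and Q² (cross-validated) per component count."""

    r2y: np.ndarray
    q2: np.ndarray
    components: np.ndarray = field(default_factory=lambda: np.array([]))

    def best_n_components(self) -> int:
        return int(self.components[int(np.argmax(self.q2))])


def _folds(labels: pd.Series, folds: int, seed: int | None):
    y = pd.Series(labels)
    n = len(y)
    if folds >= n:
        return list(LeaveOneOut().split(np.zeros(n)))
    skf = StratifiedKFold(n_splits=folds, shuffle=seed is not None, random_state=seed)
    return list(skf.split(np.zeros(n), y.to_numpy()))


def cross_validate(data, labels: pd.Series, max_components: int = 5,
                   folds: int = 10, seed: int | None = 0,
                   max_missing_frac: float = 0.20) -> CVResult:
    """Stratified k-fold R²Y/Q² for component counts 1..max_components.

    If ``data`` is a raw MetaboliteTable the preprocessing chain is fitted
    inside each training fold and frozen onto the held-out fold; a
    ProcessedMatrix is used as-is (suitable for toy inputs).
    """
    raw = isinstance(data, MetaboliteTable)
    frame = data.values
    labels = pd.Series(labels).reindex(frame.index)
    y_full, _ = _encode_labels(labels)
    n = len(frame)
    A = min(max_components, n - 2, frame.shape[1])
    press = np.zeros(A)
    tss = 0.0
    for train, test in _folds(labels, folds, seed):
        tr_ids, te_ids = frame.index[train], frame.index[test]
        if raw:
            pipe = PreprocessPipeline(max_missing_frac=max_missing_frac)
            sub = MetaboliteTable(
                data.values.loc[tr_ids], data.lod, data.creatinine.loc[tr_ids]
            )
            x_tr = pipe.fit_transform(sub)
            te_tab = MetaboliteTable(
                data.values.loc[te_ids], data.lod, data.creatinine.loc[te_ids]
            )
            x_te = pipe.transform(te_tab).values
        else:
            x_tr = ProcessedMatrix(frame.loc[tr_ids], ["pareto_scale"])
            x_te = frame.loc[te_ids]
        a_fold = min(A, len(tr_ids) - 1, x_tr.values.shape[1])
        model = fit_plsda(x_tr.values, labels.loc[tr_ids], n_components=a_fold)
        y_te = y_full[test]
        for a in range(A):
            yhat = model.predict_y(x_te, n_components=min(a + 1, a_fold))
            press[a] += float(((y_te - yhat) ** 2).sum())
        tss += float(((y_te - y_full[train].mean(axis=0)) ** 2).sum())
    full = fit_plsda(
        PreprocessPipeline(max_missing_frac=max_missing_frac).fit_transform(data)
        if raw else data,
        labels, n_components=A,
    )
    return CVResult(r2y=full.r2y, q2=1.0 - press / tss,
                    components=np.arange(1, A + 1))


def choose_components(data, labels, max_components: int = 5, folds: int = 10,
                      seed: int | None = 0) -> int:
    """Component count maximizing cross-validated Q², capped at 5."""
    return cross_validate(data, labels, max_components, folds, seed).best_n_components()


def permutation_test(data, labels: pd.Series, n_perm: int = 2000,
                     n_components: int | None = None, folds: int = 10,
                     statistic: str = "q2", seed: int = 0) -> float:
    """Permutation test of class separation.

    The observed statistic (cross-validated Q² by default, training R²Y via
    ``statistic='r2y'``) is compared with its distribution under ``n_perm``
    random relabelings; p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise PLSDAError("n_perm must be >= 1")
    labels = pd.Series(labels).reindex(data.values.index)

    def stat(lab: pd.Series) -> float:
        if statistic == "q2":
            cv = cross_validate(data, lab, max_components=n_components or 5,
                                folds=folds, seed=seed)
            return float(np.max(cv.q2))
        if statistic == "r2y":
            a = n_components or 2
            return float(fit_plsda(data, lab, n_components=a).r2y[-1])
        raise PLSDAError(f"unknown permutation statistic {statistic!r}")

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    values = labels.to_numpy()
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(values), index=labels.index)
        if stat(perm) >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)
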