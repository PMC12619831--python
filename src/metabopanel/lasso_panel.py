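"""Strategy 1 — LASSO-selected logistic biomarker panels.

Workflow: L1-penalized logistic regression over a regularization path with
the penalty chosen by stratified 10-fold cross-validated deviance; the
surviving metabolites are refit by (near-)unpenalized logistic regression
with bidirectional stepwise AIC optimization; the resulting panel is
evaluated by pooled out-of-fold 10-fold CV ROC and by balanced-subsampling
Monte-Carlo cross-validation (MCCV) with percentile 95% confidence
intervals. Fixed-coefficient published panels can be evaluated as-is, and
two ROC curves on the same samples can be compared by a paired permutation
test on the AUC difference.

Penalty convention: ``lambda`` follows the glmnet-style objective
(1/n) * deviance + lambda * ||w||_1, mapped onto scikit-learn's liblinear
solver via C = 1 / (n * lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from scipy.special import expit
from sklearn.metrics import log_loss, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .preprocess import FrozenParams, MetaboliteTable, PreprocessPipeline

_UNPENALIZED_C = 1e10
_RIDGE_FALLBACK_C = 1e6  # ridge-stabilized refit (lambda = 1e-6)


class PanelError(ValueError):
    pass


@dataclass
class PanelModel:
    """An ordered feature panel with logistic coefficients and, when fitted
    through the pipeline, the frozen preprocessing record."""

    feature_ids: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    preprocessing: FrozenParams | None = None
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_ids):
            raise PanelError("coefficient count must match feature count")

    def decision(self, x) -> np.ndarray:
        xm = _design(x, self.feature_ids)
        return self.intercept + xm @ self.coefficients

    def predict_proba(self, x) -> np.ndarray:
        return expit(self.decision(x))


#: fixed-coefficient logistic panels published for the DM-2 vs DN contrast
#: (inputs are creatinine-normalized, log-transformed, Pareto-scaled values;
#: GFR standardized). Included so pre-specified panels can be scored as-is.
MODEL_1 = PanelModel(
    ("beta_alanine", "glucose", "kynurenine", "GFR"),
    -0.975, np.array([-6.644, -6.875, -8.125, -5.609]),
    training_meta={"source": "published fixed-coefficient panel"},
)
MODEL_2 = PanelModel(
    ("beta_alanine", "argininic_acid", "kynurenine"),
    -0.066, np.array([-6.157, 3.052, -0.959]),
    training_meta={"source": "published fixed-coefficient panel"},
)


@dataclass
class RocSummary:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    scheme: str
    per_split_auc: np.ndarray | None = None


@dataclass
class LassoSelection:
    feature_ids: list[str]          # nonzero features ranked by |coefficient|
    coefficients: np.ndarray        # penalized coefficients, same order
    lambda_: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray


def _design(x, feature_ids) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        missing = [f for f in feature_ids if f not in x.columns]
        if missing:
            raise PanelError(f"input lacks panel features: {missing}")
        return x[list(feature_ids)].to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def _binary(labels: pd.Series, positive: str | None = None) -> np.ndarray:
    s = pd.Series(labels)
    classes = sorted(s.unique())
    if len(classes) != 2:
        raise PanelError(f"binary labels required, got {classes}")
    pos = positive if positive is not None else classes[1]
    return (s == pos).to_numpy(dtype=float)


def lasso_select(x: pd.DataFrame, labels, lambda_grid=None, folds: int = 10,
                 seed: int = 0, rule: str = "min") -> LassoSelection:
    """L1-logistic path with lambda chosen by stratified k-fold CV deviance.

    ``rule='min'`` picks the deviance-minimizing lambda; ``rule='1se'`` the
    sparsest lambda within one standard error of the minimum.
    """
    y = _binary(labels)
    X = x.to_numpy(dtype=float)
    n = len(y)
    if lambda_grid is None:
        lam_max = float(np.abs(X.T @ (y - y.mean())).max()) / n
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-3, 30)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    order = np.argsort(-lambda_grid)  # strong to weak: warm starts help
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(lambda_grid)))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        path = LogisticRegression(l1_ratio=1.0, solver="saga", C=1.0,
                                  max_iter=2000, tol=1e-3, random_state=0,
                                  warm_start=True)
        for i in order:
            path.C = 1.0 / max(len(tr) * lambda_grid[i], 1e-12)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                path.fit(X[tr], y[tr])
            p = path.predict_proba(X[te])[:, 1]
            dev[f, i] = 2 * log_loss(y[te], p, labels=[0.0, 1.0], normalize=False)
    mean_dev = dev.mean(axis=0)
    i_min = int(np.argmin(mean_dev))
    if rule == "1se":
        se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
        ok = np.where(mean_dev <= mean_dev[i_min] + se[i_min])[0]
        i_sel = int(ok[np.argmax(lambda_grid[ok])])  # sparsest within 1 SE
    elif rule == "min":
        i_sel = i_min
    else:
        raise PanelError(f"unknown rule {rule!r}")
    lam = float(lambda_grid[i_sel])
    clf = _l1_fit(X, y, lam)
    coef = clf.coef_.ravel()
    order = np.argsort(-np.abs(coef), kind="stable")
    nonzero = [i for i in order if coef[i] != 0.0]
    return LassoSelection(
        feature_ids=[x.columns[i] for i in nonzero],
        coefficients=coef[nonzero],
        lambda_=lam, lambda_grid=lambda_grid, cv_deviance=mean_dev,
    )


def _l1_fit(X, y, lam, tol: float = 1e-8) -> LogisticRegression:
    # saga rather than liblinear: identical objective to the elastic-net
    # module (liblinear additionally penalizes the intercept)
    C = 1.0 / max(len(y) * lam, 1e-12)
    clf = LogisticRegression(l1_ratio=1.0, solver="saga", C=C,
                             max_iter=5000, tol=tol, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def _logistic_refit(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, float, bool]:
    """Near-unpenalized logistic fit; falls back to a ridge-stabilized fit
    under (quasi-)separation. Returns (intercept, coef, aic, fallback)."""
    fallback = False
    clf = LogisticRegression(l1_ratio=0.0, C=_UNPENALIZED_C, solver="lbfgs",
                             max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    coef = clf.coef_.ravel()
    if clf.n_iter_[0] >= 5000 or np.abs(coef).max(initial=0.0) > 1e3:
        warnings.warn("quasi-separation detected; ridge-stabilized refit",
                      RuntimeWarning, stacklevel=2)
        fallback = True
        clf = LogisticRegression(l1_ratio=0.0, C=_RIDGE_FALLBACK_C,
                                 solver="lbfgs", max_iter=5000)
        clf.fit(X, y)
        coef = clf.coef_.ravel()
    p = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    k = X.shape[1] + 1
    return float(clf.intercept_[0]), coef, 2 * k - 2 * loglik, fallback


def stepwise_refit(x: pd.DataFrame, labels, candidates, positive: str | None = None
                   ) -> PanelModel:
    """Bidirectional stepwise AIC selection over ``candidates`` on an
    unpenalized logistic refit; lexicographic tie-break for determinism."""
    candidates = list(candidates)
    if not candidates:
        raise PanelError("need >= 1 candidate feature")
    y = _binary(labels, positive)

    def aic_of(feats: tuple[str, ...]) -> float:
        if not feats:
            prev = np.clip(y.mean(), 1e-12, 1 - 1e-12)
            ll = float(np.sum(y * np.log(prev) + (1 - y) * np.log(1 - prev)))
            return 2 * 1 - 2 * ll
        X = _design(x, feats)
        return _logistic_refit(X, y)[2]

    current: tuple[str, ...] = ()
    current_aic = aic_of(current)
    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, str, tuple[str, ...]]] = []
        for f in sorted(set(candidates) - set(current)):
            moves.append((aic_of(current + (f,)), f, current + (f,)))
        for f in sorted(current):
            trial = tuple(g for g in current if g != f)
            moves.append((aic_of(trial), f, trial))
        if moves:
            moves.sort(key=lambda m: (m[0], m[1]))
            best_aic, _, best_set = moves[0]
            if best_aic < current_aic - 1e-9:
                current, current_aic = best_set, best_aic
                improved = True
    if not current:
        return PanelModel((), float(np.log(y.mean() / (1 - y.mean()))), np.array([]),
                          training_meta={"aic": current_aic, "stepwise": "intercept-only"})
    X = _design(x, current)
    intercept, coef, aic, fb = _logistic_refit(X, y)
    return PanelModel(tuple(current), intercept, coef,
                      training_meta={"aic": aic, "ridge_fallback": fb})


def _bootstrap_auc_ci(probs, y, n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = []
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) == 2:
                break
        aucs.append(roc_auc_score(y[idx], probs[idx]))
    return tuple(np.percentile(aucs, [2.5, 97.5]))


def _prepare_fold_data(data, tr_ids, te_ids, features, covariate,
                       max_missing_frac=0.20):
    """Per-fold design matrices with preprocessing and covariate scaling
    learned on the training partition only."""
    if isinstance(data, MetaboliteTable):
        pipe = PreprocessPipeline(max_missing_frac=max_missing_frac)
        x_tr = pipe.fit_transform(MetaboliteTable(
            data.values.loc[tr_ids], data.lod, data.creatinine.loc[tr_ids]))
        x_te = pipe.transform(MetaboliteTable(
            data.values.loc[te_ids], data.lod, data.creatinine.loc[te_ids]))
        tr, te = x_tr.values, x_te.values
    else:
        frame = data.values if hasattr(data, "values") and not isinstance(data, pd.DataFrame) else data
        tr, te = frame.loc[tr_ids].copy(), frame.loc[te_ids].copy()
    if covariate is not None:
        mu = float(covariate.loc[tr_ids].mean())
        sd = float(covariate.loc[tr_ids].std(ddof=1)) or 1.0
        name = covariate.name or "covariate"
        tr[name] = (covariate.loc[tr_ids] - mu) / sd
        te[name] = (covariate.loc[te_ids] - mu) / sd
    feats = [f for f in features if f in tr.columns] if features is not None else list(tr.columns)
    return tr[feats], te[feats]


def kfold_cv_auc(data, labels: pd.Series, features=None, folds: int = 10,
                 seed: int = 0, covariate: pd.Series | None = None,
                 positive: str | None = None, folds_spec=None,
                 n_boot: int = 2000) -> RocSummary:
    """Pooled out-of-fold ROC under stratified k-fold CV with per-fold
    preprocessing refits (no leakage); percentile-bootstrap 95% CI."""
    ids = data.values.index if not isinstance(data, pd.DataFrame) else data.index
    labels = pd.Series(labels).reindex(ids)
    y = _binary(labels, positive)
    if folds_spec is None:
        if folds >= len(y):
            folds_spec = [(np.delete(np.arange(len(y)), i), np.array([i]))
                          for i in range(len(y))]
        else:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            folds_spec = list(skf.split(np.zeros(len(y)), y))
    probs = np.full(len(y), np.nan)
    for tr, te in folds_spec:
        tr_ids, te_ids = ids[tr], ids[te]
        Xtr, Xte = _prepare_fold_data(data, tr_ids, te_ids, features, covariate)
        intercept, coef, _, _ = _logistic_refit(Xtr.to_numpy(dtype=float), y[tr])
        probs[te] = expit(intercept + Xte.to_numpy(dtype=float) @ coef)
    fpr, tpr, _ = roc_curve(y, probs)
    auc = float(roc_auc_score(y, probs))
    lo, hi = _bootstrap_auc_ci(probs, y, n_boot=n_boot, seed=seed)
    return RocSummary(auc, float(lo), float(hi), fpr, tpr, "kfold_cv")


def mccv_roc(data, labels: pd.Series, features=None, n_splits: int = 500,
             train_frac: float = 2 / 3, seed: int = 0,
             covariate: pd.Series | None = None,
             positive: str | None = None) -> RocSummary:
    """Balanced-subsampling Monte-Carlo CV ROC.

    Each split draws an equal per-class training subsample of size
    floor(train_frac * min class n) per class, tests on the remainder, and
    the split AUC distribution is summarized by its mean and percentile
    95% CI. The reported curve is the vertical average over splits.
    """
    if n_splits < 1:
        raise PanelError("n_splits must be >= 1")
    ids = data.values.index if not isinstance(data, pd.DataFrame) else data.index
    labels = pd.Series(labels).reindex(ids)
    y = _binary(labels, positive)
    rng = np.random.default_rng(seed)
    idx0, idx1 = np.where(y == 0)[0], np.where(y == 1)[0]
    n_train = int(np.floor(train_frac * min(len(idx0), len(idx1))))
    if n_train < 1 or n_train >= min(len(idx0), len(idx1)):
        raise PanelError("train_frac leaves no training or no test samples")
    grid = np.linspace(0, 1, 101)
    tprs, aucs = [], []
    for _ in range(n_splits):
        tr = np.concatenate([rng.choice(idx0, n_train, replace=False),
                             rng.choice(idx1, n_train, replace=False)])
        te = np.setdiff1d(np.arange(len(y)), tr)
        Xtr, Xte = _prepare_fold_data(data, ids[tr], ids[te], features, covariate)
        intercept, coef, _, _ = _logistic_refit(Xtr.to_numpy(dtype=float), y[tr])
        p = expit(intercept + Xte.to_numpy(dtype=float) @ coef)
        fpr, tpr, _ = roc_curve(y[te], p)
        aucs.append(roc_auc_score(y[te], p))
        tprs.append(np.interp(grid, fpr, tpr))
    aucs = np.asarray(aucs)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return RocSummary(float(aucs.mean()), float(lo), float(hi), grid, mean_tpr,
                      "mccv", per_split_auc=aucs)


def evaluate_published_model(model: PanelModel, x) -> np.ndarray:
    """Per-sample probability from a fixed-coefficient panel; inputs must
    already be in the model's frozen scaled space."""
    return model.predict_proba(x)


def compare_rocs(scores_a, scores_b, labels, n_perm: int = 2000,
                 seed: int = 0, positive: str | None = None) -> float:
    """Paired permutation test on |AUC(a) - AUC(b)| over the same samples:
    each permutation swaps the two models' scores sample-wise."""
    y = _binary(labels, positive) if not isinstance(labels, np.ndarray) else labels.astype(float)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or len(a) != len(y):
        raise PanelError("score vectors must align with labels")
    observed = abs(roc_auc_score(y, a) - roc_auc_score(y, b))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(len(y)) < 0.5
        aa = np.where(swap, b, a)
        bb = np.where(swap, a, b)
        if abs(roc_auc_score(y, aa) - roc_auc_score(y, bb)) >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


@dataclass
class LassoPanelReport:
    selection: LassoSelection
    panel: PanelModel
    cv_roc: RocSummary
    mccv: RocSummary


def build_lasso_panel(table: MetaboliteTable, labels: pd.Series,
                      exclude=(), folds: int = 10, seed: int = 0,
                      n_mccv: int = 500, positive: str | None = None,
                      max_missing_frac: float = 0.20) -> LassoPanelReport:
    """End-to-end strategy 1 on a two-group concentration table.

    ``exclude`` removes named metabolites from candidacy (e.g. glucose when
    antidiabetic treatment confounds it).
    """
    pipe = PreprocessPipeline(max_missing_frac=max_missing_frac)
    x = pipe.fit_transform(table).values.drop(columns=list(exclude), errors="ignore")
    sel = lasso_select(x, labels, folds=folds, seed=seed)
    candidates = sel.feature_ids or list(
        x.columns[np.argsort(-np.abs(x.corrwith(pd.Series(_binary(labels, positive), index=x.index))))[:3]]
    )
    panel = stepwise_refit(x, labels, candidates, positive=positive)
    feats = list(panel.feature_ids) or candidates[:1]
    cv = kfold_cv_auc(table, labels, features=feats, folds=folds, seed=seed,
                      positive=positive)
    mc = mccv_roc(table, labels, features=feats, n_splits=n_mccv, seed=seed,
                  positive=positive)
    panel.preprocessing = pipe.frozen_
    panel.training_meta.update({"cv_scheme": f"{folds}-fold", "seed": seed})
    return LassoPanelReport(sel, panel, cv, mc)
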