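"""Strategy 2 — genetic-algorithm wrapper feature selection with
elastic-net logistic fitness, nested cross-validation, stability selection
and bootstrap performance estimation.

Candidate panels are binary masks over the metabolite set. Fitness is the
mean held-out Matthews correlation coefficient (MCC) of an elastic-net
logistic model (l1_ratio 0.5, saga solver) fitted on the masked features,
penalized for complexity beyond ``max_features``:

    fitness = mean_CV_MCC - penalty_weight * max(0, k - max_features)

The GA uses tournament selection, two-point crossover, adaptive bit-flip
mutation (each child is mutated with a probability that decays linearly
across generations from 0.25 to 0.05; a mutated child flips each bit with
probability 1/n_features), and elitism (so the best-so-far fitness is
nondecreasing). The nested-CV scheme runs one GA per
inner fold of each outer fold, retains features selected in at least half of
the inner folds, refits the elastic net on the outer-training split with the
retained features (preprocessing frozen on that split when raw tables are
used upstream), and pools the out-of-fold probabilities. Metric uncertainty
is estimated by nonparametric bootstrap (percentile 95% CIs) over the
(probability, label) pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._en_prox import en_logistic_prox
from ._en_prox import predict_proba as prox_predict
from .lasso_panel import PanelModel, _binary


class GAError(ValueError):
    pass


@dataclass(frozen=True)
class GAConfig:
    """GA and elastic-net hyperparameters.

    The full-scale profile (`paper_config`) evolves 3000 individuals for up
    to 60 generations; the reduced profile (pop 100, gen 20) is the
    desk-scale default for tests and smoke runs.
    """

    population_size: int = 3000
    max_generations: int = 60
    crossover_prob: float = 0.8
    mutation_prob_start: float = 0.25   # per-child mutation probability at gen 0
    mutation_prob_end: float = 0.05     # ... decayed linearly by the last gen
    tournament_size: int = 4
    elite_count: int = 3
    max_features: int = 8
    penalty_weight: float = 0.05
    l1_ratio: float = 0.5
    en_strength: float = 1.0
    init_active_prob: float | None = None
    plateau_generations: int = 10
    plateau_tol: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise GAError("population_size must be >= 2")
        if self.elite_count >= self.population_size:
            raise GAError("elite_count must be < population_size")
        if not 0 <= self.crossover_prob <= 1:
            raise GAError("crossover_prob must be in [0, 1]")
        if not (0 <= self.mutation_prob_end <= self.mutation_prob_start <= 1):
            raise GAError("need 0 <= mutation_prob_end <= mutation_prob_start <= 1")
        if self.tournament_size < 1:
            raise GAError("tournament_size must be >= 1")
        if not 0 <= self.l1_ratio <= 1:
            raise GAError("l1_ratio must be in [0, 1]")
        if self.penalty_weight < 0:
            raise GAError("penalty_weight must be >= 0")


def paper_config(seed: int = 0) -> GAConfig:
    return GAConfig(seed=seed)


def reduced_config(seed: int = 0) -> GAConfig:
    return GAConfig(population_size=100, max_generations=20, seed=seed)


# ---------------------------------------------------------------------------
# metrics


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; zero-denominator convention -> 0."""
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise GAError("counts must be nonnegative with positive total")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def mcc_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    return mcc(tp, fp, tn, fn)


def brier(probs, labels) -> float:
    """Mean squared error of predicted probability vs {0,1} outcome."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise GAError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def metrics_from_probs(probs, labels, threshold: float = 0.5) -> dict[str, float]:
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    pred = (p >= threshold).astype(float)
    tp = float(np.sum((pred == 1) & (y == 1)))
    fp = float(np.sum((pred == 1) & (y == 0)))
    tn = float(np.sum((pred == 0) & (y == 0)))
    fn = float(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return {
        "auc": float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else float("nan"),
        "acc": float((tp + tn) / len(y)),
        "f1": f1,
        "sens": sens,
        "spec": spec,
        "mcc": mcc(int(tp), int(fp), int(tn), int(fn)),
        "brier": brier(p, y),
    }


@dataclass
class Metric:
    point: float
    ci_low: float
    ci_high: float


@dataclass
class MetricBundle:
    auc: Metric
    acc: Metric
    f1: Metric
    sens: Metric
    spec: Metric
    mcc: Metric
    brier: Metric

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {k: vars(v) for k, v in vars(self).items()}


# ---------------------------------------------------------------------------
# elastic-net logistic regression


def en_logistic_fit(x, labels, l1_ratio: float = 0.5, strength: float = 1.0,
                    max_iter: int = 2000, tol: float = 1e-6,
                    positive: str | None = None) -> PanelModel:
    """Elastic-net logistic regression (saga solver).

    ``strength`` is the penalty strength; scikit-learn's inverse convention
    is used internally (C = 1/strength).
    """
    frame = x if isinstance(x, pd.DataFrame) else pd.DataFrame(np.asarray(x, dtype=float))
    y = labels if isinstance(labels, np.ndarray) else _binary(labels, positive)
    clf = LogisticRegression(
        solver="saga", l1_ratio=l1_ratio,
        C=1.0 / strength, max_iter=max_iter, tol=tol, random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(frame.to_numpy(dtype=float), y)
    converged = int(clf.n_iter_[0]) < max_iter
    if not converged:
        warnings.warn("elastic-net fit hit max_iter without converging",
                      RuntimeWarning, stacklevel=2)
    return PanelModel(
        tuple(str(c) for c in frame.columns),
        float(clf.intercept_[0]), clf.coef_.ravel(),
        training_meta={"l1_ratio": l1_ratio, "strength": strength,
                       "converged": converged},
    )


def _fast_en(X, y, config: GAConfig) -> LogisticRegression:
    """Relaxed-tolerance elastic net used inside GA fitness evaluation."""
    clf = LogisticRegression(
        solver="saga", l1_ratio=config.l1_ratio,
        C=1.0 / config.en_strength, max_iter=300, tol=1e-3, random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


# ---------------------------------------------------------------------------
# GA


EMPTY_MASK_FITNESS = -1.0


def fitness(mask: np.ndarray, X: np.ndarray, y: np.ndarray, cv_splits,
            config: GAConfig) -> float:
    """Mean held-out MCC of the masked elastic-net model minus the
    complexity penalty ``penalty_weight * max(0, k - max_features)``."""
    mask = np.asarray(mask, dtype=bool)
    k = int(mask.sum())
    if k == 0:
        return EMPTY_MASK_FITNESS
    Xm = X[:, mask]
    scores = []
    for tr, te in cv_splits:
        # dedicated proximal solver: same objective as saga, built for the
        # tens of thousands of tiny fits a GA run performs
        b, w = en_logistic_prox(Xm[tr], y[tr], C=1.0 / config.en_strength,
                                l1_ratio=config.l1_ratio, max_iter=300,
                                tol=1e-4)
        pred = (prox_predict(Xm[te], b, w) >= 0.5).astype(float)
        scores.append(mcc_from_predictions(y[te], pred))
    return float(np.mean(scores)) - config.penalty_weight * max(0, k - config.max_features)


@dataclass
class GAResult:
    best_mask: np.ndarray
    best_fitness: float
    hall_of_fame: list[tuple[np.ndarray, float]]
    history: np.ndarray            # best-so-far fitness per generation
    n_generations: int
    n_evaluations: int


def ga_evolve(X, y, cv_splits, config: GAConfig,
              fitness_fn=None) -> GAResult:
    """Run the generational GA over feature masks.

    ``fitness_fn(mask) -> float`` may replace the default elastic-net CV
    fitness (used by tests to probe the search on known landscapes).
    Fully seeded: the same config yields an identical evolution trace.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[1]
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(config.seed)

    cache: dict[bytes, float] = {}
    n_eval = 0

    def evaluate(mask: np.ndarray) -> float:
        nonlocal n_eval
        key = np.packbits(mask).tobytes()
        if key not in cache:
            n_eval += 1
            cache[key] = (fitness_fn(mask) if fitness_fn is not None
                          else fitness(mask, X, y, cv_splits, config))
        return cache[key]

    init_p = config.init_active_prob
    if init_p is None:
        # start sparse: expected actives = max_features / 2
        init_p = min(0.5, 0.5 * config.max_features / n_feat)
    pop = rng.random((config.population_size, n_feat)) < init_p
    for i in range(len(pop)):  # no empty individuals
        if not pop[i].any():
            pop[i, rng.integers(n_feat)] = True

    fits = np.array([evaluate(ind) for ind in pop])
    best_i = int(np.argmax(fits))
    best_mask, best_fit = pop[best_i].copy(), float(fits[best_i])
    history = [best_fit]
    hof: dict[bytes, tuple[np.ndarray, float]] = {}

    def record_hof(mask, f):
        hof[np.packbits(mask).tobytes()] = (mask.copy(), f)

    for ind, f in zip(pop, fits):
        record_hof(ind, f)

    stall = 0
    gen = 0
    denom = max(config.max_generations - 1, 1)
    for gen in range(1, config.max_generations):
        mut_p = (config.mutation_prob_start
                 + (config.mutation_prob_end - config.mutation_prob_start)
                 * (gen / denom))
        elite_idx = np.argsort(-fits, kind="stable")[: config.elite_count]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population_size,
                                          config.tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]].copy())
            a, b = parents
            if rng.random() < config.crossover_prob and n_feat > 2:
                c1, c2 = sorted(rng.choice(n_feat, size=2, replace=False))
                a[c1:c2], b[c1:c2] = b[c1:c2].copy(), a[c1:c2].copy()
            for child in (a, b):
                if rng.random() < mut_p:
                    flip = rng.random(n_feat) < 1.0 / n_feat
                    child ^= flip
                if not child.any():
                    child[rng.integers(n_feat)] = True
                if len(children) < config.population_size:
                    children.append(child)
        pop = np.array(children)
        fits = np.array([evaluate(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit + config.plateau_tol:
            best_mask, best_fit = pop[gen_best].copy(), float(fits[gen_best])
            stall = 0
        else:
            stall += 1
        for ind, f in zip(pop, fits):
            record_hof(ind, f)
        history.append(best_fit)
        if stall >= config.plateau_generations:
            break

    top = sorted(hof.values(), key=lambda t: -t[1])[:5]
    return GAResult(best_mask, best_fit, top, np.array(history), gen + 1, n_eval)


# ---------------------------------------------------------------------------
# nested cross-validation with stability selection


@dataclass
class OuterFoldResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    inner_masks: list[np.ndarray]
    stability_frequency: np.ndarray
    retained_features: list[str]
    test_probs: np.ndarray


@dataclass
class NestedCVResult:
    feature_ids: list[str]
    outer_folds: list[OuterFoldResult]
    oof_probs: np.ndarray                  # pooled, aligned to input samples
    labels: np.ndarray
    stability_frequency: pd.Series         # across all inner folds of all outer folds
    stable_features: list[str]             # global frequency >= 0.5

    def pooled_auc(self) -> float:
        return float(roc_auc_score(self.labels, self.oof_probs))


def _outer_folds(y: np.ndarray, outer, seed: int):
    n = len(y)
    if isinstance(outer, (list, tuple)):
        return [(np.asarray(tr), np.asarray(te)) for tr, te in outer]
    if outer == "loo":
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    skf = StratifiedKFold(n_splits=int(outer), shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(n), y))


def nested_cv(x, labels, config: GAConfig, outer="loo", inner: int = 4,
              positive: str | None = None) -> NestedCVResult:
    """Nested CV: outer folds for evaluation, inner stratified folds for GA
    optimization (one GA per inner fold), stability threshold 0.5.

    ``x`` is a processed feature frame (samples × features). Per outer fold:
    the outer-training split is cut into ``inner`` stratified folds; GA
    fitness is the mean held-out MCC across those folds; one GA replicate is
    run per inner fold (differing in seed, sharing the fitness cache) and
    its best mask recorded. The per-feature selection frequency across the
    replicates defines the retained set (frequency >= 0.5, falling back to
    the maximal-frequency features if none reaches it); the elastic net is
    then refit on the full outer-training split and scores the held-out
    samples.
    """
    frame = x.values if hasattr(x, "values") and not isinstance(x, pd.DataFrame) else pd.DataFrame(x)
    y = labels if isinstance(labels, np.ndarray) else _binary(pd.Series(labels).reindex(frame.index), positive)
    n, p = frame.shape
    if n < 2 * inner:
        raise GAError("too few samples for the inner stratification")
    X = frame.to_numpy(dtype=float)
    feature_ids = [str(c) for c in frame.columns]

    folds = _outer_folds(y, outer, config.seed)
    oof = np.full(n, np.nan)
    results = []
    all_masks: list[np.ndarray] = []
    for k, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise GAError("an outer training fold lost a class")
        inner_cv = StratifiedKFold(n_splits=inner, shuffle=True,
                                   random_state=config.seed + 7919 * k)
        splits = list(inner_cv.split(X[tr], y[tr]))
        cache: dict[bytes, float] = {}

        def shared_fitness(mask, _X=X[tr], _y=y[tr], _splits=splits):
            key = np.packbits(mask).tobytes()
            if key not in cache:
                cache[key] = fitness(mask, _X, _y, _splits, config)
            return cache[key]

        inner_masks = []
        for j in range(len(splits)):
            ga_cfg = replace(config, seed=config.seed + 104729 * k + 31 * j)
            res = ga_evolve(X[tr], y[tr], splits, ga_cfg,
                            fitness_fn=shared_fitness)
            inner_masks.append(res.best_mask)
        freq = np.mean(inner_masks, axis=0)
        retained = freq >= 0.5
        if not retained.any():
            retained = freq >= freq.max()
        clf = _fast_en(X[tr][:, retained], y[tr], config)
        oof[te] = clf.predict_proba(X[te][:, retained])[:, 1]
        results.append(OuterFoldResult(
            np.asarray(tr), np.asarray(te), inner_masks, freq,
            [f for f, r in zip(feature_ids, retained) if r],
            oof[te].copy(),
        ))
        all_masks.extend(inner_masks)
    global_freq = pd.Series(np.mean(all_masks, axis=0), index=feature_ids)
    stable = [f for f in feature_ids if global_freq[f] >= 0.5]
    return NestedCVResult(feature_ids, results, oof, y, global_freq, stable)


def evaluate_fixed_panel(x, labels, features, config: GAConfig | None = None,
                         covariate: pd.Series | None = None, outer="loo",
                         positive: str | None = None) -> np.ndarray:
    """Pooled out-of-fold probabilities of an elastic-net model on a fixed
    feature subset (optionally plus a z-scored clinical covariate)."""
    config = config or reduced_config()
    frame = x.values if hasattr(x, "values") and not isinstance(x, pd.DataFrame) else pd.DataFrame(x).copy()
    frame = frame[list(features)].copy()
    y = labels if isinstance(labels, np.ndarray) else _binary(pd.Series(labels).reindex(frame.index), positive)
    cov = None if covariate is None else pd.Series(covariate).reindex(frame.index)
    oof = np.full(len(y), np.nan)
    for tr, te in _outer_folds(y, outer, config.seed):
        Xtr, Xte = frame.iloc[tr].copy(), frame.iloc[te].copy()
        if cov is not None:
            mu = float(cov.iloc[tr].mean())
            sd = float(cov.iloc[tr].std(ddof=1)) or 1.0
            name = cov.name or "covariate"
            Xtr[name] = (cov.iloc[tr] - mu) / sd
            Xte[name] = (cov.iloc[te] - mu) / sd
        clf = _fast_en(Xtr.to_numpy(dtype=float), y[tr], config)
        oof[te] = clf.predict_proba(Xte.to_numpy(dtype=float))[:, 1]
    return oof


def bootstrap_metrics(probs, labels, n_boot: int = 2000, threshold: float = 0.5,
                      seed: int = 0) -> MetricBundle:
    """Nonparametric bootstrap 95% CIs for AUC, ACC, F1, SENS, SPEC, MCC and
    Brier. Point estimates come from the unresampled set; replicates lacking
    a class are redrawn."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise GAError("need both classes present")
    point = metrics_from_probs(p, y, threshold)
    rng = np.random.default_rng(seed)
    n = len(y)
    reps = {k: [] for k in point}
    for _ in range(n_boot):
        for _attempt in range(1000):
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) == 2:
                break
        rep = metrics_from_probs(p[idx], y[idx], threshold)
        for k, v in rep.items():
            reps[k].append(v)
    out = {}
    for k in point:
        lo, hi = np.percentile(reps[k], [2.5, 97.5])
        out[k] = Metric(point[k], float(min(lo, point[k])), float(max(hi, point[k])))
    return MetricBundle(**out)
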