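"""Ensemble classifiers of RRA labels, hyperparameter search and importance.

Two tree-ensemble families are compared on the labelled cell-dekad feature
table: AdaBoost with depth-limited decision trees, and a random forest whose
(max_depth, n_estimators) pair is selected by particle swarm optimisation
over the same box that the exhaustive grid search scans (depths 2-7,
40-50 estimators in steps of 2). Model fit quality is mean accuracy over a
shared stratified five-fold partition; the winning forest's mean
impurity-decrease importances, normalised to sum to one, rank the nine
candidate predictors and the top five are passed on to the neural classifier.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .evaluation import ConfusionCounts, metrics

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "high"


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid shared by both ensemble families."""

    max_depth: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    n_estimators: tuple[int, ...] = (40, 42, 44, 46, 48, 50)

    def __post_init__(self) -> None:
        if not self.max_depth or not self.n_estimators:
            raise ValueError("empty grid")
        if min(self.max_depth) < 1 or min(self.n_estimators) < 1:
            raise ValueError("grid values must be positive integers")

    @property
    def bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (
            (min(self.max_depth), max(self.max_depth)),
            (min(self.n_estimators), max(self.n_estimators)),
        )


@dataclass
class CVResult:
    family: str
    surface: pd.DataFrame  # max_depth, n_estimators, mean_accuracy
    best_params: dict
    best_accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    accuracy: float | None  # pooled out-of-fold accuracy of the best model


@dataclass
class ImportanceRanking:
    """Normalised predictor importances in descending order."""

    importances: dict[str, float]
    order: list[str] = field(init=False)

    def __post_init__(self) -> None:
        # ties break toward the lexicographically earlier predictor id
        self.order = sorted(self.importances, key=lambda p: (-self.importances[p], p))

    def top(self, k: int = 5) -> list[str]:
        return select_top_factors(self, k)


@dataclass(frozen=True)
class PSOConfig:
    """Canonical particle swarm settings (maximisation, clipped to bounds)."""

    swarm_size: int = 12
    iterations: int = 30
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be at least 2")
        if min(self.cognitive, self.social, self.inertia) < 0:
            raise ValueError("coefficients must be non-negative")


def _make_model(family: str, max_depth: int, n_estimators: int, seed: int):
    if family == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=max_depth, random_state=seed),
            n_estimators=n_estimators,
            learning_rate=1.0,
            random_state=seed,
        )
    if family == "rf":
        return RandomForestClassifier(
            max_depth=max_depth, n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
    raise ValueError(f"unknown family {family!r}")


def _fold_partition(y: np.ndarray, folds: int, seed: int, retries: int = 5):
    """Stratified fold indices; regenerated if any fold misses a class."""
    classes = np.unique(y)
    for attempt in range(retries):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(np.zeros(len(y)), y))
        ok = all(
            set(np.unique(y[tr])) == set(classes) and set(np.unique(y[va])) <= set(classes)
            for tr, va in splits
        )
        if ok:
            return splits
    raise RuntimeError("could not build a stratified fold partition with all classes")


def _cv_eval(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    max_depth: int,
    n_estimators: int,
    splits,
    seed: int,
) -> tuple[float, np.ndarray]:
    """Mean fold accuracy and pooled out-of-fold predictions."""
    oof = np.empty(len(y), dtype=object)
    accs = []
    for tr, va in splits:
        model = _make_model(family, max_depth, n_estimators, seed)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[va])
        oof[va] = pred
        accs.append(float((pred == y[va]).mean()))
    return float(np.mean(accs)), oof.astype(str)


def _oof_metrics(y: np.ndarray, oof: np.ndarray):
    pos = POSITIVE_LABEL
    cm = ConfusionCounts(
        tp=int(((oof == pos) & (y == pos)).sum()),
        fp=int(((oof == pos) & (y != pos)).sum()),
        fn=int(((oof != pos) & (y == pos)).sum()),
        tn=int(((oof != pos) & (y != pos)).sum()),
    )
    return metrics(cm)


def cv_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    grid: GridSpec | None = None,
    folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Exhaustive grid search with a shared stratified k-fold partition.

    Every (max_depth, n_estimators) combination is scored by mean fold
    accuracy on the same partition; the best combination's precision, recall
    and F1 come from its pooled out-of-fold predictions (positive class =
    high RRA). Ties go to the first combination in grid order.
    """
    grid = grid or GridSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=str)
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValueError(f"need at least {folds} rows per class, got {counts.to_dict()}")
    splits = _fold_partition(y, folds, seed)

    rows = []
    best = None
    for d, n in itertools.product(grid.max_depth, grid.n_estimators):
        acc, oof = _cv_eval(X, y, family, d, n, splits, seed)
        rows.append({"family": family, "max_depth": d, "n_estimators": n, "mean_accuracy": acc})
        if best is None or acc > best[0]:
            best = (acc, d, n, oof)
    acc, d, n, oof = best
    m = _oof_metrics(y, oof)
    return CVResult(
        family=family,
        surface=pd.DataFrame(rows),
        best_params={"max_depth": d, "n_estimators": n},
        best_accuracy=acc,
        precision=m.precision,
        recall=m.recall,
        f1=m.f1,
        accuracy=m.accuracy,
    )


def pso_optimize(
    fitness: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    cfg: PSOConfig | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Maximise a black-box fitness over a bounded box with a particle swarm.

    Canonical velocity update: inertia plus cognitive (personal best) and
    social (swarm best) pulls, with positions clipped to the bounds.
    Non-finite fitness values are treated as worst. Returns the swarm best,
    its fitness, and the non-decreasing best-fitness trace per iteration.
    """
    cfg = cfg or PSOConfig()
    bounds = np.asarray(bounds, dtype=float)
    if not np.isfinite(bounds).all():
        raise ValueError("bounds must be finite")
    lo, hi = bounds[:, 0], bounds[:, 1]
    dim = len(bounds)
    rng = np.random.default_rng(cfg.rng_seed)

    def safe_fitness(v: np.ndarray) -> float:
        val = float(fitness(v))
        if not np.isfinite(val):
            logger.warning("non-finite fitness at %s treated as worst", v)
            return -np.inf
        return val

    x = rng.uniform(lo, hi, size=(cfg.swarm_size, dim))
    vel = rng.uniform(-(hi - lo), hi - lo, size=(cfg.swarm_size, dim)) * 0.1
    pbest = x.copy()
    pbest_val = np.array([safe_fitness(p) for p in x])
    g = int(np.argmax(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
    trace = [gbest_val]
    for _ in range(cfg.iterations):
        r1 = rng.random((cfg.swarm_size, dim))
        r2 = rng.random((cfg.swarm_size, dim))
        vel = (
            cfg.inertia * vel
            + cfg.cognitive * r1 * (pbest - x)
            + cfg.social * r2 * (gbest - x)
        )
        x = np.clip(x + vel, lo, hi)
        for p in range(cfg.swarm_size):
            val = safe_fitness(x[p])
            if val > pbest_val[p]:
                pbest[p], pbest_val[p] = x[p].copy(), val
                if val > gbest_val:
                    gbest, gbest_val = x[p].copy(), val
        trace.append(gbest_val)
    return gbest, gbest_val, trace


def fit_pso_rf(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    grid: GridSpec | None = None,
    pso_cfg: PSOConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[CVResult, ImportanceRanking]:
    """Random forest with PSO-selected hyperparameters and importance ranking.

    PSO searches the continuous relaxation of the (max_depth, n_estimators)
    box; fitness is the mean five-fold CV accuracy of a forest at the
    rounded integer point (memoised, same fold partition as the grid
    search). The final forest is refit on all rows at the best integers;
    its mean impurity-decrease importances are normalised to sum to one.
    """
    grid = grid or GridSpec()
    pso_cfg = pso_cfg or PSOConfig(rng_seed=seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=str)
    splits = _fold_partition(y, folds, seed)

    cache: dict[tuple[int, int], tuple[float, np.ndarray]] = {}

    def fitness(v: np.ndarray) -> float:
        d, n = int(round(v[0])), int(round(v[1]))
        if (d, n) not in cache:
            cache[(d, n)] = _cv_eval(X, y, "rf", d, n, splits, seed)
        return cache[(d, n)][0]

    best_pos, best_acc, _trace = pso_optimize(fitness, grid.bounds, pso_cfg)
    d, n = int(round(best_pos[0])), int(round(best_pos[1]))
    acc, oof = cache[(d, n)]
    m = _oof_metrics(y, oof)
    surface = pd.DataFrame(
        [
            {"family": "pso_rf", "max_depth": dd, "n_estimators": nn, "mean_accuracy": a}
            for (dd, nn), (a, _) in sorted(cache.items())
        ]
    )
    result = CVResult(
        family="pso_rf",
        surface=surface,
        best_params={"max_depth": d, "n_estimators": n},
        best_accuracy=acc,
        precision=m.precision,
        recall=m.recall,
        f1=m.f1,
        accuracy=m.accuracy,
    )

    final = _make_model("rf", d, n, seed)
    final.fit(X, y)
    imp = np.asarray(final.feature_importances_, dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    ranking = ImportanceRanking(dict(zip(feature_names, imp)))
    return result, ranking


def select_top_factors(ranking: ImportanceRanking, k: int = 5) -> list[str]:
    """First k predictors by descending importance; ties break by id order."""
    if k > len(ranking.importances):
        raise ValueError(f"k={k} exceeds the {len(ranking.importances)} ranked predictors")
    return ranking.order[:k]
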