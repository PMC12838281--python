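"""Gradient boosting with spider-monkey-optimized hyperparameters.

Spider monkey optimization (SMO) is a fission–fusion population
metaheuristic: the population forages in groups led by local leaders under
one global leader; members move by component-wise perturbations toward
their leaders, stagnating local groups are re-dispersed, and a stagnating
global leader triggers a group split.  Here SMO minimizes the stratified
cross-validated error of a multinomial-deviance gradient-boosting
classifier over a bounded hyperparameter box (learning rate, number of
stages, depth, minimum leaf size; integers relaxed to reals and rounded at
evaluation).

The boosting surface also exposes external backends (XGBoost; CatBoost if
installed) behind one fit/predict-probability adapter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .metaheuristics import OptimizerResult

__all__ = [
    "SMOConfig",
    "GBMModel",
    "BoostingBackendSpec",
    "BackendUnavailableError",
    "smo_optimize",
    "gbm_fit",
    "gbm_predict",
    "gbm_staged_deviance",
    "smo_gbm_train",
    "backend_fit",
    "DEFAULT_GBM_PARAMS",
    "DEFAULT_SEARCH_SPACE",
]

#: default GBM hyperparameters: 100 stages, learning rate 0.2, full
#: subsample, unrestricted depth, minimum leaf size 1
DEFAULT_GBM_PARAMS = {
    "n_estimators": 100,
    "learning_rate": 0.2,
    "subsample": 1.0,
    "max_depth": None,
    "min_samples_leaf": 1,
}


@dataclass
class SMOConfig:
    """SMO control parameters.

    Reference settings: population 250, global-leader limit 50,
    local-leader limit 75, perturbation rate 0.5, 500 iterations; reduced
    budgets are used for small problems.
    """

    population: int = 250
    local_leader_limit: int = 75
    global_leader_limit: int = 50
    perturbation_rate: float = 0.5
    iterations: int = 500
    seed: int = 0
    max_groups: int | None = None  # default population // 10

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4 (groups must be splittable)")
        if not (0.0 <= self.perturbation_rate <= 1.0):
            raise ValueError("perturbation rate must lie in [0, 1]")


def smo_optimize(
    objective,
    dim: int,
    bounds: tuple[float, float] | list[tuple[float, float]],
    config: SMOConfig,
) -> OptimizerResult:
    """Minimize ``objective`` over a box by spider monkey optimization.

    Phases per iteration: local-leader moves (component-wise with
    probability Pr, attraction to the local leader plus a random peer
    term), a fitness-probability global-leader phase (members are updated
    with probability proportional to inverse fitness — the maximization
    transform adapted to minimization), greedy selection throughout,
    local-leader re-dispersal after ``local_leader_limit`` stagnant rounds,
    and a group split (up to population//10 groups, then merge back to
    one) after ``global_leader_limit`` stagnant rounds.
    """
    rng = np.random.default_rng(config.seed)
    if isinstance(bounds, tuple) and np.isscalar(bounds[0]):
        lb = np.full(dim, float(bounds[0]))
        ub = np.full(dim, float(bounds[1]))
    else:
        lb = np.array([b[0] for b in bounds], dtype=float)
        ub = np.array([b[1] for b in bounds], dtype=float)
    H = config.population
    Pr = config.perturbation_rate
    max_groups = config.max_groups or max(H // 10, 1)

    def ev(x: np.ndarray) -> float:
        v = float(objective(x))
        return v if np.isfinite(v) else np.inf

    pos = lb + rng.uniform(size=(H, dim)) * (ub - lb)
    fit = np.array([ev(p) for p in pos])
    n_eval = H

    groups: list[np.ndarray] = [np.arange(H)]
    gbest_idx = int(np.argmin(fit))
    gbest = pos[gbest_idx].copy()
    gbest_fit = float(fit[gbest_idx])
    gl_count = 0
    trace = [gbest_fit]

    def local_leaders() -> list[tuple[np.ndarray, float]]:
        out = []
        for g in groups:
            i = g[int(np.argmin(fit[g]))]
            out.append((pos[i].copy(), float(fit[i])))
        return out

    lls = local_leaders()
    ll_counts = [0] * len(groups)

    for _ in range(config.iterations):
        # --- local-leader phase
        for gi, g in enumerate(groups):
            ll_pos = lls[gi][0]
            for i in g:
                update = rng.uniform(size=dim) < Pr
                if not update.any():
                    continue
                peer = int(rng.choice(g))
                new = pos[i].copy()
                new[update] = (
                    pos[i][update]
                    + rng.uniform(size=update.sum())
                    * (ll_pos[update] - pos[i][update])
                    + rng.uniform(-1, 1, size=update.sum())
                    * (pos[peer][update] - pos[i][update])
                )
                new = np.clip(new, lb, ub)
                f = ev(new)
                n_eval += 1
                if f < fit[i]:  # greedy selection
                    pos[i], fit[i] = new, f

        # --- global-leader phase: selection probability by inverse fitness
        inv = 1.0 / (1.0 + np.where(np.isfinite(fit), fit - fit.min(), np.inf))
        prob = 0.9 * inv / inv.max() + 0.1
        for gi, g in enumerate(groups):
            for i in g:
                if rng.uniform() >= prob[i]:
                    continue
                h = int(rng.integers(dim))
                peer = int(rng.choice(g))
                new = pos[i].copy()
                new[h] = (
                    pos[i][h]
                    + rng.uniform() * (gbest[h] - pos[i][h])
                    + rng.uniform(-1, 1) * (pos[peer][h] - pos[i][h])
                )
                new = np.clip(new, lb, ub)
                f = ev(new)
                n_eval += 1
                if f < fit[i]:
                    pos[i], fit[i] = new, f

        # --- leader learning
        new_lls = local_leaders()
        for gi in range(len(groups)):
            if new_lls[gi][1] < lls[gi][1] - 1e-15:
                ll_counts[gi] = 0
            else:
                ll_counts[gi] += 1
        lls = new_lls
        cur_best = int(np.argmin(fit))
        if fit[cur_best] < gbest_fit - 1e-15:
            gbest = pos[cur_best].copy()
            gbest_fit = float(fit[cur_best])
            gl_count = 0
        else:
            gl_count += 1

        # --- local-leader decision: re-disperse stagnant groups
        for gi, g in enumerate(groups):
            if ll_counts[gi] > config.local_leader_limit:
                ll_counts[gi] = 0
                ll_pos = lls[gi][0]
                for i in g:
                    if rng.uniform() < 0.5:
                        new = lb + rng.uniform(size=dim) * (ub - lb)
                    else:
                        new = (
                            pos[i]
                            + rng.uniform(size=dim) * (gbest - pos[i])
                            + rng.uniform(size=dim) * (pos[i] - ll_pos)
                        )
                    new = np.clip(new, lb, ub)
                    f = ev(new)
                    n_eval += 1
                    if f < fit[i]:
                        pos[i], fit[i] = new, f

        # --- global-leader decision: split, or merge when too many groups
        if gl_count > config.global_leader_limit:
            gl_count = 0
            if len(groups) < max_groups:
                largest = int(np.argmax([len(g) for g in groups]))
                g = groups.pop(largest)
                half = len(g) // 2
                groups.extend([g[:half], g[half:]])
            else:
                groups = [np.arange(H)]
            lls = local_leaders()
            ll_counts = [0] * len(groups)

        trace.append(gbest_fit)

    return OptimizerResult(
        position=gbest, fitness=gbest_fit, trace=trace, n_evaluations=n_eval
    )


# ---------------------------------------------------------------------------
# Gradient boosting surface


@dataclass
class GBMModel:
    """A fitted multinomial-deviance gradient-boosting classifier.

    The staged prediction after g stages is the initial constant plus the
    sum of the first g shrunken regression-tree increments; the training
    deviance is non-increasing per stage.
    """

    estimator: GradientBoostingClassifier
    params: dict
    classes_: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.classes_ = self.estimator.classes_


def gbm_fit(X: np.ndarray, y: np.ndarray, params: dict | None = None) -> GBMModel:
    """Fit gradient boosting with multinomial deviance loss."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    p = dict(DEFAULT_GBM_PARAMS)
    if params:
        p.update(params)
    est = GradientBoostingClassifier(
        n_estimators=int(p["n_estimators"]),
        learning_rate=float(p["learning_rate"]),
        subsample=float(p.get("subsample", 1.0)),
        max_depth=p["max_depth"] if p["max_depth"] is None else int(p["max_depth"]),
        min_samples_leaf=int(p["min_samples_leaf"]),
        random_state=int(p.get("seed", 0)),
    )
    est.fit(np.asarray(X, dtype=float), y)
    return GBMModel(estimator=est, params=p)


def gbm_predict(model: GBMModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities via softmax over per-class boosted scores."""
    return model.estimator.predict_proba(np.asarray(X, dtype=float))


def gbm_staged_deviance(model: GBMModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Multinomial deviance of the training data after each stage."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = model.classes_
    onehot = (y[:, None] == classes[None, :]).astype(float)
    out = []
    for proba in model.estimator.staged_predict_proba(X):
        out.append(float(-(onehot * np.log(np.clip(proba, 1e-12, 1))).sum(axis=1).mean()))
    return np.array(out)


# ---------------------------------------------------------------------------
# SMO-tuned GBM

#: hyperparameter box for tuning: (learning rate, n_estimators, max depth,
#: min samples per leaf); integer axes relaxed and rounded at evaluation
DEFAULT_SEARCH_SPACE = {
    "learning_rate": (0.01, 0.5),
    "n_estimators": (20.0, 150.0),
    "max_depth": (1.0, 6.0),
    "min_samples_leaf": (1.0, 10.0),
}


def _decode_point(x: np.ndarray, keys: list[str]) -> dict:
    params = {}
    for val, key in zip(x, keys):
        if key == "learning_rate":
            params[key] = float(val)
        else:
            params[key] = int(round(val))
    return params


def _gbm_cv_error(
    X: np.ndarray, y: np.ndarray, params: dict, folds: int = 3, seed: int = 0
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for tr, te in skf.split(X, y):
        model = gbm_fit(X[tr], y[tr], {**params, "seed": seed})
        pred = model.classes_[np.argmax(gbm_predict(model, X[te]), axis=1)]
        errs.append(float(np.mean(pred != y[te])))
    return float(np.mean(errs))


def smo_gbm_train(
    X: np.ndarray,
    y: np.ndarray,
    search_space: dict | None = None,
    smo_config: SMOConfig | None = None,
    cv_folds: int = 3,
    seed: int = 0,
) -> tuple[GBMModel, dict, OptimizerResult]:
    """Tune GBM hyperparameters by SMO and refit on all data.

    One SMO individual is seeded at the default hyperparameters (clipped
    into the box), so the tuned cross-validated error never exceeds the
    default configuration's.  Returns the refitted model, the best
    hyperparameters and the optimizer trace.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    space = search_space or DEFAULT_SEARCH_SPACE
    keys = list(space.keys())
    bounds = [tuple(map(float, space[k])) for k in keys]
    config = smo_config or SMOConfig(
        population=8, iterations=6, local_leader_limit=5,
        global_leader_limit=4, seed=seed,
    )
    cache: dict[tuple, float] = {}

    def objective(x: np.ndarray) -> float:
        params = _decode_point(np.asarray(x), keys)
        key = tuple(sorted(params.items()))
        if key not in cache:
            cache[key] = _gbm_cv_error(X, y, params, folds=cv_folds, seed=seed)
        return cache[key]

    # seed the defaults into the box so they are always evaluated
    default_point = []
    for k, (lo, hi) in zip(keys, bounds):
        v = DEFAULT_GBM_PARAMS.get(k)
        if v is None:  # unrestricted depth maps to the box's upper edge
            v = hi
        default_point.append(float(np.clip(v, lo, hi)))
    default_point = np.array(default_point)

    res = smo_optimize(objective, len(keys), bounds, config)
    f_default = objective(default_point)
    if f_default < res.fitness:
        res = OptimizerResult(
            position=default_point, fitness=f_default,
            trace=res.trace, n_evaluations=res.n_evaluations + 1,
        )
    best_params = _decode_point(res.position, keys)
    model = gbm_fit(X, y, {**best_params, "seed": seed})
    return model, best_params, res


# ---------------------------------------------------------------------------
# External boosting backends


class BackendUnavailableError(RuntimeError):
    """The requested boosting backend is not installed."""


@dataclass
class BoostingBackendSpec:
    """Which boosting backend to use and its hyperparameters.

    Reference settings: CatBoost iterations 500, learning rate 0.08,
    depth 4, L2 leaf regularization 3; XGBoost eta 0.4, gamma 0,
    max_depth 5, lambda 0.5, alpha 0, max_leaves 4.
    """

    backend: str = "internal"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backend not in ("internal", "xgboost", "catboost"):
            raise ValueError(f"unknown backend: {self.backend!r}")


class _BackendModel:
    """Uniform fit/predict-probability adapter over backends."""

    def __init__(self, backend: str, model, classes: np.ndarray):
        self.backend = backend
        self.model = model
        self.classes_ = classes

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.backend == "internal":
            return gbm_predict(self.model, X)
        return self.model.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def backend_fit(
    X: np.ndarray, y: np.ndarray, spec: BoostingBackendSpec
) -> _BackendModel:
    """Train a boosting backend; hyperparameters pass through verbatim.

    A missing optional backend raises :class:`BackendUnavailableError`
    rather than silently substituting another implementation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    hp = dict(spec.hyperparameters)
    if spec.backend == "internal":
        return _BackendModel("internal", gbm_fit(X, y, hp), classes)
    if spec.backend == "xgboost":
        try:
            import xgboost as xgb
        except ImportError as exc:
            raise BackendUnavailableError("xgboost is not installed") from exc
        hp.setdefault("n_estimators", 100)
        model = xgb.XGBClassifier(**hp, verbosity=0)
        codes = np.searchsorted(classes, y)
        model.fit(X, codes)
        return _BackendModel("xgboost", model, classes)
    if spec.backend == "catboost":
        try:
            import catboost  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError("catboost is not installed") from exc
        model = catboost.CatBoostClassifier(**hp, verbose=False)
        model.fit(X, y)
        return _BackendModel("catboost", model, classes)
    raise ValueError(f"unknown backend: {spec.backend!r}")
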