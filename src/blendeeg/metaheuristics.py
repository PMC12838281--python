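"""Wrapper feature selection by population metaheuristics.

A feature subset is a binary string P of length J (bit k = 1 keeps feature
k).  Subsets are scored by the shared wrapper fitness

    fitness(P) = gamma * Err(P) + beta * |P| / J,        gamma + beta = 1,

where Err(P) is the stratified k-fold error of a nearest-neighbour
classifier restricted to the selected features — lower is better.  The
optimizers search a continuous space and candidate positions are turned
into bits by a stochastic sigmoid transfer with an all-zero repair rule.

Three optimizers share one calling convention (minimize ``objective`` over
a box):

* grey wolf optimization (GWO) — agents move toward the mean of three
  attraction points around the alpha/beta/delta leaders, with the control
  scalar decaying linearly from 2 to 0 over the run;
* the salp-swarm / particle-swarm hybrid (SSO-PSO) — the best individual
  moves by the salp-leader rule around the food source (global best) while
  every other individual follows a PSO velocity rule whose attractors are
  its personal best and the food source;
* Bayesian optimization (BOA) — a Gaussian-process surrogate with an
  expected-improvement acquisition maximized over a random candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .filter_selection import FeatureMask

__all__ = [
    "FitnessSpec",
    "OptimizerResult",
    "evaluate_fitness",
    "knn_cv_error",
    "gwo_optimize",
    "sso_pso_optimize",
    "boa_optimize",
    "binarize",
    "wrapper_select",
]


@dataclass
class FitnessSpec:
    """Weights and error protocol of the wrapper fitness.

    gamma weighs the classification error, beta the selected-subset size
    ratio; they sum to one.  The error estimator is a stratified
    ``cv_folds``-fold nearest-neighbour (``knn_k``) classifier, which keeps
    each fitness evaluation cheap.
    """

    gamma: float = 0.99
    beta: float = 0.01
    knn_k: int = 5
    cv_folds: int = 3
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("gamma and beta must lie in [0, 1]")
        if abs(self.gamma + self.beta - 1.0) > 1e-12:
            raise ValueError("gamma + beta must equal 1")


@dataclass
class OptimizerResult:
    """Best position found plus the best-so-far fitness trace."""

    position: np.ndarray
    fitness: float
    trace: list[float] = field(default_factory=list)
    n_evaluations: int = 0


def knn_cv_error(
    X: np.ndarray, y: np.ndarray, spec: FitnessSpec
) -> float:
    """Stratified k-fold nearest-neighbour misclassification rate.

    Features are z-scored on each training fold (fold statistics only) so
    no single high-variance feature dominates the Euclidean metric.
    """
    _, counts = np.unique(y, return_counts=True)
    folds = min(spec.cv_folds, counts.min())
    if folds < 2:
        raise ValueError("need at least 2 samples per class for stratified CV")
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=spec.cv_seed
    )
    errors = []
    for tr, te in skf.split(X, y):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        k = min(spec.knn_k, len(tr))
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit((X[tr] - mu) / sd, y[tr])
        pred = clf.predict((X[te] - mu) / sd)
        errors.append(float(np.mean(pred != y[te])))
    return float(np.mean(errors))


def evaluate_fitness(
    mask: FeatureMask | np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    spec: FitnessSpec | None = None,
) -> float:
    """Wrapper fitness gamma*Err + beta*(selected/total); in [0, 1],
    lower is better, deterministic given the spec's CV seed."""
    spec = spec or FitnessSpec()
    bits = mask.bits if isinstance(mask, FeatureMask) else np.asarray(mask)
    idx = np.flatnonzero(bits)
    if idx.size == 0:
        raise ValueError("mask selects no features (repair before evaluating)")
    err = knn_cv_error(X[:, idx], y, spec)
    return spec.gamma * err + spec.beta * (idx.size / bits.size)


# ---------------------------------------------------------------------------
# Continuous optimizers


def _init_population(
    rng: np.random.Generator, pop: int, dim: int, lb: np.ndarray, ub: np.ndarray
) -> np.ndarray:
    return lb + rng.uniform(size=(pop, dim)) * (ub - lb)


def _safe_eval(objective, x: np.ndarray) -> float:
    v = float(objective(x))
    return v if np.isfinite(v) else np.inf


def gwo_optimize(
    objective,
    dim: int,
    bounds: tuple[float, float] = (0.0, 1.0),
    pop: int = 200,
    iters: int = 500,
    seed: int = 0,
) -> OptimizerResult:
    """Grey wolf optimization.

    Per iteration the control scalar v decays linearly from 2 to 0; each
    agent draws coefficient vectors V = 2*v*r1 - v and C = 2*r2 for each of
    the three leaders (alpha, beta, delta), forms the attraction points
    P1..P3 and moves to their mean, clipped to bounds.  Greedy bookkeeping
    keeps the best-so-far non-increasing.
    """
    if pop < 3:
        raise ValueError("need at least 3 wolves (alpha, beta, delta)")
    rng = np.random.default_rng(seed)
    lb = np.full(dim, bounds[0], dtype=float)
    ub = np.full(dim, bounds[1], dtype=float)
    P = _init_population(rng, pop, dim, lb, ub)
    fit = np.array([_safe_eval(objective, p) for p in P])
    order = np.argsort(fit)
    leaders = P[order[:3]].copy()
    leader_fit = fit[order[:3]].copy()
    trace = [float(leader_fit[0])]
    n_eval = pop

    for t in range(iters):
        v = 2.0 - t * 2.0 / iters
        cand = np.empty_like(P)
        for li in range(3):
            r1 = rng.uniform(size=(pop, dim))
            r2 = rng.uniform(size=(pop, dim))
            V = 2.0 * v * r1 - v
            C = 2.0 * r2
            D = np.abs(C * leaders[li][None, :] - P)
            cand_li = leaders[li][None, :] - V * D
            if li == 0:
                cand = cand_li / 3.0
            else:
                cand += cand_li / 3.0
        P = np.clip(cand, lb, ub)
        fit = np.array([_safe_eval(objective, p) for p in P])
        n_eval += pop
        # refresh the three leaders from the union of old leaders + new pack
        all_pos = np.vstack([leaders, P])
        all_fit = np.concatenate([leader_fit, fit])
        order = np.argsort(all_fit)
        leaders = all_pos[order[:3]].copy()
        leader_fit = all_fit[order[:3]].copy()
        trace.append(float(leader_fit[0]))

    return OptimizerResult(
        position=leaders[0], fitness=float(leader_fit[0]),
        trace=trace, n_evaluations=n_eval,
    )


def sso_pso_optimize(
    objective,
    dim: int,
    bounds: tuple[float, float] = (0.0, 1.0),
    pop: int = 600,
    iters: int = 1000,
    seed: int = 0,
    inertia: float = 0.5,
    alpha1: float = 2.0,
    alpha2: float = 2.0,
) -> OptimizerResult:
    """Hybrid salp-swarm / particle-swarm optimizer.

    The current best individual acts as the salp leader and jumps around
    the food source f (global best) with step r1*(ub-lb)*r2 + lb, where
    r1 = 2*exp(-(4c/M)^2) shifts from exploration to exploitation; all
    other individuals move by the PSO velocity rule with their personal
    best and the food source as attractors.
    """
    if pop < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    lb = np.full(dim, bounds[0], dtype=float)
    ub = np.full(dim, bounds[1], dtype=float)
    Z = _init_population(rng, pop, dim, lb, ub)
    V = np.zeros_like(Z)
    fit = np.array([_safe_eval(objective, z) for z in Z])
    pbest = Z.copy()
    pbest_fit = fit.copy()
    g = int(np.argmin(fit))
    food = Z[g].copy()
    food_fit = float(fit[g])
    trace = [food_fit]
    n_eval = pop

    for c in range(1, iters + 1):
        r1 = 2.0 * np.exp(-((4.0 * c / iters) ** 2))
        leader = int(np.argmin(fit))
        for i in range(pop):
            if i == leader:
                r2 = rng.uniform(size=dim)
                r3 = rng.uniform(size=dim)
                step = r1 * ((ub - lb) * r2 + lb)
                Z[i] = np.where(r3 >= 0.5, food + step, food - step)
            else:
                ru = rng.uniform(size=dim)
                rv = rng.uniform(size=dim)
                V[i] = (
                    inertia * V[i]
                    + alpha1 * ru * (pbest[i] - Z[i])
                    + alpha2 * rv * (food - Z[i])
                )
                Z[i] = Z[i] + V[i]
        Z = np.clip(Z, lb, ub)
        fit = np.array([_safe_eval(objective, z) for z in Z])
        n_eval += pop
        improved = fit < pbest_fit
        pbest[improved] = Z[improved]
        pbest_fit[improved] = fit[improved]
        b = int(np.argmin(pbest_fit))
        if pbest_fit[b] < food_fit:
            food = pbest[b].copy()
            food_fit = float(pbest_fit[b])
        trace.append(food_fit)

    return OptimizerResult(
        position=food, fitness=food_fit, trace=trace, n_evaluations=n_eval
    )


def _expected_improvement(
    mu: np.ndarray, sd: np.ndarray, best: float
) -> np.ndarray:
    from scipy.stats import norm

    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return (best - mu) * norm.cdf(z) + sd * norm.pdf(z)


def boa_optimize(
    objective,
    dim: int,
    bounds: tuple[float, float] = (0.0, 1.0),
    budget: int = 60,
    n_initial: int | None = None,
    seed: int = 0,
    candidate_pool: int = 256,
    noise: float = 1e-2,
) -> OptimizerResult:
    """Bayesian optimization: RBF-kernel Gaussian-process surrogate with
    expected-improvement acquisition, maximized over a random candidate
    pool each step.

    ``noise`` is the assumed observation-noise variance; the wrapper
    objective is stochastic through binarization, so the surrogate must
    not interpolate exactly.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel

    rng = np.random.default_rng(seed)
    lb = np.full(dim, bounds[0], dtype=float)
    ub = np.full(dim, bounds[1], dtype=float)
    n_init = n_initial if n_initial is not None else min(max(2 * dim, 5), budget // 2)
    n_init = max(2, min(n_init, budget - 1))
    X = _init_population(rng, n_init, dim, lb, ub)
    yv = np.array([_safe_eval(objective, x) for x in X])
    trace = list(np.minimum.accumulate(yv).astype(float))

    kernel = ConstantKernel(1.0) * RBF(length_scale=np.sqrt(dim) / 2.0)
    while len(yv) < budget:
        finite = np.isfinite(yv)
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, alpha=noise,
            random_state=int(rng.integers(2**31 - 1)),
        )
        gp.fit(X[finite], yv[finite])
        cand = _init_population(rng, candidate_pool, dim, lb, ub)
        mu, sd = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sd, float(yv[finite].min()))
        x_next = cand[int(np.argmax(ei))]
        y_next = _safe_eval(objective, x_next)
        X = np.vstack([X, x_next])
        yv = np.append(yv, y_next)
        trace.append(float(min(trace[-1], y_next)))

    best = int(np.argmin(yv))
    return OptimizerResult(
        position=X[best], fitness=float(yv[best]),
        trace=trace, n_evaluations=len(yv),
    )


# ---------------------------------------------------------------------------
# Binarization


def binarize(
    position: np.ndarray, rng: np.random.Generator, transfer: str = "sigmoid"
) -> FeatureMask:
    """Stochastic sigmoid transfer: bit k = 1 iff S(x_k) > u_k with
    u_k ~ Uniform(0,1).  An all-zero draw is repaired by forcing the bit
    with the largest transfer value to 1."""
    if transfer != "sigmoid":
        raise ValueError(f"unknown transfer function: {transfer!r}")
    x = np.asarray(position, dtype=float)
    s = 1.0 / (1.0 + np.exp(-x))
    bits = (s > rng.uniform(size=x.shape)).astype(int)
    if bits.sum() == 0:
        bits[int(np.argmax(s))] = 1
    return FeatureMask(bits=bits)


# ---------------------------------------------------------------------------
# Wrapper selection

#: slope applied to (u - 1/2) before the sigmoid transfer so positions in
#: [0,1] span bit probabilities ~[0.02, 0.98]
TRANSFER_GAIN = 8.0


def _boa_mask_search(
    X: np.ndarray,
    y: np.ndarray,
    spec: FitnessSpec,
    budget: int,
    rng: np.random.Generator,
    cache: dict,
    best_holder: dict,
    candidate_pool: int = 128,
) -> OptimizerResult:
    """Bayesian optimization over the binary mask space.

    The fitness of a mask is deterministic, so the GP surrogate is fitted
    on the evaluated mask *vertices* of the hypercube rather than on the
    continuous positions that generated them.  Candidate masks come from
    the stochastic sigmoid transfer on random positions plus single
    bit-flip mutations of the incumbent; expected improvement picks the
    next mask to evaluate.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel

    J = X.shape[1]

    def eval_mask(mask: FeatureMask) -> float:
        key = mask.bits.astype(np.int8).tobytes()
        if key not in cache:
            cache[key] = evaluate_fitness(mask, X, y, spec)
        f = cache[key]
        if f < best_holder["fitness"]:
            best_holder["fitness"] = f
            best_holder["mask"] = mask
        return f

    def random_mask() -> FeatureMask:
        return binarize(TRANSFER_GAIN * (rng.uniform(size=J) - 0.5), rng)

    n_init = max(4, min(2 * J, budget // 3))
    corners, vals = [], []
    for _ in range(n_init):
        mask = random_mask()
        corners.append(mask.bits.astype(float))
        vals.append(eval_mask(mask))
    trace = list(np.minimum.accumulate(vals).astype(float))

    kernel = ConstantKernel(1.0) * RBF(length_scale=np.sqrt(J) / 2.0)
    n_eval = n_init
    while n_eval < budget:
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, alpha=1e-6,
            random_state=int(rng.integers(2**31 - 1)),
        )
        gp.fit(np.array(corners), np.array(vals))
        cand = [random_mask().bits.astype(float) for _ in range(candidate_pool)]
        incumbent = best_holder["mask"].bits
        for k in range(J):  # single bit flips of the incumbent
            flip = incumbent.astype(float).copy()
            flip[k] = 1.0 - flip[k]
            if flip.sum() >= 1:
                cand.append(flip)
        cand = np.unique(np.array(cand), axis=0)
        mu, sd = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sd, float(min(vals)))
        pick = cand[int(np.argmax(ei))].astype(int)
        mask = FeatureMask(bits=pick)
        corners.append(pick.astype(float))
        vals.append(eval_mask(mask))
        n_eval += 1
        trace.append(float(min(trace[-1], vals[-1])))

    return OptimizerResult(
        position=best_holder["mask"].bits.astype(float),
        fitness=float(best_holder["fitness"]),
        trace=trace, n_evaluations=n_eval,
    )


def wrapper_select(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str = "gwo",
    spec: FitnessSpec | None = None,
    pop: int = 20,
    iters: int = 30,
    budget: int | None = None,
    seed: int = 0,
    **optimizer_kwargs,
) -> tuple[FeatureMask, OptimizerResult]:
    """Select features by optimizing the wrapper fitness.

    Positions live in [0,1]^J; each candidate is binarized (stochastic
    sigmoid on gain*(u - 1/2)) and scored by :func:`evaluate_fitness`.
    Mask fitnesses are cached so re-visited subsets cost nothing.  Returns
    the best mask seen together with the optimizer trace.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    J = X.shape[1]
    if J < 2:
        raise ValueError("need at least 2 features")
    spec = spec or FitnessSpec()
    rng = np.random.default_rng(seed)
    cache: dict[bytes, float] = {}
    best_holder: dict = {"mask": None, "fitness": np.inf}

    def objective(u: np.ndarray) -> float:
        mask = binarize(TRANSFER_GAIN * (np.asarray(u) - 0.5), rng)
        key = mask.bits.astype(np.int8).tobytes()
        if key not in cache:
            cache[key] = evaluate_fitness(mask, X, y, spec)
        f = cache[key]
        if f < best_holder["fitness"]:
            best_holder["fitness"] = f
            best_holder["mask"] = mask
        return f

    opt_seed = int(rng.integers(2**31 - 1))
    if algorithm == "gwo":
        res = gwo_optimize(
            objective, J, (0.0, 1.0), pop=pop, iters=iters, seed=opt_seed,
            **optimizer_kwargs,
        )
    elif algorithm == "sso_pso":
        res = sso_pso_optimize(
            objective, J, (0.0, 1.0), pop=pop, iters=iters, seed=opt_seed,
            **optimizer_kwargs,
        )
    elif algorithm == "boa":
        b = budget if budget is not None else pop * iters
        if b < 4:
            raise ValueError("evaluation budget too small")
        res = _boa_mask_search(
            X, y, spec, budget=b, rng=rng, cache=cache,
            best_holder=best_holder, **optimizer_kwargs,
        )
    else:
        raise ValueError(f"unknown wrapper algorithm: {algorithm!r}")

    mask = best_holder["mask"]
    res.fitness = float(best_holder["fitness"])
    return mask, res
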