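"""Swarm metaheuristics (SSA, PSO, GWO) and BPNN architecture search.

All three optimizers minimize a scalar objective over a box, share one
configuration type and return the same result contract: the best position,
its fitness, a per-iteration best-so-far history and the evaluation count.

The sparrow search algorithm (SSA) splits the population into producers
(the fittest fraction, ranging widely), scroungers (following the best
producer) and forewarners (a random fraction relocating relative to the
global best/worst when alarmed). PSO and GWO are the canonical comparator
algorithms. The architecture-search harness binds any of them to the
cross-validated accuracy of a BPNN whose hidden-layer node counts are the
integer search variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .bpnn import BPNNConfig, accuracy, init_model, train

__all__ = [
    "SwarmConfig",
    "OptResult",
    "ssa_optimize",
    "pso_optimize",
    "gwo_optimize",
    "optimize_bpnn_architecture",
]

#: Small constant guarding divisions in the forewarner update.
SSA_EPS = 1e-8


@dataclass(frozen=True)
class SwarmConfig:
    population: int = 15
    iterations: int = 100
    bounds: tuple[tuple[float, float], ...] = ((-5.0, 5.0),) * 5
    integer_dims: frozenset[int] = frozenset()
    producer_fraction: float = 0.2
    forewarner_fraction: float = 0.1
    safety_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bounds", tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        )
        object.__setattr__(self, "integer_dims", frozenset(self.integer_dims))
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for lo, hi in self.bounds:
            # lo == hi is allowed: a dimension collapsed to a single point
            if lo > hi:
                raise ValueError(f"invalid bound [{lo}, {hi}]")
        for frac in (self.producer_fraction, self.forewarner_fraction):
            if not 0.0 < frac < 1.0:
                raise ValueError("fractions must be in (0, 1)")
        if not 0.5 <= self.safety_threshold <= 1.0:
            raise ValueError("safety_threshold must be in [0.5, 1]")

    @property
    def n_dims(self) -> int:
        return len(self.bounds)

    def with_(self, **kwargs) -> "SwarmConfig":
        return replace(self, **kwargs)


@dataclass
class OptResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    evaluations: int


def _clip_round(X: np.ndarray, config: SwarmConfig) -> np.ndarray:
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    X = np.clip(X, lo, hi)
    for j in config.integer_dims:
        X[..., j] = np.round(X[..., j])
    return X


def _evaluate(objective: Callable, X: np.ndarray) -> np.ndarray:
    f = np.array([float(objective(x)) for x in X])
    if np.isnan(f).any():
        bad = X[int(np.flatnonzero(np.isnan(f))[0])]
        raise FloatingPointError(f"objective returned NaN at position {bad}")
    return f


def _init_population(
    config: SwarmConfig, rng: np.random.Generator
) -> np.ndarray:
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    X = rng.uniform(lo, hi, size=(config.population, config.n_dims))
    return _clip_round(X, config)


def ssa_optimize(objective: Callable, config: SwarmConfig) -> OptResult:
    """Sparrow search algorithm (minimization).

    Each iteration the population is ranked by fitness. The best
    ``producer_fraction`` are producers: while the alarm value R2 stays
    below the safety threshold they contract multiplicatively
    (``x * exp(-i / (alpha T))``); once alarmed they take a Gaussian step.
    The remaining scroungers follow the best producer (the worse half
    instead jump relative to the globally worst position), and a random
    ``forewarner_fraction`` relocate around the global best.
    """
    rng = np.random.default_rng(config.seed)
    pop, T, d = config.population, config.iterations, config.n_dims
    X = _init_population(config, rng)
    f = _evaluate(objective, X)
    evals = pop
    best_i = int(np.argmin(f))
    best_x, best_f = X[best_i].copy(), float(f[best_i])
    history: list[float] = []
    n_prod = max(1, int(round(pop * config.producer_fraction)))
    n_warn = max(1, int(round(pop * config.forewarner_fraction)))
    for t in range(1, T + 1):
        order = np.argsort(f)
        X, f = X[order], f[order]
        x_best_iter = X[0].copy()
        x_worst = X[-1].copy()
        f_worst = float(f[-1])
        R2 = rng.uniform()
        new_X = X.copy()
        # producers
        for rank in range(n_prod):
            i = rank + 1
            if R2 < config.safety_threshold:
                alpha = rng.uniform(np.finfo(float).tiny, 1.0)
                new_X[rank] = X[rank] * np.exp(-i / (alpha * T))
            else:
                Q = rng.normal()
                new_X[rank] = X[rank] + Q
        x_p = new_X[0].copy()  # best producer after its own update
        # scroungers
        for rank in range(n_prod, pop):
            i = rank + 1
            if i > pop / 2:
                Q = rng.normal()
                new_X[rank] = Q * np.exp((x_worst - X[rank]) / i**2)
            else:
                signs = rng.choice([-1.0, 1.0], size=d)
                step = np.dot(np.abs(X[rank] - x_p), signs) / d
                new_X[rank] = x_p + step
        # forewarners
        for rank in rng.choice(pop, size=min(n_warn, pop), replace=False):
            if f[rank] > f[0]:
                beta = rng.normal()
                new_X[rank] = x_best_iter + beta * np.abs(new_X[rank] - x_best_iter)
            else:
                K = rng.uniform(-1.0, 1.0)
                new_X[rank] = new_X[rank] + K * (
                    np.abs(new_X[rank] - x_worst) / ((f[rank] - f_worst) + SSA_EPS)
                )
        X = _clip_round(new_X, config)
        f = _evaluate(objective, X)
        evals += pop
        i_min = int(np.argmin(f))
        if f[i_min] < best_f:
            best_f = float(f[i_min])
            best_x = X[i_min].copy()
        history.append(best_f)
    return OptResult(best_x, best_f, history, evals)


def pso_optimize(
    objective: Callable,
    config: SwarmConfig,
    inertia: float = 0.7,
    cognitive: float = 1.5,
    social: float = 1.5,
) -> OptResult:
    """Canonical particle swarm optimization with inertia weight; velocity
    clamped to 20% of each dimension's span."""
    rng = np.random.default_rng(config.seed)
    pop, T, d = config.population, config.iterations, config.n_dims
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    v_max = 0.2 * (hi - lo)
    X = _init_population(config, rng)
    V = rng.uniform(-v_max, v_max, size=(pop, d))
    f = _evaluate(objective, X)
    evals = pop
    p_best_x, p_best_f = X.copy(), f.copy()
    g = int(np.argmin(f))
    best_x, best_f = X[g].copy(), float(f[g])
    history: list[float] = []
    for _ in range(T):
        r1 = rng.uniform(size=(pop, d))
        r2 = rng.uniform(size=(pop, d))
        V = (
            inertia * V
            + cognitive * r1 * (p_best_x - X)
            + social * r2 * (best_x - X)
        )
        V = np.clip(V, -v_max, v_max)
        X = _clip_round(X + V, config)
        f = _evaluate(objective, X)
        evals += pop
        improved = f < p_best_f
        p_best_x[improved] = X[improved]
        p_best_f[improved] = f[improved]
        g = int(np.argmin(p_best_f))
        if p_best_f[g] < best_f:
            best_f = float(p_best_f[g])
            best_x = p_best_x[g].copy()
        history.append(best_f)
    return OptResult(best_x, best_f, history, evals)


def gwo_optimize(objective: Callable, config: SwarmConfig) -> OptResult:
    """Canonical grey wolf optimizer: each wolf moves toward the mean of
    encircling positions around the three best (alpha, beta, delta) with
    the exploration coefficient `a` decreasing linearly from 2 to 0."""
    rng = np.random.default_rng(config.seed)
    pop, T, d = config.population, config.iterations, config.n_dims
    X = _init_population(config, rng)
    f = _evaluate(objective, X)
    evals = pop
    order = np.argsort(f)
    leaders = X[order[: min(3, pop)]].copy()
    leader_f = f[order[: min(3, pop)]].copy()
    best_x, best_f = leaders[0].copy(), float(leader_f[0])
    history: list[float] = []
    for t in range(T):
        a = 2.0 * (1.0 - t / T)
        new_X = np.empty_like(X)
        for i in range(pop):
            targets = []
            for lead in leaders:
                r1 = rng.uniform(size=d)
                r2 = rng.uniform(size=d)
                A = 2 * a * r1 - a
                C = 2 * r2
                D = np.abs(C * lead - X[i])
                targets.append(lead - A * D)
            new_X[i] = np.mean(targets, axis=0)
        X = _clip_round(new_X, config)
        f = _evaluate(objective, X)
        evals += pop
        all_x = np.vstack([leaders, X])
        all_f = np.concatenate([leader_f, f])
        order = np.argsort(all_f)[: min(3, pop)]
        leaders = all_x[order].copy()
        leader_f = all_f[order].copy()
        if leader_f[0] < best_f:
            best_f = float(leader_f[0])
            best_x = leaders[0].copy()
        history.append(best_f)
    return OptResult(best_x, best_f, history, evals)


_ALGORITHMS = {
    "ssa": ssa_optimize,
    "pso": pso_optimize,
    "gwo": gwo_optimize,
}


def _inner_cv_accuracy(
    X: np.ndarray,
    labels: np.ndarray,
    hidden_sizes: tuple[int, ...],
    template: BPNNConfig,
    n_folds: int,
    seed: int,
) -> float:
    """Mean validation accuracy of a BPNN over an inner stratified split."""
    cfg = replace(template, input_dim=X.shape[1], hidden_sizes=hidden_sizes)
    codes = np.unique(labels, return_inverse=True)[1]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, va in skf.split(X, codes):
        model = train(init_model(cfg), X[tr], labels[tr])
        accs.append(accuracy(model, X[va], labels[va]))
    return float(np.mean(accs))


def optimize_bpnn_architecture(
    train_X: np.ndarray,
    train_labels: np.ndarray,
    algorithm: str = "ssa",
    node_bounds: Sequence[tuple[int, int]] = ((2, 64), (2, 64)),
    swarm: SwarmConfig | None = None,
    bpnn_template: BPNNConfig | None = None,
    eval_protocol: Callable[[tuple[int, ...]], float] | None = None,
    inner_folds: int = 3,
    initial_guess: Sequence[int] | None = None,
) -> tuple[tuple[int, ...], OptResult]:
    """Search hidden-layer node counts by swarm-optimizing CV accuracy.

    The objective handed to the optimizer is the negated mean validation
    accuracy of a BPNN with the candidate (integer) hidden sizes, estimated
    by ``eval_protocol`` (default: inner stratified k-fold on the training
    data with a fixed seed). Fitness values are cached per rounded
    architecture so identical candidates are never retrained.

    ``initial_guess`` warm-starts the search with an incumbent architecture:
    if the incumbent stays unbeaten under the objective, it is what the
    search returns.
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from "
                         f"{sorted(_ALGORITHMS)}")
    for lo, hi in node_bounds:
        if lo < 1:
            raise ValueError(
                f"node bounds must not permit 0 nodes (got low={lo})"
            )
        if int(lo) != lo or int(hi) != hi:
            raise ValueError("node bounds must be integers")
    train_X = np.asarray(train_X, dtype=float)
    train_labels = np.asarray(train_labels)
    swarm = swarm or SwarmConfig()
    swarm = swarm.with_(
        bounds=tuple((float(lo), float(hi)) for lo, hi in node_bounds),
        integer_dims=frozenset(range(len(node_bounds))),
    )
    template = bpnn_template or BPNNConfig(
        input_dim=train_X.shape[1],
        n_classes=len(set(train_labels.tolist())),
        seed=swarm.seed,
    )
    if eval_protocol is None:
        def eval_protocol(hidden_sizes: tuple[int, ...]) -> float:
            return _inner_cv_accuracy(
                train_X, train_labels, hidden_sizes, template,
                inner_folds, swarm.seed,
            )
    cache: dict[tuple[int, ...], float] = {}

    def objective(x: np.ndarray) -> float:
        sizes = tuple(int(round(v)) for v in x)
        if sizes not in cache:
            cache[sizes] = -eval_protocol(sizes)
        return cache[sizes]

    f_inc = None
    if initial_guess is not None:
        incumbent = tuple(int(v) for v in initial_guess)
        if len(incumbent) != len(node_bounds):
            raise ValueError("initial_guess length must match node_bounds")
        # evaluate the incumbent up front so best-so-far includes it
        f_inc = objective(np.array(incumbent, dtype=float))
    result = _ALGORITHMS[algorithm](objective, swarm)
    best_sizes = tuple(int(round(v)) for v in result.best_position)
    if f_inc is not None:
        history = [min(h, f_inc) for h in result.history]
        if f_inc <= result.best_fitness:
            result = OptResult(
                np.array(incumbent, dtype=float), f_inc, history,
                result.evaluations + 1,
            )
            best_sizes = incumbent
        else:
            result = OptResult(
                result.best_position, result.best_fitness, history,
                result.evaluations + 1,
            )
    return best_sizes, result
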