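"""Butterfly optimization algorithm, its chaotic variant, and DBN tuning.

Each candidate solution ("butterfly") emits fragrance f = c * I^a, where c
is the sensory modality, a the power exponent, and I the stimulus intensity
derived from its fitness. Per iteration every butterfly moves either
globally toward the swarm best,

    x' = x + s^2 * (g* - x) * f,

or locally along the difference of two random peers,

    x' = x + s^2 * (x_j - x_k) * f,

where the scalar s is a uniform random draw (plain BOA) or an iterate of a
chaotic map (CBOA). The exponent a ramps from a_start to a_final on a
sinusoidal schedule and c grows by 0.025 / (c * T_max) per iteration from
an initial 0.01. Moves are clipped to the search box and accepted greedily,
so the best-so-far trace is monotone non-increasing.

The tuning adapter decodes a position vector into a DBN configuration and
scores it with the stratified k-fold cross-validated classification error
rate (in percent), the fitness being minimised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from .dbn import DBNConfig, RBMTrainConfig, fit_dbn

_LOGISTIC_FIXED_POINTS = (0.0, 0.25, 0.5, 0.75, 1.0)


# ---------------------------------------------------------------------------
# primitives


def fragrance(intensity: float, c: float, a: float) -> float:
    """Perceived fragrance c * I^a (a=0: constant c; a=1: no absorption)."""
    if intensity < 0:
        raise ValueError("stimulus intensity must be non-negative")
    return c * intensity ** a


def update_a(t: int, config: "CBOAConfig") -> float:
    """Sinusoidal ramp from a_start to a_final over the iteration budget."""
    if not 0 <= t <= config.t_max:
        raise ValueError(f"iteration {t} outside [0, {config.t_max}]")
    s = np.sin(np.pi * config.mu * t / (2.0 * config.t_max))
    if config.a_schedule == "sin2":
        s = s * s
    return config.a_start - (config.a_start - config.a_final) * s


def update_c(c: float, t_max: int) -> float:
    """c + 0.025 / (c * T_max); strictly increasing for c > 0."""
    if c <= 0:
        raise ValueError("sensory modality c must be positive")
    return c + 0.025 / (c * t_max)


def logistic_map_next(x: float) -> float:
    """Chaotic logistic map 4 x (1 - x) on [0, 1]."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("logistic map state must lie in [0, 1]")
    return 4.0 * x * (1.0 - x)


CHAOTIC_MAPS = {"logistic": logistic_map_next, "none": None}


@dataclass
class Butterfly:
    x: np.ndarray
    fitness: float = np.inf
    intensity: float = 0.0
    fragrance: float = 0.0


@dataclass(frozen=True)
class CBOAConfig:
    pop_size: int = 10
    t_max: int = 50
    a_start: float = 0.1
    a_final: float = 0.3
    mu: float = 1.0
    c0: float = 0.01
    p_switch: float = 0.8
    chaotic_map: str = "logistic"        # key in CHAOTIC_MAPS or a callable
    chaos_x0: float = 0.7
    bounds: tuple = ((0.0, 1.0),)
    rng_seed: int = 0
    a_schedule: str = "sin"              # "sin" or the sin**2 alternative

    def __post_init__(self):
        if not 0.0 < self.p_switch < 1.0:
            raise ValueError("p_switch must lie strictly in (0, 1)")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        for lo, hi in self.bounds:
            if lo >= hi:
                raise ValueError("each bound must satisfy low < high")
        if (self.chaotic_map == "logistic"
                and self.chaos_x0 in _LOGISTIC_FIXED_POINTS):
            raise ValueError(
                "chaos_x0 must avoid the logistic map's fixed points")
        if self.a_schedule not in ("sin", "sin2"):
            raise ValueError("a_schedule must be 'sin' or 'sin2'")

    def map_fn(self):
        if callable(self.chaotic_map):
            return self.chaotic_map
        try:
            return CHAOTIC_MAPS[self.chaotic_map]
        except KeyError:
            raise ValueError(f"unknown chaotic map {self.chaotic_map!r}")


def _clip(x, bounds):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def global_move(b: Butterfly, g_best: np.ndarray, s: float,
                bounds) -> np.ndarray:
    """x + s^2 (g* - x) f, clipped to the search box."""
    if b.x.shape != np.shape(g_best):
        raise ValueError("dimension mismatch between butterfly and g*")
    return _clip(b.x + s * s * (np.asarray(g_best) - b.x) * b.fragrance, bounds)


def local_move(b: Butterfly, x_j: np.ndarray, x_k: np.ndarray, s: float,
               bounds) -> np.ndarray:
    """x + s^2 (x_j - x_k) f, clipped to the search box."""
    return _clip(b.x + s * s * (np.asarray(x_j) - np.asarray(x_k))
                 * b.fragrance, bounds)


# ---------------------------------------------------------------------------
# the optimiser


def default_intensity(fitness: float) -> float:
    """Stimulus intensity for minimisation: better fitness, stronger smell."""
    return 1.0 / (1.0 + max(fitness, 0.0))


@dataclass
class OptimizeResult:
    best_x: np.ndarray
    best_fitness: float
    trace: pd.DataFrame          # iteration, best_fitness, mean_fitness, a, c
    population: list = field(default_factory=list)


def optimize(objective, config: CBOAConfig,
             intensity_fn=default_intensity) -> OptimizeResult:
    """Minimise ``objective`` over the bounded box.

    Greedy per-butterfly acceptance (ties keep the incumbent) guarantees a
    monotone best-so-far trace. With chaotic_map="none" the scalar s in each
    move is a fresh uniform draw (plain BOA); otherwise each butterfly owns
    an independent chaotic stream.
    """
    if config.pop_size < 2:
        raise ValueError("need at least two butterflies")
    rng = np.random.default_rng(config.rng_seed)
    dim = len(config.bounds)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])

    def evaluate(x, t):
        val = float(objective(np.asarray(x)))
        if not np.isfinite(val):
            raise ValueError(f"objective returned non-finite value at "
                             f"iteration {t}: {val}")
        return val

    pop = []
    for i in range(config.pop_size):
        x = rng.uniform(lo, hi, size=dim)
        pop.append(Butterfly(x=x, fitness=evaluate(x, 0)))

    map_fn = config.map_fn()
    chaos = None
    if map_fn is not None:
        # independent stream per butterfly: warm up the shared seed i+1 times
        chaos = []
        for i in range(config.pop_size):
            s = config.chaos_x0
            for _ in range(i + 1):
                s = map_fn(s)
            chaos.append(s)

    best_i = int(np.argmin([b.fitness for b in pop]))
    g_best = pop[best_i].x.copy()
    best_fitness = pop[best_i].fitness
    c = config.c0
    rows = []

    for t in range(1, config.t_max + 1):
        a = update_a(t, config)
        c = update_c(c, config.t_max)
        for b in pop:
            b.intensity = intensity_fn(b.fitness)
            b.fragrance = fragrance(b.intensity, c, a)
        for i, b in enumerate(pop):
            if map_fn is not None:
                chaos[i] = map_fn(chaos[i])
                s = chaos[i]
            else:
                s = rng.random()
            if rng.random() < config.p_switch:
                x_new = global_move(b, g_best, s, config.bounds)
            else:
                j, k = rng.choice(config.pop_size, size=2, replace=False)
                x_new = local_move(b, pop[j].x, pop[k].x, s, config.bounds)
            f_new = evaluate(x_new, t)
            if f_new < b.fitness:       # ties keep the incumbent
                b.x, b.fitness = x_new, f_new
            if b.fitness < best_fitness:
                best_fitness = b.fitness
                g_best = b.x.copy()
        rows.append({"iteration": t, "best_fitness": best_fitness,
                     "mean_fitness": float(np.mean([p.fitness for p in pop])),
                     "a": a, "c": c})

    return OptimizeResult(best_x=g_best, best_fitness=best_fitness,
                          trace=pd.DataFrame(rows), population=pop)


# ---------------------------------------------------------------------------
# DBN hyperparameter tuning


@dataclass
class FitnessResult:
    error_rate_percent: float
    n_misclassified: int
    n_total: int
    fold_errors: list[int] = field(default_factory=list)


# position layout: (log10 RBM lr, hidden-1 width, hidden-2 width,
#                   pretrain epochs, log10 fine-tune lr)
DEFAULT_HYPERPARAM_BOUNDS = (
    (-4.0, -1.0),
    (16.0, 512.0),
    (8.0, 256.0),
    (5.0, 50.0),
    (-4.0, -1.0),
)


def decode_position(x, bounds=DEFAULT_HYPERPARAM_BOUNDS, seed: int = 0,
                    finetune_epochs: int = 40) -> DBNConfig:
    """Map a position vector to a DBN configuration (nearest-integer widths)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(bounds),):
        raise ValueError(f"position must have {len(bounds)} dimensions")
    for xi, (lo, hi) in zip(x, bounds):
        if not lo <= xi <= hi:
            raise ValueError(f"position component {xi} outside [{lo}, {hi}]")
    return DBNConfig(
        layer_sizes=(int(round(x[1])), int(round(x[2]))),
        rbm_train=RBMTrainConfig(epsilon=10.0 ** x[0],
                                 epochs=int(round(x[3])), seed=seed),
        finetune_lr=10.0 ** x[4],
        finetune_epochs=finetune_epochs,
        seed=seed,
    )


def fitness_error_rate(position, features, labels, k_folds: int = 5,
                       seed: int = 0, bounds=DEFAULT_HYPERPARAM_BOUNDS,
                       train_predict=None) -> FitnessResult:
    """Cross-validated classification error rate in percent.

    Pools misclassifications over stratified folds and returns
    100 * misclassified / total. ``train_predict(x_tr, y_tr, x_te, cfg)``
    may replace the default pretrain+finetune+predict classifier (used by
    tests with stub classifiers).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    cfg = decode_position(position, bounds=bounds, seed=seed)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_errors = []
    for tr, te in skf.split(x, y):
        if train_predict is not None:
            pred = train_predict(x[tr], y[tr], x[te], cfg)
        else:
            clf = fit_dbn(x[tr], y[tr], cfg)
            pred = clf.predict(x[te])
        fold_errors.append(int((np.asarray(pred) != y[te]).sum()))
    n_mis = int(sum(fold_errors))
    return FitnessResult(error_rate_percent=100.0 * n_mis / len(y),
                         n_misclassified=n_mis, n_total=len(y),
                         fold_errors=fold_errors)


def tune_dbn(features, labels, config: CBOAConfig | None = None,
             k_folds: int = 5, bounds=DEFAULT_HYPERPARAM_BOUNDS,
             train_predict=None):
    """CBOA search over the DBN hyperparameter box.

    Returns (best DBNConfig, FitnessResult of the best position, trace).
    The greedy optimizer guarantees the returned cross-validated error is
    no worse than the best initial-population error.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("tuning requires both classes present")
    if config is None:
        config = CBOAConfig(pop_size=6, t_max=5, bounds=bounds)
    elif config.bounds != bounds:
        config = CBOAConfig(**{**config.__dict__, "bounds": bounds})

    cache: dict[tuple, float] = {}

    def objective(x):
        key = tuple(np.round(x, 12))
        if key not in cache:
            cache[key] = fitness_error_rate(
                x, features, labels, k_folds=k_folds, seed=config.rng_seed,
                bounds=bounds, train_predict=train_predict).error_rate_percent
        return cache[key]

    result = optimize(objective, config)
    best_cfg = decode_position(result.best_x, bounds=bounds,
                               seed=config.rng_seed)
    best_fit = fitness_error_rate(result.best_x, features, labels,
                                  k_folds=k_folds, seed=config.rng_seed,
                                  bounds=bounds, train_predict=train_predict)
    return best_cfg, best_fit, result.trace


# ---------------------------------------------------------------------------
# YAML config round-trip


def config_to_yaml(config: CBOAConfig, path: str) -> None:
    d = dict(config.__dict__)
    d["bounds"] = [list(b) for b in config.bounds]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def config_from_yaml(path: str) -> CBOAConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["bounds"] = tuple(tuple(b) for b in d["bounds"])
    return CBOAConfig(**d)
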