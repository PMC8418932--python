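"""Binary metaheuristic wrapper feature selection.

Six population-based selectors operate on binary masks over the feature
set (bit 1 = feature kept): the binary bat algorithm (BBA), binary
differential evolution (BDE), the firefly algorithm (FA), a genetic
algorithm (GA), binary grey wolf optimization (GWO) and binary particle
swarm optimization (PSO).  All share one fitness interface — typically a
classifier's cross-validated accuracy on the masked features — and return
the best mask encountered, with an elitist best-so-far history.

Continuous velocities/positions are mapped to bits through a sigmoid
transfer: a bit is set when a uniform draw falls below S(v) = 1/(1+e^-v)
(GWO uses the steeper transfer T(x) = 1/(1+e^{-10(x-0.5)}) centered on
0.5).  Candidate masks that come out all-zero are repaired by setting one
uniformly random bit, since a classifier cannot be fit on zero features.
Ties on fitness prefer fewer selected features (the stated goal of
selection being lower model complexity).

An exhaustive-search oracle over all non-empty masks (dimension <= 20) is
provided for validating the metaheuristics on small landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "FitnessContext",
    "SelectionResult",
    "MetaheuristicConfig",
    "sigmoid_binarize",
    "select_bba",
    "select_bde",
    "select_fa",
    "select_ga",
    "select_gwo",
    "select_pso",
    "exhaustive_oracle",
    "run_selector",
    "SELECTOR_METHODS",
]


@dataclass
class FitnessContext:
    """A fitness landscape over binary feature masks (maximized)."""

    evaluate: Callable[[np.ndarray], float]
    dimension: int

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be positive")


@dataclass
class SelectionResult:
    """Outcome of one selector run."""

    method: str
    mask: np.ndarray
    best_fitness: float
    history: list[float]
    n_selected: int
    seed: int
    n_evaluations: int = 0

    def to_dict(self, feature_names: list[str] | None = None) -> dict:
        out = {
            "method": self.method,
            "seed": self.seed,
            "mask": [int(b) for b in self.mask],
            "best_fitness": float(self.best_fitness),
            "history": [float(h) for h in self.history],
            "n_selected": int(self.n_selected),
            "n_evaluations": int(self.n_evaluations),
        }
        if feature_names is not None:
            out["selected_features"] = [
                n for n, b in zip(feature_names, self.mask) if b
            ]
        return out


def sigmoid_binarize(v: float, rho: float) -> int:
    """Map a continuous value to a bit: 1 iff rho <= S(v) = 1/(1+e^-v)."""
    return int(rho <= 1.0 / (1.0 + np.exp(-v)))


def _binarize_vector(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-v))
    return (rng.random(v.shape) <= s).astype(np.uint8)


class _Tracker:
    """Evaluation bookkeeping: mask repair, memoization, elitist best.

    Fitness functions are deterministic for a fixed run seed, so repeated
    masks are served from a cache (wrapper fitness is the dominant cost).
    """

    def __init__(self, ctx: FitnessContext, rng: np.random.Generator):
        self.ctx = ctx
        self.rng = rng
        self.best_mask: np.ndarray | None = None
        self.best_fit = -np.inf
        self.history: list[float] = []
        self.n_evaluations = 0
        self._cache: dict[bytes, float] = {}

    def repair(self, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask, dtype=np.uint8).copy()
        if mask.sum() == 0:
            mask[self.rng.integers(self.ctx.dimension)] = 1
        return mask

    def evaluate(self, mask: np.ndarray) -> tuple[np.ndarray, float]:
        mask = self.repair(mask)
        key = mask.tobytes()
        if key in self._cache:
            fit = self._cache[key]
        else:
            fit = float(self.ctx.evaluate(mask))
            self._cache[key] = fit
            self.n_evaluations += 1
        better = fit > self.best_fit or (
            fit == self.best_fit
            and self.best_mask is not None
            and mask.sum() < self.best_mask.sum()
        )
        if better:
            self.best_fit = fit
            self.best_mask = mask.copy()
        return mask, fit

    def close_iteration(self) -> None:
        self.history.append(self.best_fit)

    def result(self, method: str, seed: int) -> SelectionResult:
        assert self.best_mask is not None, "no candidate was ever evaluated"
        return SelectionResult(
            method=method,
            mask=self.best_mask,
            best_fitness=self.best_fit,
            history=list(self.history),
            n_selected=int(self.best_mask.sum()),
            seed=seed,
            n_evaluations=self.n_evaluations,
        )


def _init_population(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    # each bit Bernoulli(1/2) under the run seed
    return rng.integers(0, 2, size=(n, d), dtype=np.uint8)


def select_bba(
    ctx: FitnessContext,
    population: int = 4,
    iterations: int = 40,
    loudness: float = 1.0,
    pulse_rate: float = 0.5,
    alpha_loud: float = 1.0,
    gamma: float = 0.9,
    f_min: float = 0.0,
    f_max: float = 2.0,
    seed: int = 0,
) -> SelectionResult:
    """Binary bat algorithm.

    Each bat carries a continuous velocity and a binary position.  Per
    iteration a random pulse frequency ``f = f_min + (f_min - f_max)*beta``
    (beta uniform in [0,1]) scales the pull toward the global best,
    ``v += (x - gbest)*f``; with probability ``1 - pulse_rate`` a local walk
    perturbs the velocity by ``eps * mean loudness`` (eps uniform in
    [-1,1]); bits are drawn through the sigmoid transfer.  A candidate is
    accepted into the bat's position when a draw falls below its loudness
    and the candidate is at least as fit; loudness then decays by
    ``alpha_loud`` and the pulse rate grows as ``r0*(1 - e^{-gamma*t})``.
    With ``alpha_loud = 1`` the loudness schedule is constant (the default
    operating point).
    """
    if population < 2 or iterations < 1:
        raise ValueError("population >= 2 and iterations >= 1 required")
    rng = np.random.default_rng(seed)
    d = ctx.dimension
    tracker = _Tracker(ctx, rng)

    x = _init_population(population, d, rng)
    v = np.zeros((population, d))
    A = np.full(population, float(loudness))
    r = np.full(population, pulse_rate * (1.0 - np.exp(-gamma)))
    fits = np.empty(population)
    for i in range(population):
        x[i], fits[i] = tracker.evaluate(x[i])
    tracker.close_iteration()

    for t in range(1, iterations + 1):
        a_mean = A.mean()
        gbest = tracker.best_mask.astype(float)
        for i in range(population):
            beta = rng.random()
            f = f_min + (f_min - f_max) * beta
            v[i] = v[i] + (x[i].astype(float) - gbest) * f
            if rng.random() > r[i]:
                v_cand = v[i] + rng.uniform(-1.0, 1.0, d) * a_mean
            else:
                v_cand = v[i]
            cand = _binarize_vector(v_cand, rng)
            cand, fit = tracker.evaluate(cand)
            if rng.random() < A[i] and fit >= fits[i]:
                x[i] = cand
                fits[i] = fit
                v[i] = v_cand
                A[i] *= alpha_loud
                r[i] = pulse_rate * (1.0 - np.exp(-gamma * (t + 1)))
        tracker.close_iteration()
    return tracker.result("BBA", seed)


def select_bde(
    ctx: FitnessContext,
    population: int = 10,
    iterations: int = 100,
    cr: float = 0.9,
    seed: int = 0,
) -> SelectionResult:
    """Binary differential evolution.

    For each target vector, three distinct donors r1, r2, r3 are drawn; the
    difference vector is 0 where X_r1 == X_r2 and X_r1 elsewhere; the
    mutant takes 1 where the difference is 1 and X_r3 otherwise.  Binomial
    crossover with rate ``cr`` (one uniformly chosen coordinate always
    inherited from the mutant) forms the trial, which replaces its parent
    when at least as fit.
    """
    if population < 4:
        raise ValueError("BDE needs population >= 4 (three donors distinct from i)")
    if iterations < 1:
        raise ValueError("iterations >= 1 required")
    rng = np.random.default_rng(seed)
    d = ctx.dimension
    tracker = _Tracker(ctx, rng)

    x = _init_population(population, d, rng)
    fits = np.empty(population)
    for i in range(population):
        x[i], fits[i] = tracker.evaluate(x[i])
    tracker.close_iteration()

    for _ in range(iterations):
        for i in range(population):
            others = [k for k in range(population) if k != i]
            r1, r2, r3 = rng.choice(others, size=3, replace=False)
            diff = np.where(x[r1] == x[r2], 0, x[r1]).astype(np.uint8)
            mutant = np.where(diff == 1, 1, x[r3]).astype(np.uint8)
            cross = rng.random(d) <= cr
            cross[rng.integers(d)] = True
            trial = np.where(cross, mutant, x[i]).astype(np.uint8)
            trial, fit = tracker.evaluate(trial)
            if fit >= fits[i]:
                x[i] = trial
                fits[i] = fit
        tracker.close_iteration()
    return tracker.result("BDE", seed)


def select_fa(
    ctx: FitnessContext,
    population: int = 6,
    iterations: int = 100,
    alpha: float = 0.5,
    gamma: float = 0.0,
    beta0: float = 1.0,
    seed: int = 0,
) -> SelectionResult:
    """Binary firefly algorithm.

    A firefly moves toward every brighter one with attractiveness
    ``beta0 * exp(-gamma * r^2)`` (r the Cartesian distance between the
    bit vectors) plus a zero-mean random term ``alpha*(rand - 1/2)``; the
    moved coordinates are mapped back to bits with the sigmoid transfer.
    With ``gamma = 0`` attractiveness does not decay with distance (the
    default operating point).
    """
    if population < 2 or iterations < 1:
        raise ValueError("population >= 2 and iterations >= 1 required")
    rng = np.random.default_rng(seed)
    d = ctx.dimension
    tracker = _Tracker(ctx, rng)

    x = _init_population(population, d, rng)
    fits = np.empty(population)
    for i in range(population):
        x[i], fits[i] = tracker.evaluate(x[i])
    tracker.close_iteration()

    for _ in range(iterations):
        new_x = x.copy()
        new_fits = fits.copy()
        for i in range(population):
            xi = x[i].astype(float)
            attracted = False
            for j in range(population):
                if fits[j] > fits[i]:
                    r2 = float(np.sum((x[i].astype(float) - x[j]) ** 2))
                    beta = beta0 * np.exp(-gamma * r2)
                    xi = xi + beta * (x[j] - xi) + alpha * (rng.random(d) - 0.5)
                    attracted = True
            if not attracted:  # brightest firefly: pure random walk
                xi = xi + alpha * (rng.random(d) - 0.5)
            cand = (rng.random(d) <= 1.0 / (1.0 + np.exp(-xi))).astype(np.uint8)
            cand, fit = tracker.evaluate(cand)
            new_x[i] = cand
            new_fits[i] = fit
        x, fits = new_x, new_fits
        tracker.close_iteration()
    return tracker.result("FA", seed)


def select_ga(
    ctx: FitnessContext,
    population: int = 10,
    iterations: int = 100,
    cr: float = 0.8,
    mr: float = 0.01,
    seed: int = 0,
) -> SelectionResult:
    """Genetic algorithm: roulette selection, single-point crossover
    (probability ``cr``), per-bit mutation (probability ``mr``), and
    elitism of the best chromosome each generation."""
    if population < 2 or iterations < 1:
        raise ValueError("population >= 2 and iterations >= 1 required")
    rng = np.random.default_rng(seed)
    d = ctx.dimension
    tracker = _Tracker(ctx, rng)

    pop = _init_population(population, d, rng)
    fits = np.empty(population)
    for i in range(population):
        pop[i], fits[i] = tracker.evaluate(pop[i])
    tracker.close_iteration()

    def roulette() -> int:
        w = fits - fits.min()
        total = w.sum()
        if total <= 0:
            return int(rng.integers(population))
        return int(rng.choice(population, p=w / total))

    for _ in range(iterations):
        children = [tracker.best_mask.copy()]  # elitism
        while len(children) < population:
            p1, p2 = pop[roulette()], pop[roulette()]
            if rng.random() < cr and d >= 2:
                cut = int(rng.integers(1, d))
                c1 = np.concatenate([p1[:cut], p2[cut:]])
                c2 = np.concatenate([p2[:cut], p1[cut:]])
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                flip = rng.random(d) < mr
                child[flip] ^= 1
                if len(children) < population:
                    children.append(child.astype(np.uint8))
        for i, child in enumerate(children):
            pop[i], fits[i] = tracker.evaluate(child)
        tracker.close_iteration()
    return tracker.result("GA", seed)


def _gwo_transfer(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-10.0 * (x - 0.5)))


def select_gwo(
    ctx: FitnessContext,
    population: int = 10,
    iterations: int = 100,
    seed: int = 0,
) -> SelectionResult:
    """Binary grey wolf optimizer.

    Wolves carry continuous positions in [0,1]^d.  The three fittest
    (alpha, beta, delta) steer every wolf: with the exploration scalar
    ``a`` decaying linearly 2 -> 0, each leader contributes a candidate
    ``X_k = leader - A*|C*leader - x|`` (A = 2a*r1 - a, C = 2*r2), and the
    new position is the mean of the three.  Bits are drawn through the
    steep transfer T(x) = 1/(1+e^{-10(x-0.5)}).
    """
    if population < 3:
        raise ValueError("GWO needs population >= 3 (alpha/beta/delta leaders)")
    if iterations < 1:
        raise ValueError("iterations >= 1 required")
    rng = np.random.default_rng(seed)
    d = ctx.dimension
    tracker = _Tracker(ctx, rng)

    pos = rng.random((population, d))
    fits = np.empty(population)
    for i in range(population):
        mask = (rng.random(d) <= _gwo_transfer(pos[i])).astype(np.uint8)
        _, fits[i] = tracker.evaluate(mask)
    tracker.close_iteration()

    for t in range(iterations):
        a = 2.0 * (1.0 - t / iterations)
        order = np.argsort(-fits)
        leaders = pos[order[:3]]
        for i in range(population):
            cand = np.zeros(d)
            for leader in leaders:
                A = 2.0 * a * rng.random(d) - a
                C = 2.0 * rng.random(d)
                D = np.abs(C * leader - pos[i])
                cand += leader - A * D
            pos[i] = np.clip(cand / 3.0, 0.0, 1.0)
            mask = (rng.random(d) <= _gwo_transfer(pos[i])).astype(np.uint8)
            _, fits[i] = tracker.evaluate(mask)
        tracker.close_iteration()
    return tracker.result("GWO", seed)


def select_pso(
    ctx: FitnessContext,
    population: int = 10,
    iterations: int = 100,
    c1: float = 2.0,
    c2: float = 2.0,
    w_min: float = 0.4,
    w_max: float = 0.9,
    v_max: float = 6.0,
    seed: int = 0,
) -> SelectionResult:
    """Binary particle swarm optimization.

    Velocity update ``v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)``
    with the inertia ``w`` annealed linearly from ``w_max`` to ``w_min``
    and velocities clamped to [-v_max, v_max]; positions are redrawn
    through the sigmoid transfer each iteration.
    """
    if population < 2 or iterations < 1:
        raise ValueError("population >= 2 and iterations >= 1 required")
    rng = np.random.default_rng(seed)
    d = ctx.dimension
    tracker = _Tracker(ctx, rng)

    x = _init_population(population, d, rng)
    v = np.zeros((population, d))
    fits = np.empty(population)
    for i in range(population):
        x[i], fits[i] = tracker.evaluate(x[i])
    pbest = x.copy().astype(float)
    pfits = fits.copy()
    tracker.close_iteration()

    for t in range(iterations):
        if iterations > 1:
            w = w_max - (w_max - w_min) * t / (iterations - 1)
        else:
            w = w_max
        gbest = tracker.best_mask.astype(float)
        for i in range(population):
            r1 = rng.random(d)
            r2 = rng.random(d)
            v[i] = (
                w * v[i]
                + c1 * r1 * (pbest[i] - x[i])
                + c2 * r2 * (gbest - x[i])
            )
            np.clip(v[i], -v_max, v_max, out=v[i])
            x[i] = _binarize_vector(v[i], rng)
            x[i], fit = tracker.evaluate(x[i])
            if fit > pfits[i] or (fit == pfits[i] and x[i].sum() < pbest[i].sum()):
                pbest[i] = x[i].astype(float)
                pfits[i] = fit
        tracker.close_iteration()
    return tracker.result("PSO", seed)


def exhaustive_oracle(ctx: FitnessContext) -> SelectionResult:
    """Global optimum by enumeration of every non-empty mask (d <= 20).

    Ties break toward fewer selected features, then the lexicographically
    smallest mask.
    """
    d = ctx.dimension
    if d > 20:
        raise ValueError(f"exhaustive search refused for dimension {d} > 20")
    best_mask = None
    best_key = None
    history = []
    n_eval = 0
    for m in range(1, 1 << d):
        mask = np.array([(m >> k) & 1 for k in range(d)], dtype=np.uint8)
        fit = float(ctx.evaluate(mask))
        n_eval += 1
        key = (-fit, int(mask.sum()), tuple(mask))
        if best_key is None or key < best_key:
            best_key = key
            best_mask = mask
        history.append(-best_key[0])
    return SelectionResult(
        method="exhaustive",
        mask=best_mask,
        best_fitness=-best_key[0],
        history=history,
        n_selected=int(best_mask.sum()),
        seed=0,
        n_evaluations=n_eval,
    )


SELECTOR_METHODS: dict[str, Callable[..., SelectionResult]] = {
    "bba": select_bba,
    "bde": select_bde,
    "fa": select_fa,
    "ga": select_ga,
    "gwo": select_gwo,
    "pso": select_pso,
}


@dataclass
class MetaheuristicConfig:
    """Method name plus overrides of that method's keyword defaults."""

    method: str
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method.lower() not in SELECTOR_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; "
                f"choose from {sorted(SELECTOR_METHODS)}"
            )


def run_selector(ctx: FitnessContext, cfg: MetaheuristicConfig) -> SelectionResult:
    """Dispatch a selector run from a :class:`MetaheuristicConfig`."""
    func = SELECTOR_METHODS[cfg.method.lower()]
    return func(ctx, seed=cfg.seed, **cfg.overrides)
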