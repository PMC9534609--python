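"""Squirrel search algorithm (SSA) for continuous bounded minimisation.

The population model mimics flying squirrels foraging between three kinds
of trees: the single best individual sits on the hickory tree, the next
best few on acorn trees, the rest on normal trees.  Acorn squirrels glide
toward the hickory squirrel and normal squirrels toward a random acorn
squirrel, with a gliding distance derived from aerodynamic drag and lift:

    dg = hg / (tan(phi) * sf),   tan(phi) = D_drag / L_lift = C_D / C_L,

where C_L is drawn uniformly in [0.675, 1.5] each glide, giving
dg in [0.5, 8/(0.4*18)] ~= [0.5, 1.1111].  With probability P_dp a glide
is interrupted by a predator and the squirrel relocates uniformly at
random.  A seasonal check compares each acorn squirrel's squared distance
to the hickory squirrel against a decaying threshold; when all fall below
it (winter ends), normal squirrels that escaped predators this iteration
relocate by a heavy-tailed Levy flight, restoring exploration.

An elite opposition-based learning hook (see :mod:`heartsel.eobl`) can be
applied once per iteration between the gliding updates and role re-ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SSAConfig",
    "Population",
    "SeasonState",
    "OptimizeResult",
    "init_population",
    "gliding_distance",
    "levy_sigma",
    "levy_step",
    "update_toward_hickory",
    "update_toward_acorn",
    "seasonal_constant",
    "seasonal_threshold",
    "relocate_random",
    "step",
    "optimize",
]

HICKORY, ACORN, NORMAL = "hickory", "acorn", "normal"

Objective = Callable[[np.ndarray], float]


@dataclass
class SSAConfig:
    """Search-space geometry and the algorithm's physical constants.

    The aerodynamic constants (air density rho, speed V, surface S, drag
    coefficient C_D, lift coefficient range C_L_range) only enter through
    the ratio C_D/C_L, so the gliding distance is dg = hg*C_L/(C_D*sf).
    """

    N: int = 30
    D: int = 2
    FS_L: float | Sequence[float] = 0.0
    FS_U: float | Sequence[float] = 1.0
    T: int = 100
    G_c: float = 1.9
    P_dp: float = 0.1
    hg: float = 8.0
    sf: float = 18.0
    rho: float = 1.204
    V: float = 5.25
    S: float = 154.0
    C_D: float = 0.6
    C_L_range: tuple[float, float] = (0.675, 1.5)
    levy_beta: float = 1.5
    n_hickory: int = 1
    n_acorn: int = 3
    seed: int = 0
    normal_to_hickory: bool = False  # optional third update rule
    sc_sqrt: bool = False  # seasonal constant as distance instead of squared

    def __post_init__(self) -> None:
        self.lower = np.broadcast_to(
            np.asarray(self.FS_L, dtype=float), (self.D,)
        ).copy()
        self.upper = np.broadcast_to(
            np.asarray(self.FS_U, dtype=float), (self.D,)
        ).copy()
        if np.any(self.lower > self.upper):
            raise ValueError("FS_L must be <= FS_U elementwise")
        if self.N < self.n_hickory + self.n_acorn:
            raise ValueError("N must be >= n_hickory + n_acorn")
        if not 0.0 <= self.P_dp <= 1.0:
            raise ValueError("P_dp must lie in [0, 1]")
        for name in ("G_c", "hg", "sf", "rho", "V", "S", "C_D", "levy_beta", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Population:
    """Positions, cached fitnesses and tree roles of the N squirrels."""

    positions: np.ndarray  # (N, D)
    fitness: np.ndarray  # (N,)
    roles: np.ndarray  # (N,) of {hickory, acorn, normal}

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))

    def indices_with_role(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)


@dataclass
class SeasonState:
    season: str = "winter"
    S_c: np.ndarray = field(default_factory=lambda: np.empty(0))
    S_min: float = float("nan")


def _evaluate(objective: Objective, position: np.ndarray) -> float:
    value = float(objective(position))
    if not math.isfinite(value):
        raise ValueError(f"objective returned non-finite value at {position!r}")
    return value


def assign_roles(fitness: np.ndarray, n_hickory: int, n_acorn: int) -> np.ndarray:
    """Rank-based tree roles: best n_hickory hickory, next n_acorn acorn."""
    roles = np.full(fitness.shape[0], NORMAL, dtype=object)
    order = np.argsort(fitness, kind="stable")
    roles[order[:n_hickory]] = HICKORY
    roles[order[n_hickory : n_hickory + n_acorn]] = ACORN
    return roles


def init_population(cfg: SSAConfig, objective: Objective, rng: np.random.Generator) -> Population:
    """Uniform initial positions in [FS_L, FS_U]; fitnesses and roles set."""
    positions = cfg.lower + rng.random((cfg.N, cfg.D)) * (cfg.upper - cfg.lower)
    fitness = np.array([_evaluate(objective, p) for p in positions])
    return Population(positions, fitness, assign_roles(fitness, cfg.n_hickory, cfg.n_acorn))


def gliding_distance(cfg: SSAConfig, rng: np.random.Generator) -> float:
    """One glide's distance: dg = hg/(tan(phi)*sf) with C_L ~ U(C_L_range)."""
    c_lo, c_hi = cfg.C_L_range
    C_L = c_lo + rng.random() * (c_hi - c_lo)
    tan_phi = cfg.C_D / C_L  # (0.5*rho*V^2*S) cancels between drag and lift
    return cfg.hg / (tan_phi * cfg.sf)


def levy_sigma(beta: float) -> float:
    """Scale of the heavy-tailed step generator (Mantegna's construction)."""
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(D: int, cfg: SSAConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-coordinate step 0.01 * ra*sigma/|rb|^(1/beta), ra, rb ~ N(0,1)."""
    beta = cfg.levy_beta
    sigma = levy_sigma(beta)
    ra = rng.standard_normal(D)
    rb = rng.standard_normal(D)
    return 0.01 * ra * sigma / np.abs(rb) ** (1.0 / beta)


def _clamp(position: np.ndarray, cfg: SSAConfig) -> np.ndarray:
    return np.clip(position, cfg.lower, cfg.upper)


def _glide_update(
    position: np.ndarray,
    target: np.ndarray,
    cfg: SSAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Shared gliding rule; returns (new position, predator met?)."""
    r = rng.random()
    if r > cfg.P_dp:
        dg = gliding_distance(cfg, rng)
        new = position + dg * cfg.G_c * (target - position)
        return _clamp(new, cfg), False
    new = cfg.lower + rng.random(cfg.D) * (cfg.upper - cfg.lower)
    return new, True


def update_toward_hickory(
    position: np.ndarray, hickory: np.ndarray, cfg: SSAConfig, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Acorn-squirrel move toward the hickory squirrel."""
    return _glide_update(position, hickory, cfg, rng)


def update_toward_acorn(
    position: np.ndarray, acorn: np.ndarray, cfg: SSAConfig, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Normal-squirrel move toward a (caller-chosen) acorn squirrel."""
    return _glide_update(position, acorn, cfg, rng)


def seasonal_constant(
    acorn_position: np.ndarray, hickory_position: np.ndarray, sqrt: bool = False
) -> float:
    """Squared Euclidean distance acorn->hickory (distance if sqrt=True)."""
    s = float(np.sum((np.asarray(acorn_position) - np.asarray(hickory_position)) ** 2))
    return math.sqrt(s) if sqrt else s


def seasonal_threshold(t: int, T: int) -> float:
    """Decaying winter-end threshold S_min = 1e-5 / 365^(t / (T/2.5))."""
    if T <= 0:
        raise ValueError("T must be positive")
    return 1e-5 / 365.0 ** (t / (T / 2.5))


def relocate_random(cfg: SSAConfig, rng: np.random.Generator) -> np.ndarray:
    """Levy-flight relocation FS_L + Levy * (FS_U - FS_L), clamped."""
    return _clamp(cfg.lower + levy_step(cfg.D, cfg, rng) * (cfg.upper - cfg.lower), cfg)


def step(
    population: Population,
    season: SeasonState,
    t: int,
    cfg: SSAConfig,
    objective: Objective,
    rng: np.random.Generator,
    post_update_hook: Callable[[Population], Population] | None = None,
) -> tuple[Population, SeasonState]:
    """One SSA iteration: glides, optional hook, re-ranking, seasonal check."""
    pos = population.positions
    predator_met = np.zeros(cfg.N, dtype=bool)
    hickory_pos = pos[population.indices_with_role(HICKORY)[0]].copy()
    acorn_idx = population.indices_with_role(ACORN)

    for i in population.indices_with_role(ACORN):
        pos[i], predator_met[i] = update_toward_hickory(pos[i], hickory_pos, cfg, rng)
    for i in population.indices_with_role(NORMAL):
        if cfg.normal_to_hickory and rng.random() < 0.5:
            target = hickory_pos
        else:
            target = pos[acorn_idx[rng.integers(len(acorn_idx))]] if len(acorn_idx) else hickory_pos
        pos[i], predator_met[i] = update_toward_acorn(pos[i], target, cfg, rng)

    population.fitness = np.array([_evaluate(objective, p) for p in pos])

    if post_update_hook is not None:
        population = post_update_hook(population)

    population.roles = assign_roles(population.fitness, cfg.n_hickory, cfg.n_acorn)

    # seasonal monitoring: winter ends when every acorn squirrel is close
    # (in squared distance) to the hickory squirrel
    hickory_now = population.positions[population.indices_with_role(HICKORY)[0]]
    s_c = np.array(
        [
            seasonal_constant(population.positions[i], hickory_now, sqrt=cfg.sc_sqrt)
            for i in population.indices_with_role(ACORN)
        ]
    )
    s_min = seasonal_threshold(t, cfg.T)
    season = SeasonState(season=season.season, S_c=s_c, S_min=s_min)
    if season.season == "winter" and s_c.size and np.all(s_c < s_min):
        season.season = "summer"
        for i in population.indices_with_role(NORMAL):
            if not predator_met[i]:
                population.positions[i] = relocate_random(cfg, rng)
                population.fitness[i] = _evaluate(objective, population.positions[i])
        population.roles = assign_roles(population.fitness, cfg.n_hickory, cfg.n_acorn)
    return population, season


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness, length T+1

    def trace_csv(self, path) -> None:
        import csv as _csv

        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["iteration", "best_fitness"])
            for i, v in enumerate(self.trace):
                w.writerow([i, repr(float(v))])


def optimize(
    objective: Objective,
    cfg: SSAConfig,
    post_update_hook: Callable[[Population], Population] | None = None,
    rng: np.random.Generator | None = None,
) -> OptimizeResult:
    """Run init + T iterations with elitism; returns best and its trace.

    The best-so-far solution is retained: if an iteration loses it, the
    worst individual is overwritten with the stored elite before roles are
    re-ranked, so the best-fitness trace is monotonically non-increasing.
    The season resets to winter at the start of every iteration; a summer
    triggered by the seasonal check lasts for the relocation phase of that
    iteration only.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    population = init_population(cfg, objective, rng)
    best_i = population.best_index
    best_position = population.positions[best_i].copy()
    best_fitness = float(population.fitness[best_i])
    trace = [best_fitness]
    for t in range(cfg.T):
        season = SeasonState(season="winter")
        population, season = step(
            population, season, t, cfg, objective, rng, post_update_hook
        )
        i = population.best_index
        if population.fitness[i] < best_fitness:
            best_fitness = float(population.fitness[i])
            best_position = population.positions[i].copy()
        else:  # elitism: re-inject the stored best over the current worst
            worst = int(np.argmax(population.fitness))
            population.positions[worst] = best_position
            population.fitness[worst] = best_fitness
            population.roles = assign_roles(
                population.fitness, cfg.n_hickory, cfg.n_acorn
            )
        trace.append(best_fitness)
    return OptimizeResult(best_position, best_fitness, np.asarray(trace))
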