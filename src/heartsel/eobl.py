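"""Elite opposition-based learning (EOBL) for population optimizers.

Opposition-based learning probes the "mirror image" of candidate
solutions; the elite variant reflects through the current best individual
inside the dynamic per-dimension bounds of the population:

    x~_{i,j} = eta * (da_j + db_j) - x_{e,j},

where [da_j, db_j] is the min/max of coordinate j over the population and
eta is a generalised coefficient in U(0, 1).  Reflected coordinates that
leave [da_j, db_j] are reset uniformly inside it.  The opposition
population is evaluated and the best N of the union (current U opposition)
are kept, so the operator can only improve the population's best fitness
while widening exploration around the elite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ssa import Objective, Population, _evaluate

__all__ = ["EOBLConfig", "dynamic_bounds", "elite_opposition", "apply_eobl"]


@dataclass
class EOBLConfig:
    enabled: bool = True
    eta_mode: str = "uniform01"  # or "fixed1"

    def __post_init__(self) -> None:
        if self.eta_mode not in ("uniform01", "fixed1"):
            raise ValueError(f"unknown eta_mode {self.eta_mode!r}")


def dynamic_bounds(population: Population) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension (min, max) over the current population positions."""
    if population.positions.shape[0] == 0:
        raise ValueError("empty population has no dynamic bounds")
    return population.positions.min(axis=0), population.positions.max(axis=0)


def elite_opposition(
    x_e: np.ndarray,
    population: Population,
    cfg: EOBLConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Opposition positions reflected through the elite x_e.

    One eta is drawn per individual per dimension (with ``fixed1`` every
    eta is 1, the classical reflection), so the NP opposition individuals
    differ rather than collapsing onto a single reflected point.
    Out-of-bound coordinates are reset uniformly inside [da_j, db_j].
    """
    da, db = dynamic_bounds(population)
    NP, D = population.positions.shape
    if cfg.eta_mode == "fixed1":
        eta = np.ones((NP, D))
    else:
        eta = rng.random((NP, D))
    opp = eta * (da + db) - np.asarray(x_e, dtype=float)
    out = (opp < da) | (opp > db)
    if out.any():
        opp[out] = (da + rng.random((NP, D)) * (db - da))[out]
    return opp


def apply_eobl(
    population: Population,
    objective: Objective,
    cfg: EOBLConfig,
    rng: np.random.Generator,
) -> Population:
    """Greedy union step: keep the best N of current U opposition."""
    if not cfg.enabled:
        return population
    x_e = population.positions[population.best_index]
    opp_positions = elite_opposition(x_e, population, cfg, rng)
    opp_fitness = np.array([_evaluate(objective, p) for p in opp_positions])
    all_pos = np.vstack([population.positions, opp_positions])
    all_fit = np.concatenate([population.fitness, opp_fitness])
    keep = np.argsort(all_fit, kind="stable")[: population.positions.shape[0]]
    population.positions = all_pos[keep]
    population.fitness = all_fit[keep]
    return population
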