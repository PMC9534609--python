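"""Synthetic clinical tables and benchmark objectives.

The generator emulates the shape of the UCI Cleveland heart-disease table:
303 rows, 13 numeric features, a binary outcome with roughly 46% positive
prevalence, a small fraction of informative features carrying a mean shift
between classes, and a few percent of cells missing at random.  It lets
every stage of the pipeline — parsing, preprocessing, wrapper feature
selection, classification, evaluation — be exercised end to end without
any external download, and it returns the planted informative index set so
recovery can be scored.

``benchmark_objective`` provides the standard sphere / Rastrigin /
Rosenbrock test functions used to validate the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import ClinicalTable

__all__ = [
    "SynthConfig",
    "generate_clinical",
    "write_cleveland_csv",
    "benchmark_objective",
]


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults mirror the Cleveland table: n=303 rows, d=13 features,
    positive prevalence 139/303, with 4 informative features shifted by
    1.5 standard deviations between classes and 2% of cells missing.
    """

    n: int = 303
    d: int = 13
    k_informative: int = 4
    effect_size: float = 1.5
    class_balance: float = 139 / 303
    missing_rate: float = 0.02
    noise_sd: float = 1.0
    categorical: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k_informative <= self.d:
            raise ValueError("need 1 <= k_informative <= d")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("need 0 <= missing_rate < 1")
        if not 0 < self.class_balance < 1:
            raise ValueError("need 0 < class_balance < 1")


def generate_clinical(cfg: SynthConfig) -> tuple[ClinicalTable, np.ndarray]:
    """Draw a Cleveland-shaped table; returns (table, informative indices).

    Labels are Bernoulli(class_balance); informative features are
    Normal(label * effect_size, noise_sd), the rest Normal(0, noise_sd).
    With ``categorical=True`` three of the noise features are discretised
    to small integer codes, mimicking Cleveland's cp/restecg/thal columns.
    Missing cells are masked uniformly at random and hold NaN.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = (rng.random(cfg.n) < cfg.class_balance).astype(int)
    informative = np.sort(rng.choice(cfg.d, size=cfg.k_informative, replace=False))
    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.n, cfg.d))
    values[:, informative] += labels[:, None] * cfg.effect_size
    if cfg.categorical:
        noise_idx = [j for j in range(cfg.d) if j not in set(informative.tolist())]
        for j in noise_idx[:3]:
            values[:, j] = np.clip(np.round(values[:, j]), -1, 2) + 1
    mask = rng.random((cfg.n, cfg.d)) < cfg.missing_rate
    values = values.copy()
    values[mask] = np.nan
    table = ClinicalTable(values=values, missing_mask=mask, labels=labels)
    return table, informative


def write_cleveland_csv(table: ClinicalTable, path: str | Path) -> Path:
    """Write a table in the Cleveland CSV dialect (``?`` for missing cells).

    The label is written as the stage column (0/1), which round-trips
    through the stage > 0 binarisation rule.
    """
    path = Path(path)
    with path.open("w") as fh:
        for i in range(table.n):
            cells = [
                "?" if table.missing_mask[i, j] else repr(float(table.values[i, j]))
                for j in range(table.d)
            ]
            cells.append(str(int(table.labels[i])))
            fh.write(",".join(cells) + "\n")
    return path


def benchmark_objective(name: str, D: int):
    """Return a standard test objective f: R^D -> R with global minimum 0.

    sphere: sum x_j^2, optimum at the origin.
    rastrigin: 10 D + sum (x_j^2 - 10 cos 2 pi x_j), optimum at the origin.
    rosenbrock: sum 100 (x_{j+1} - x_j^2)^2 + (1 - x_j)^2, optimum at ones.
    """
    if name == "sphere":
        return lambda x: float(np.sum(np.asarray(x, dtype=float) ** 2))
    if name == "rastrigin":
        def rastrigin(x):
            x = np.asarray(x, dtype=float)
            return float(10.0 * D + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))
        return rastrigin
    if name == "rosenbrock":
        def rosenbrock(x):
            x = np.asarray(x, dtype=float)
            return float(
                np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2)
            )
        return rosenbrock
    raise ValueError(f"unknown benchmark objective {name!r}")
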