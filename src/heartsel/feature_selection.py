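"""Wrapper feature selection driven by the EO-SSA optimizer.

Candidate feature subsets are scored by the weighted cost

    fitness = alpha * error + (1 - alpha) * |Y| / |T|,

where ``error`` is the stratified cross-validated misclassification rate
of a wrapper classifier on the masked feature matrix, |Y| the subset size
and |T| the total feature count.  With the conventional alpha = 0.99 the
classification error dominates and subset size acts as a tie-breaker, so
two subsets of equal error prefer the smaller one.

The optimizer searches the continuous cube [0, 1]^d; a position is mapped
to a subset by thresholding each coordinate at 0.5 (taking the single
largest coordinate when none passes, so subsets are never empty).  The
search wrapper is a fast k-nearest-neighbour classifier by default; any
scikit-learn style estimator factory can be substituted, including the
full attention CNN-LSTM.

The model/results surface follows the fitted-model idiom:
``EOSSAFeatureSelection(table).fit()`` returns a
:class:`FeatureSelectionResults` with the subset, its cost, the search
trace and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .data import ClinicalTable
from .eobl import EOBLConfig, apply_eobl
from .ssa import SSAConfig, optimize

__all__ = [
    "FeatureSubset",
    "FitnessConfig",
    "binarize_position",
    "wrapper_error",
    "subset_fitness",
    "EOSSAFeatureSelection",
    "FeatureSelectionResults",
    "select_features",
]


@dataclass
class FeatureSubset:
    """Binary inclusion mask over the d features."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 1 or not self.mask.any():
            raise ValueError("a feature subset must select at least one feature")

    @property
    def indices(self) -> list[int]:
        """Selected feature indices, 1-based (reporting convention)."""
        return [int(j) + 1 for j in np.flatnonzero(self.mask)]

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    def apply(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values)[:, self.mask]


@dataclass
class FitnessConfig:
    """Weights and wrapper for the subset cost.

    alpha : weight of the classification error (beta = 1 - alpha weighs
        the relative subset size).
    wrapper_factory : zero-argument callable returning a fresh classifier
        with fit/predict; default 5-nearest-neighbours.
    cv_folds : stratified folds for the error estimate.
    """

    alpha: float = 0.99
    wrapper_factory: Callable = field(
        default_factory=lambda: (lambda: KNeighborsClassifier(n_neighbors=5))
    )
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


def binarize_position(position: np.ndarray) -> FeatureSubset:
    """Threshold a [0,1]^d position at 0.5; guarantee a non-empty subset.

    If no coordinate exceeds 0.5 the single largest coordinate is selected
    (lowest index on ties).
    """
    position = np.asarray(position, dtype=float)
    mask = position > 0.5
    if not mask.any():
        mask = np.zeros(position.shape, dtype=bool)
        mask[int(np.argmax(position))] = True
    return FeatureSubset(mask)


def wrapper_error(
    X: np.ndarray, y: np.ndarray, cfg: FitnessConfig
) -> float:
    """Mean stratified-CV misclassification rate of the wrapper classifier."""
    y = np.asarray(y)
    counts = np.bincount(y)
    if (counts[counts > 0] < cfg.cv_folds).any():
        raise ValueError(
            f"cannot stratify {cfg.cv_folds} folds: smallest class has "
            f"{counts[counts > 0].min()} members"
        )
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    errors = []
    for train, test in skf.split(X, y):
        clf = cfg.wrapper_factory()
        clf.fit(X[train], y[train])
        errors.append(float(np.mean(clf.predict(X[test]) != y[test])))
    return float(np.mean(errors))


def subset_fitness(
    subset: FeatureSubset, table: ClinicalTable, cfg: FitnessConfig
) -> float:
    """Weighted cost alpha*error + (1-alpha)*|Y|/|T| for one subset."""
    if table.missing_mask.any():
        raise ValueError("table must be preprocessed (no missing values)")
    err = wrapper_error(subset.apply(table.values), table.labels, cfg)
    return cfg.alpha * err + cfg.beta * (subset.size / table.d)


@dataclass
class FeatureSelectionResults:
    """Outcome of one EO-SSA feature-selection run."""

    subset: FeatureSubset
    cost: float
    trace: np.ndarray
    feature_names: list[str]
    n_fitness_evaluations: int

    def summary(self) -> str:
        names = [self.feature_names[j - 1] for j in self.subset.indices]
        lines = [
            "EO-SSA feature selection",
            "=" * 40,
            f"selected indices (1-based): {self.subset.indices}",
            f"selected features:          {names}",
            f"subset size:                {self.subset.size}/{len(self.feature_names)}",
            f"best cost:                  {self.cost:.4f}",
            f"iterations:                 {len(self.trace) - 1}",
            f"distinct subsets evaluated: {self.n_fitness_evaluations}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "indices": self.subset.indices,
            "mask": self.subset.mask.astype(int).tolist(),
            "size": self.subset.size,
            "cost": float(self.cost),
            "trace": [float(v) for v in self.trace],
        }


class EOSSAFeatureSelection:
    """Feature-selection model: EO-SSA over [0,1]^d with the wrapper cost.

    Parameters
    ----------
    table : ClinicalTable
        Preprocessed table (no missing cells; features in [0, 1]).
    fitness_config, ssa_config, eobl_config : optional
        Sub-configurations; the SSA dimensionality and bounds are forced
        to d and [0, 1].  ``eobl_config.enabled=False`` gives the plain
        SSA ablation.
    """

    def __init__(
        self,
        table: ClinicalTable,
        fitness_config: FitnessConfig | None = None,
        ssa_config: SSAConfig | None = None,
        eobl_config: EOBLConfig | None = None,
    ):
        if table.missing_mask.any():
            raise ValueError("table must be preprocessed before feature selection")
        self.table = table
        self.fitness_config = fitness_config or FitnessConfig()
        ssa = ssa_config or SSAConfig(N=20, T=100)
        ssa.D = table.d
        ssa.FS_L, ssa.FS_U = 0.0, 1.0
        ssa.__post_init__()  # re-derive bounds for the forced geometry
        self.ssa_config = ssa
        self.eobl_config = eobl_config or EOBLConfig(enabled=True)
        self._cache: dict[bytes, float] = {}

    def _objective(self, position: np.ndarray) -> float:
        subset = binarize_position(position)
        key = subset.mask.tobytes()
        if key not in self._cache:
            self._cache[key] = subset_fitness(subset, self.table, self.fitness_config)
        return self._cache[key]

    def fit(self) -> FeatureSelectionResults:
        rng = np.random.default_rng(self.ssa_config.seed)
        hook = None
        if self.eobl_config.enabled:
            hook = lambda pop: apply_eobl(pop, self._objective, self.eobl_config, rng)
        res = optimize(self._objective, self.ssa_config, post_update_hook=hook, rng=rng)
        return FeatureSelectionResults(
            subset=binarize_position(res.best_position),
            cost=res.best_fitness,
            trace=res.trace,
            feature_names=list(self.table.feature_names),
            n_fitness_evaluations=len(self._cache),
        )


def select_features(
    table: ClinicalTable,
    ssa_config: SSAConfig | None = None,
    eobl_config: EOBLConfig | None = None,
    fitness_config: FitnessConfig | None = None,
) -> FeatureSelectionResults:
    """Functional convenience wrapper around :class:`EOSSAFeatureSelection`."""
    model = EOSSAFeatureSelection(table, fitness_config, ssa_config, eobl_config)
    return model.fit()
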