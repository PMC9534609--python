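"""Core tabular container for clinical feature matrices.

A :class:`ClinicalTable` is an ``n x d`` numeric matrix with an explicit
missingness mask, per-column feature names and a binary outcome vector
(1 = disease present, 0 = absent).  It is the object every stage of the
pipeline — imputation, noise repair, normalisation, feature selection and
classification — consumes and returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClinicalTable"]


@dataclass
class ClinicalTable:
    """Numeric clinical table with missingness mask and binary labels.

    Parameters
    ----------
    values : ndarray of shape (n, d)
        Feature matrix.  Cells flagged in ``missing_mask`` hold a
        placeholder (NaN by convention) until imputation.
    missing_mask : ndarray of bool, shape (n, d)
        True exactly where the source data was missing.
    feature_names : list of str, length d
    labels : ndarray of int, shape (n,)
        Binary outcome; 1 encodes presence of heart disease.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape "
                f"{self.missing_mask.shape}"
            )
        if self.labels.size and self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length must equal number of rows")
        if not self.feature_names:
            self.feature_names = [f"f{j + 1}" for j in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must equal number of columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ClinicalTable":
        return ClinicalTable(
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            feature_names=list(self.feature_names),
            labels=self.labels.copy(),
        )
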