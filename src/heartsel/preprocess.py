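"""Reading and preprocessing of Cleveland-dialect clinical tables.

The pipeline has three stages applied in order:

1. missing-value replacement (per-feature median by default, mean optional);
2. noise repair by the median studentized-residual rule: each feature is
   regressed on all other features, cells whose externally studentized
   residual exceeds a threshold are replaced by the feature median;
3. min-max normalisation of every feature to [0, 1] (z-score optional),
   with the fitted per-feature parameters retained so held-out data can be
   transformed without leakage.

The file dialect is the UCI Cleveland one: comma-separated, 13 predictor
columns plus an integer disease-stage column, ``?`` marking missing cells.
The multi-valued stage is collapsed to a binary label (stage > 0 = disease
present).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .data import ClinicalTable

__all__ = [
    "PreprocessConfig",
    "Normalizer",
    "read_cleveland",
    "impute_missing",
    "remove_noise_studentized",
    "normalize",
    "preprocess",
]

logger = logging.getLogger(__name__)

CLEVELAND_FEATURES = [
    "age", "sex", "cp", "restbps", "chol", "fbs", "restecg",
    "thalach", "examg", "oldpeak", "slope", "ca", "thal",
]


@dataclass
class PreprocessConfig:
    """Knobs for the three preprocessing stages.

    missing_strategy : {"median", "mean"}
    studentized_threshold : positive float
        Cells with |externally studentized residual| above this are
        repaired.  3.0 is the conventional outlier cut.
    normalization : {"minmax", "zscore"}
    """

    missing_strategy: str = "median"
    studentized_threshold: float = 3.0
    normalization: str = "minmax"

    def __post_init__(self) -> None:
        if self.missing_strategy not in ("median", "mean"):
            raise ValueError(f"unknown missing_strategy {self.missing_strategy!r}")
        if self.studentized_threshold <= 0:
            raise ValueError("studentized_threshold must be positive")
        if self.normalization not in ("minmax", "zscore"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


class ParseError(ValueError):
    """Raised for malformed rows or cells in a Cleveland-dialect file."""


def read_cleveland(path: str | Path) -> ClinicalTable:
    """Read a Cleveland-dialect CSV into a :class:`ClinicalTable`.

    The canonical file has 14 comma-separated columns (13 features plus
    the integer disease stage, binarised as label = 1 iff stage > 0), but
    any consistent width >= 2 is accepted so generated tables round-trip.
    ``?`` cells are recorded in the missing mask with a NaN placeholder.
    """
    path = Path(path)
    rows: list[list[float]] = []
    mask_rows: list[list[bool]] = []
    labels: list[int] = []
    width: int | None = None
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if width is None:
                if len(row) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected at least 2 columns, got {len(row)}"
                    )
                width = len(row)
            if len(row) != width:
                raise ParseError(
                    f"{path}:{lineno}: expected {width} columns, got {len(row)}"
                )
            vals, miss = [], []
            for col, cell in enumerate(row[:-1]):
                cell = cell.strip()
                if cell == "?":
                    vals.append(np.nan)
                    miss.append(True)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}:{lineno}: column {col + 1}: "
                            f"non-numeric cell {cell!r}"
                        ) from exc
                    miss.append(False)
            stage_cell = row[-1].strip()
            try:
                stage = float(stage_cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric stage {stage_cell!r}"
                ) from exc
            rows.append(vals)
            mask_rows.append(miss)
            labels.append(1 if stage > 0 else 0)
    if not rows:
        raise ParseError(f"{path}: empty file")
    d = len(rows[0])
    names = list(CLEVELAND_FEATURES) if d == 13 else [f"f{j + 1}" for j in range(d)]
    return ClinicalTable(
        values=np.array(rows, dtype=float),
        missing_mask=np.array(mask_rows, dtype=bool),
        feature_names=names,
        labels=np.array(labels, dtype=int),
    )


def impute_missing(table: ClinicalTable, cfg: PreprocessConfig | None = None) -> ClinicalTable:
    """Replace masked cells by the per-feature median (or mean) of observed cells."""
    cfg = cfg or PreprocessConfig()
    if not table.missing_mask.any():
        return table
    out = table.copy()
    stat = np.nanmedian if cfg.missing_strategy == "median" else np.nanmean
    for j in range(out.d):
        col_mask = out.missing_mask[:, j]
        if not col_mask.any():
            continue
        observed = out.values[~col_mask, j]
        if observed.size == 0:
            raise ValueError(
                f"feature {out.feature_names[j]!r} is entirely missing; "
                "no imputation statistic defined"
            )
        out.values[col_mask, j] = stat(observed)
    out.missing_mask[:] = False
    return out


def _studentized_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Externally studentized residuals of OLS of y on X (intercept added)."""
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    return np.asarray(OLSInfluence(fit).resid_studentized_external)


def remove_noise_studentized(
    table: ClinicalTable, cfg: PreprocessConfig | None = None
) -> tuple[ClinicalTable, int]:
    """Repair noisy cells flagged by the median studentized-residual rule.

    For each feature j, the feature is regressed on all other features and
    cells with |externally studentized residual| > threshold are replaced
    by the feature's median.  When the design for a feature is rank
    deficient the studentization falls back to the robust per-feature
    (value - median)/MAD score, with a logged notice.

    Returns the repaired table and the number of replaced cells.
    """
    cfg = cfg or PreprocessConfig()
    if table.missing_mask.any():
        raise ValueError("impute missing values before noise removal")
    out = table.copy()
    flags = np.zeros(out.values.shape, dtype=bool)
    for j in range(out.d):
        y = out.values[:, j]
        X = np.delete(out.values, j, axis=1)
        if np.linalg.matrix_rank(np.column_stack([np.ones(out.n), X])) < X.shape[1] + 1:
            logger.warning(
                "singular design for feature %s; falling back to median/MAD "
                "studentization", out.feature_names[j],
            )
            med = np.median(y)
            mad = np.median(np.abs(y - med))
            scale = 1.4826 * mad if mad > 0 else (np.std(y) or 1.0)
            resid = (y - med) / scale
        else:
            resid = _studentized_residuals(y, X)
        flags[:, j] = np.abs(resid) > cfg.studentized_threshold
    n_replaced = int(flags.sum())
    for j in range(out.d):
        if flags[:, j].any():
            out.values[flags[:, j], j] = np.median(table.values[:, j])
    logger.info("studentized-residual repair replaced %d cells", n_replaced)
    return out, n_replaced


@dataclass
class Normalizer:
    """Per-feature affine normalisation with parameters fit once.

    minmax maps the fitted min/max to [0, 1] (constant features to 0);
    zscore centres and scales by the fitted mean/sd.  Transforming
    held-out data reuses the fitted parameters, clipping minmax output to
    [0, 1] so downstream [0, 1] assumptions hold.
    """

    method: str = "minmax"
    loc_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "Normalizer":
        values = np.asarray(values, dtype=float)
        if self.method == "minmax":
            self.loc_ = values.min(axis=0)
            rng = values.max(axis=0) - self.loc_
            self.scale_ = np.where(rng > 0, rng, 1.0)
        elif self.method == "zscore":
            self.loc_ = values.mean(axis=0)
            sd = values.std(axis=0, ddof=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            raise ValueError(f"unknown normalization {self.method!r}")
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.loc_ is None:
            raise RuntimeError("Normalizer not fitted")
        out = (np.asarray(values, dtype=float) - self.loc_) / self.scale_
        if self.method == "minmax":
            out = np.clip(out, 0.0, 1.0)
        return out

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "loc": self.loc_.tolist(),
            "scale": self.scale_.tolist(),
        }


def normalize(
    table: ClinicalTable, cfg: PreprocessConfig | None = None
) -> tuple[ClinicalTable, Normalizer]:
    """Normalise every feature; returns the table and the fitted parameters."""
    cfg = cfg or PreprocessConfig()
    if table.missing_mask.any():
        raise ValueError("impute missing values before normalisation")
    norm = Normalizer(method=cfg.normalization).fit(table.values)
    out = table.copy()
    out.values = norm.transform(table.values)
    return out, norm


def preprocess(
    table: ClinicalTable, cfg: PreprocessConfig | None = None
) -> tuple[ClinicalTable, dict]:
    """Full pipeline: impute -> studentized noise repair -> normalise.

    Returns the processed table and a JSON-serialisable parameter record
    (imputation strategy, repaired-cell count, normalisation parameters).
    """
    cfg = cfg or PreprocessConfig()
    t = impute_missing(table, cfg)
    t, n_replaced = remove_noise_studentized(t, cfg)
    t, norm = normalize(t, cfg)
    params = {
        "missing_strategy": cfg.missing_strategy,
        "studentized_threshold": cfg.studentized_threshold,
        "noise_cells_replaced": n_replaced,
        "normalization": norm.to_dict(),
    }
    return t, params
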