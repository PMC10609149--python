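"""Significance filtering, min-max normalization and discretization.

Records are kept when p <= p_max and fold change >= fc_min (both inclusive).
Each descriptor column is rescaled to [0, 1] by its fitted min and max;
discretization turns a continuous column into ordinal bin indices for the
information-gain scorer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import DescriptorMatrix, MetaboliteTable
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "NormalizationState",
    "DiscretizationSpec",
    "filter_significance",
    "fit_normalization",
    "apply_normalization",
    "discretize",
]


@dataclass(frozen=True)
class FilterSpec:
    """Inclusive significance thresholds: keep p <= p_max and FC >= fc_min."""

    p_max: float = 0.05
    fc_min: float = 1.2

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max <= 1.0):
            raise ValidationError(f"p_max must be in (0, 1], got {self.p_max}")
        if not self.fc_min > 0:
            raise ValidationError(f"fc_min must be > 0, got {self.fc_min}")


@dataclass
class NormalizationState:
    """Per-column min and max fitted on a training matrix."""

    col_ids: list[str]
    col_min: np.ndarray
    col_max: np.ndarray

    def __post_init__(self) -> None:
        self.col_min = np.asarray(self.col_min, dtype=float)
        self.col_max = np.asarray(self.col_max, dtype=float)
        if not (self.col_max >= self.col_min).all():
            raise ValidationError("per-column max must be >= min")


@dataclass(frozen=True)
class DiscretizationSpec:
    n_bins: int = 10
    strategy: str = "equal_width"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.strategy not in ("equal_width", "equal_frequency"):
            raise ValidationError(f"unknown discretization strategy {self.strategy!r}")


def filter_significance(table: MetaboliteTable, spec: FilterSpec | None = None) -> MetaboliteTable:
    """Keep records with p_value <= p_max AND fold_change >= fc_min, in order."""
    spec = spec or FilterSpec()
    if len(table) == 0:
        raise ValidationError("cannot filter an empty table")
    kept = [
        r for r in table if r.p_value <= spec.p_max and r.fold_change >= spec.fc_min
    ]
    logger.info("significance filter retained %d of %d records", len(kept), len(table))
    if not kept:
        logger.warning("significance filter removed every record")
    return MetaboliteTable(kept)


def fit_normalization(matrix: DescriptorMatrix) -> NormalizationState:
    """Record column-wise min and max of the input matrix."""
    if matrix.values.size == 0:
        raise ValidationError("cannot fit normalization on an empty matrix")
    return NormalizationState(
        col_ids=list(matrix.col_ids),
        col_min=matrix.values.min(axis=0),
        col_max=matrix.values.max(axis=0),
    )


def apply_normalization(matrix: DescriptorMatrix, state: NormalizationState) -> DescriptorMatrix:
    """Map each cell to (x - min) / (max - min), clipped to [0, 1].

    Constant columns (max == min) map to 0.  Out-of-range values from a new
    matrix are clipped and the clip count logged.
    """
    if list(matrix.col_ids) != list(state.col_ids):
        raise ValidationError("matrix columns do not match normalization state")
    span = state.col_max - state.col_min
    safe = np.where(span > 0, span, 1.0)
    scaled = (matrix.values - state.col_min) / safe
    scaled[:, span == 0] = 0.0
    clipped = np.clip(scaled, 0.0, 1.0)
    n_clip = int((clipped != scaled).sum())
    if n_clip:
        logger.info("normalization clipped %d out-of-range cell(s)", n_clip)
    return DescriptorMatrix(list(matrix.row_ids), list(matrix.col_ids), clipped)


def _equal_width_column(col: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.zeros(col.shape, dtype=int)
    idx = np.floor((col - lo) / (hi - lo) * n_bins).astype(int)
    return np.minimum(idx, n_bins - 1)


def _equal_frequency_column(col: np.ndarray, n_bins: int) -> np.ndarray:
    # stable rank-based quantile binning: ties resolved by original order
    n = col.shape[0]
    order = np.argsort(col, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def discretize(matrix: DescriptorMatrix, spec: DiscretizationSpec | None = None) -> np.ndarray:
    """Bin each column independently into integer indices 0..n_bins-1."""
    spec = spec or DiscretizationSpec()
    values = matrix.values
    if not np.isfinite(values).all():
        raise ValidationError("matrix values must be finite for discretization")
    strategy = spec.strategy
    if strategy == "equal_frequency" and spec.n_bins > values.shape[0]:
        logger.warning(
            "equal_frequency with n_bins=%d > n_rows=%d; falling back to equal_width",
            spec.n_bins,
            values.shape[0],
        )
        strategy = "equal_width"
    out = np.empty(values.shape, dtype=int)
    for j in range(values.shape[1]):
        col = values[:, j]
        if strategy == "equal_width":
            out[:, j] = _equal_width_column(col, spec.n_bins)
        else:
            if col.max() == col.min():
                out[:, j] = 0
            else:
                out[:, j] = _equal_frequency_column(col, spec.n_bins)
    return out
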