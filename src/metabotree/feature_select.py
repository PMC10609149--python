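"""Entropy / information-gain feature scoring and top-k selection.

Features are scored on their discretized form; the selected matrix returned
to the caller keeps the *continuous* values of the winning columns, since
the downstream dimensionality reduction operates on real numbers.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import DescriptorMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["InfoGainScore", "entropy", "info_gain", "rank_and_select"]


@dataclass(frozen=True)
class InfoGainScore:
    feature: str
    gain: float  # bits


def entropy(labels: Sequence, base: float = 2.0) -> float:
    """Shannon entropy of the empirical label distribution (0*log0 = 0)."""
    labels = list(labels)
    if not labels:
        raise ValidationError("entropy of an empty label list is undefined")
    n = len(labels)
    h = 0.0
    for count in Counter(labels).values():
        p = count / n
        h -= p * math.log(p, base)
    return max(h, 0.0)


def info_gain(feature_bins: Sequence[int], labels: Sequence, base: float = 2.0) -> float:
    """H(labels) minus the bin-weighted conditional entropy of the labels."""
    feature_bins = list(feature_bins)
    labels = list(labels)
    if len(feature_bins) != len(labels):
        raise ValidationError(
            f"feature ({len(feature_bins)}) and labels ({len(labels)}) lengths differ"
        )
    n = len(labels)
    by_bin: dict[int, list] = {}
    for b, y in zip(feature_bins, labels):
        by_bin.setdefault(b, []).append(y)
    conditional = sum(len(ys) / n * entropy(ys, base) for ys in by_bin.values())
    return max(entropy(labels, base) - conditional, 0.0)


def rank_and_select(
    discrete: np.ndarray,
    continuous: DescriptorMatrix,
    labels: Sequence,
    k: int,
    base: float = 2.0,
) -> tuple[DescriptorMatrix, list[InfoGainScore]]:
    """Score every column by information gain and keep the k best.

    Columns are sorted by gain descending with ties broken by original
    column order; the returned matrix is ``continuous`` restricted to the
    selected columns.  The full score list (all columns, ranked) is
    returned alongside.
    """
    discrete = np.asarray(discrete)
    if discrete.shape != continuous.shape:
        raise ValidationError(
            f"discrete shape {discrete.shape} does not match matrix {continuous.shape}"
        )
    n_cols = discrete.shape[1]
    if not (1 <= k <= n_cols):
        raise ValidationError(f"k must be in [1, {n_cols}], got {k}")
    gains = [info_gain(discrete[:, j], labels, base) for j in range(n_cols)]
    order = sorted(range(n_cols), key=lambda j: (-gains[j], j))
    scores = [InfoGainScore(continuous.col_ids[j], gains[j]) for j in order]
    selected_cols = [continuous.col_ids[j] for j in order[:k]]
    logger.info("information gain selected %d of %d features", k, n_cols)
    return continuous.select_columns(selected_cols), scores
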