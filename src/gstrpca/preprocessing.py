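"""Feature filtering that turns raw per-omic matrices into the integrated
irregular tensor.

Two filters are applied per omic layer, in order:

1. drop features with zero expression in every cell;
2. drop features expressed (entry > 0) in too few cells — a feature is kept
   only when its expression prevalence is *strictly above* the threshold
   (default 0.8, i.e. expressed in over 80% of cells).

No normalisation or log transform is applied; ``build_tensor`` accepts a
``transform`` hook for callers that need one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .tensor import ConformabilityError, DomainError, IrregularTensor


@dataclass
class FilterReport:
    """Per-slice bookkeeping of both filter stages."""

    threshold: float
    n_before: list[int] = field(default_factory=list)
    n_after_unexpressed: list[int] = field(default_factory=list)
    n_after_prevalence: list[int] = field(default_factory=list)
    kept_indices: list[np.ndarray] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_before": self.n_before,
            "n_after_unexpressed": self.n_after_unexpressed,
            "n_after_prevalence": self.n_after_prevalence,
            "kept_indices": [idx.tolist() for idx in self.kept_indices],
        }


def _check_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise DomainError("expected a 2-D feature x cell matrix")
    if m.shape[1] == 0:
        raise DomainError("matrix has zero cells (columns)")
    if np.any(m < 0):
        warnings.warn(
            "matrix contains negative entries; expression data are "
            "expected to be nonnegative",
            stacklevel=3,
        )
    return m


def drop_unexpressed(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove features (rows) that are zero in every cell; order preserved."""
    m = _check_matrix(m)
    kept = np.flatnonzero(np.any(m != 0, axis=1))
    return m[kept], kept


def prevalence_filter(
    m: np.ndarray, threshold: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Keep features expressed (entry > 0) in strictly more than
    ``threshold`` of the cells."""
    if not (0.0 <= threshold <= 1.0):
        raise DomainError(f"threshold {threshold} outside [0, 1]")
    m = _check_matrix(m)
    prevalence = np.mean(m > 0, axis=1)
    kept = np.flatnonzero(prevalence > threshold)
    return m[kept], kept


def build_tensor(
    mats: Sequence[np.ndarray],
    threshold: float = 0.8,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[IrregularTensor, FilterReport]:
    """Filter each omic matrix and assemble the integrated irregular tensor.

    All matrices must have the same cell count and a consistent cell
    ordering (the caller's responsibility).  ``transform`` is an optional
    per-slice hook (e.g. a normalisation) applied after filtering.
    """
    if not mats:
        raise DomainError("no matrices given")
    n_cells = {np.asarray(m).shape[1] for m in mats}
    if len(n_cells) != 1:
        raise ConformabilityError(
            f"matrices disagree on cell count: {sorted(n_cells)}"
        )

    report = FilterReport(threshold=threshold)
    filtered = []
    for k, m in enumerate(mats):
        m = _check_matrix(m)
        report.n_before.append(m.shape[0])
        m1, kept1 = drop_unexpressed(m)
        report.n_after_unexpressed.append(m1.shape[0])
        m2, kept2 = prevalence_filter(m1, threshold)
        report.n_after_prevalence.append(m2.shape[0])
        report.kept_indices.append(kept1[kept2])
        if m2.shape[0] == 0:
            raise DomainError(
                f"no features survive filtering in slice {k} "
                f"(threshold={threshold})"
            )
        if transform is not None:
            m2 = np.asarray(transform(m2), dtype=float)
        filtered.append(m2)
    return IrregularTensor(filtered), report
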