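"""Irregular tensor data model.

An *irregular tensor* is an ordered collection of K real matrices (one per
omic layer) that share their column (cell) dimension M but may differ in row
(feature) count: slice k has shape N_k x M.  It is the central object of the
decomposition: the data X, the low-rank part L, the sparse part E and the
ADMM dual variable Y are all irregular tensors over the same shape.

Slices are stored as an explicit list of dense 2-D arrays, never as a padded
3-D array, so no algorithm can silently operate on padding.  Zero-padding to
a regular N_max x M x K array is an explicit, separate operation
(:func:`zero_pad`) used only by the padding-based baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class ConformabilityError(ValueError):
    """Raised when tensor shapes are incompatible for an operation."""


class DomainError(ValueError):
    """Raised when an argument is outside an operation's domain."""


class IrregularTensor:
    """Ordered collection of K feature x cell matrices sharing M columns.

    Parameters
    ----------
    slices
        Matrices of shape (N_k, M); every slice must have the same number of
        columns M >= 1 and finite entries.
    copy
        Copy the input arrays (default).  Pass ``False`` only when the caller
        guarantees the arrays are never mutated elsewhere.
    """

    __slots__ = ("_slices",)

    def __init__(self, slices: Iterable[np.ndarray], *, copy: bool = True):
        mats = [np.array(s, dtype=np.float64, copy=copy, ndmin=2) for s in slices]
        if not mats:
            raise DomainError("an irregular tensor needs at least one slice")
        m = mats[0].shape[1]
        for k, s in enumerate(mats):
            if s.ndim != 2:
                raise DomainError(f"slice {k} is not a matrix (ndim={s.ndim})")
            if s.shape[1] != m:
                raise ConformabilityError(
                    f"slice {k} has {s.shape[1]} columns, expected {m} "
                    "(all slices must share the cell dimension)"
                )
            if not np.all(np.isfinite(s)):
                raise DomainError(f"slice {k} contains non-finite entries")
        self._slices = tuple(mats)

    # -- basic structure ---------------------------------------------------

    @property
    def slices(self) -> tuple[np.ndarray, ...]:
        return self._slices

    @property
    def row_dims(self) -> list[int]:
        """Feature count N_k of each slice."""
        return [s.shape[0] for s in self._slices]

    @property
    def n_cols(self) -> int:
        """Shared cell count M."""
        return self._slices[0].shape[1]

    @property
    def n_slices(self) -> int:
        """Number of omic layers K."""
        return len(self._slices)

    def __len__(self) -> int:
        return len(self._slices)

    def __getitem__(self, k: int) -> np.ndarray:
        return self._slices[k]

    def __iter__(self):
        return iter(self._slices)

    def __repr__(self) -> str:
        dims = ",".join(str(n) for n in self.row_dims)
        return f"IrregularTensor(({dims})x{self.n_cols}x{self.n_slices})"

    def conformable(self, other: "IrregularTensor") -> bool:
        """True iff K, M and every N_k match (an equivalence relation)."""
        return (
            self.n_slices == other.n_slices
            and self.n_cols == other.n_cols
            and self.row_dims == other.row_dims
        )

    def _require_conformable(self, other: "IrregularTensor") -> None:
        if not self.conformable(other):
            raise ConformabilityError(
                f"tensors are not conformable: {self!r} vs {other!r}"
            )

    # -- elementwise algebra ----------------------------------------------

    def copy(self) -> "IrregularTensor":
        return IrregularTensor(self._slices, copy=True)

    def map(self, fn) -> "IrregularTensor":
        """Apply ``fn`` to each slice; shapes must be preserved."""
        return IrregularTensor([fn(s) for s in self._slices], copy=False)

    def __add__(self, other: "IrregularTensor") -> "IrregularTensor":
        self._require_conformable(other)
        return IrregularTensor(
            [a + b for a, b in zip(self._slices, other._slices)], copy=False
        )

    def __sub__(self, other: "IrregularTensor") -> "IrregularTensor":
        self._require_conformable(other)
        return IrregularTensor(
            [a - b for a, b in zip(self._slices, other._slices)], copy=False
        )

    def __mul__(self, a: float) -> "IrregularTensor":
        return IrregularTensor([a * s for s in self._slices], copy=False)

    __rmul__ = __mul__

    def __neg__(self) -> "IrregularTensor":
        return self * (-1.0)

    def abs_max(self) -> float:
        """Largest absolute entry across all slices."""
        return max(float(np.abs(s).max()) for s in self._slices)

    def sum_abs(self) -> float:
        """Entrywise L1 norm, summed over all slices."""
        return float(sum(np.abs(s).sum() for s in self._slices))

    def allfinite(self) -> bool:
        return all(np.all(np.isfinite(s)) for s in self._slices)


@dataclass
class RegularTensor:
    """Zero-padded regular N_max x M x K array plus its padding mask.

    ``data[:, :, k]`` holds slice k in its top N_k rows; rows at and beyond
    N_k are exactly zero.  ``pad_mask[k, i]`` is True where row i of slice k
    is padding (not data), so un-padding then re-padding is the identity.
    """

    data: np.ndarray
    pad_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise DomainError("regular tensor data must be 3-D (N x M x K)")
        n_max, _, k = self.data.shape
        if self.pad_mask.shape != (k, n_max):
            raise ConformabilityError(
                f"pad_mask shape {self.pad_mask.shape} does not match "
                f"data shape {self.data.shape}"
            )
        for kk in range(k):
            if np.any(self.data[self.pad_mask[kk], :, kk] != 0.0):
                raise DomainError(f"padded rows of slice {kk} are not zero")

    @property
    def row_dims(self) -> list[int]:
        return [int((~self.pad_mask[k]).sum()) for k in range(self.data.shape[2])]


def make_irregular(slabs: Sequence[np.ndarray]) -> IrregularTensor:
    """Validate and assemble a list of feature x cell matrices."""
    return IrregularTensor(slabs)


def zeros_like(t: IrregularTensor) -> IrregularTensor:
    return IrregularTensor([np.zeros(s.shape) for s in t.slices], copy=False)


def fro_norm(t: IrregularTensor) -> float:
    """Frobenius norm over all slices: sqrt(sum_k ||slice_k||_F^2)."""
    return float(np.sqrt(sum(float(np.sum(s * s)) for s in t.slices)))


def axpy(a: float, x: IrregularTensor, y: IrregularTensor) -> IrregularTensor:
    """Slicewise a*x + y for conformable tensors."""
    x._require_conformable(y)
    return IrregularTensor(
        [a * xs + ys for xs, ys in zip(x.slices, y.slices)], copy=False
    )


def zero_pad(t: IrregularTensor) -> RegularTensor:
    """Embed an irregular tensor in a regular array by appending zero rows."""
    n_max = max(t.row_dims)
    m, k = t.n_cols, t.n_slices
    data = np.zeros((n_max, m, k))
    mask = np.ones((k, n_max), dtype=bool)
    for kk, s in enumerate(t.slices):
        n_k = s.shape[0]
        data[:n_k, :, kk] = s
        mask[kk, :n_k] = False
    return RegularTensor(data=data, pad_mask=mask)


def unpad(r: RegularTensor) -> IrregularTensor:
    """Inverse of :func:`zero_pad`: recover the irregular slices."""
    return IrregularTensor(
        [r.data[~r.pad_mask[k], :, k] for k in range(r.data.shape[2])]
    )
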