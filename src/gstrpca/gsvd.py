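"""Joint (generalized) SVD of an irregular tensor's slices.

All K slices are factorized against one *shared* right factor V spanning a
common cell-space subspace, with per-slice left factors U_k and per-slice
singular-value vectors sigma_k:

    slice_k  =  U_k . diag(sigma_k) . V^T        (exact when r = M)

The shared subspace is built from the vertical stack of the slices: the
top-r right singular vectors of the (sum_k N_k) x M stacked matrix D give V.
Each slice is then projected, C_k = slice_k V, and column j of C_k is split
into a direction (column j of U_k) and a magnitude sigma_k[j] = ||C_k[:,j]||.
Because V is orthonormal this reconstructs every slice exactly at full
dimension, and column j of every U_k refers to the same shared direction —
the property the weighted thresholding step relies on.

Notes
-----
* sigma vectors follow the *stacked* matrix's singular-value order (shared
  across slices), not per-slice descending order.
* U_k columns have unit norm where sigma_k[j] > 0 but are not orthonormal in
  general; where sigma_k[j] = 0 the column is the zero vector.
* Sign convention: the first entry of each V column with magnitude above
  1e-12 is made nonnegative, for reproducibility.

The construction is deliberately behind one narrow contract so another
joint-SVD variant (e.g. HO-GSVD) can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .tensor import ConformabilityError, DomainError, IrregularTensor

_SIGN_TOL = 1e-12


@dataclass
class GSVDFactors:
    """Per-slice left factors and singular values with one shared V.

    Attributes
    ----------
    U_list : list of (N_k, r) arrays
    sigma_list : list of length-r nonnegative vectors
    V : (M, r) array with orthonormal columns
    """

    U_list: list[np.ndarray]
    sigma_list: list[np.ndarray]
    V: np.ndarray

    @property
    def r(self) -> int:
        return self.V.shape[1]

    @property
    def n_slices(self) -> int:
        return len(self.U_list)

    def __post_init__(self) -> None:
        if len(self.U_list) != len(self.sigma_list):
            raise ConformabilityError("U_list and sigma_list lengths differ")
        r = self.V.shape[1]
        for k, (u, s) in enumerate(zip(self.U_list, self.sigma_list)):
            if u.shape[1] != r or s.shape != (r,):
                raise ConformabilityError(
                    f"factor shapes inconsistent at slice {k}: "
                    f"U {u.shape}, sigma {s.shape}, r={r}"
                )


def _fix_column_signs(v: np.ndarray) -> np.ndarray:
    """Flip each column so its first entry with |.| > tol is nonnegative."""
    v = v.copy()
    for j in range(v.shape[1]):
        col = v[:, j]
        nz = np.flatnonzero(np.abs(col) > _SIGN_TOL)
        if nz.size and col[nz[0]] < 0:
            v[:, j] = -col
    return v


def _complete_orthonormal(v: np.ndarray, r: int) -> np.ndarray:
    """Extend the orthonormal columns of ``v`` (M x q, q < r) to M x r."""
    m, q = v.shape
    rng = np.eye(m)
    proj = rng - v @ v.T  # projector onto the orthogonal complement
    # orthonormal basis of the complement via QR of the projector's columns
    qmat, _ = np.linalg.qr(proj)
    # keep complement directions that are genuinely orthogonal to v
    extra = []
    for j in range(m):
        c = qmat[:, j] - v @ (v.T @ qmat[:, j])
        nrm = np.linalg.norm(c)
        if nrm > 1e-8:
            c = c / nrm
            extra.append(c)
            v = np.hstack([v, c[:, None]])
            if v.shape[1] == r:
                break
    if v.shape[1] != r:
        raise DomainError("could not complete orthonormal basis")
    return v


def joint_gsvd(t: IrregularTensor, r: int | None = None) -> GSVDFactors:
    """Decompose all slices against one shared right factor.

    Parameters
    ----------
    t
        The irregular tensor to factorize.
    r
        Shared subspace dimension, 1 <= r <= M.  Default: r = M (exact).
    """
    m = t.n_cols
    if r is None:
        r = m
    if not (1 <= r <= m):
        raise DomainError(f"subspace dimension r={r} outside [1, {m}]")

    stacked = np.vstack(t.slices)
    # thin SVD of the stack; right singular vectors span the shared subspace
    _, _, vh = scipy.linalg.svd(stacked, full_matrices=False)
    v = vh.T  # M x min(sum N_k, M)
    if v.shape[1] >= r:
        v = v[:, :r]
    else:
        v = _complete_orthonormal(v, r)
    v = _fix_column_signs(v)

    u_list, sig_list = [], []
    for s in t.slices:
        c = s @ v  # N_k x r projections onto the shared directions
        sig = np.linalg.norm(c, axis=0)
        u = np.zeros_like(c)
        nz = sig > 0
        u[:, nz] = c[:, nz] / sig[nz]
        u_list.append(u)
        sig_list.append(sig)
    return GSVDFactors(U_list=u_list, sigma_list=sig_list, V=v)


def dump_factors(f: GSVDFactors, outdir) -> None:
    """Debug dump: shared V and per-slice spectra as CSV files."""
    from pathlib import Path

    import numpy as np

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "V.csv", f.V, delimiter=",")
    for k, s in enumerate(f.sigma_list):
        np.savetxt(outdir / f"sigma_slice{k}.csv", s, delimiter=",")


def gsvd_reconstruct(f: GSVDFactors) -> IrregularTensor:
    """Map factors back to an irregular tensor: slice_k = U_k diag(s_k) V^T."""
    vt = f.V.T
    return IrregularTensor(
        [(u * s) @ vt for u, s in zip(f.U_list, f.sigma_list)], copy=False
    )
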