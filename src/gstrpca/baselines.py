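"""Ablation baselines: padding-based GSTRPCA and a t-SVD variant.

Two reference methods isolate the contributions of (a) operating on the
irregular tensor directly and (b) the shared-subspace GSVD engine:

* ``fill_gstrpca`` — zero-pad the irregular tensor to a regular
  N_max x M x K array and run the identical ADMM loop on the padded slices,
  un-padding the outputs.
* ``t_strpca`` — same padding and ADMM scaffold, but the low-rank step is a
  weighted *tubal* singular-value thresholding built on the t-SVD (matrix
  SVDs of the mode-3 Fourier-transformed frontal slices), with the same
  weight scheme applied per frequency slice.

Both share the solver's configuration so a comparison isolates the
decomposition engine only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shrinkage import WeightScheme, make_weights
from .solver import SolverConfig, SolverState, admm_loop, gstrpca, _gsvt_step
from .tensor import (
    DomainError,
    IrregularTensor,
    RegularTensor,
    unpad,
    zero_pad,
)


# ---------------------------------------------------------------------------
# t-SVD machinery (tensor-tensor product via mode-3 DFT)
# ---------------------------------------------------------------------------


@dataclass
class TSVDFactors:
    """t-SVD factors T = U * S * V^T in the t-product sense.

    U is N x N x K and V is M x M x K, both orthogonal tensors under the
    t-product; S is N x M x K and f-diagonal (each Fourier-domain frontal
    slice diagonal, nonnegative, nonincreasing).  ``transform`` names the
    mode-3 unitary transform used.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    transform: str = "fft"


def t_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Tensor-tensor product: slicewise matrix products in the DFT domain."""
    if a.shape[2] != b.shape[2] or a.shape[1] != b.shape[0]:
        raise DomainError(f"t-product shape mismatch: {a.shape} * {b.shape}")
    af = np.fft.fft(a, axis=2)
    bf = np.fft.fft(b, axis=2)
    cf = np.einsum("ijk,jlk->ilk", af, bf)
    return np.real(np.fft.ifft(cf, axis=2))


def t_transpose(a: np.ndarray) -> np.ndarray:
    """t-product transpose: transpose frontal slices, reverse slices 1..K-1."""
    at = np.transpose(a, (1, 0, 2)).copy()
    at[:, :, 1:] = at[:, :, :0:-1]
    return at


def tsvd(t: RegularTensor | np.ndarray) -> TSVDFactors:
    """Full t-SVD of a regular tensor via per-frequency matrix SVDs."""
    data = t.data if isinstance(t, RegularTensor) else np.asarray(t, dtype=float)
    if data.ndim != 3:
        raise DomainError("tsvd expects an N x M x K array")
    n, m, k = data.shape
    tf = np.fft.fft(data, axis=2)
    uf = np.zeros((n, n, k), dtype=complex)
    sf = np.zeros((n, m, k), dtype=complex)
    vf = np.zeros((m, m, k), dtype=complex)
    for i in range(k):
        u, s, vh = np.linalg.svd(tf[:, :, i], full_matrices=True)
        uf[:, :, i] = u
        sf[: len(s), : len(s), i][np.diag_indices(len(s))] = s
        vf[:, :, i] = vh.conj().T
    out = []
    for arr in (uf, sf, vf):
        back = np.fft.ifft(arr, axis=2)
        out.append(np.real(back))
    return TSVDFactors(U=out[0], S=out[1], V=out[2])


def tsvd_reconstruct(f: TSVDFactors) -> np.ndarray:
    """U * S * V^T under the t-product."""
    return t_product(t_product(f.U, f.S), t_transpose(f.V))


def _tubal_weighted_svt(
    data: np.ndarray, tau: float, scheme: WeightScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted SVT of each Fourier-domain frontal slice.

    Conjugate-symmetric frequency pairs carry identical singular values and
    get identical thresholds, so the inverse transform is real up to
    rounding; the imaginary residue is truncated.
    """
    tf = np.fft.fft(data, axis=2)
    k = data.shape[2]
    out = np.empty_like(tf)
    kept = []
    for i in range(k):
        u, s, vh = np.linalg.svd(tf[:, :, i], full_matrices=False)
        w = make_weights(s, scheme)
        s_new = np.maximum(s - tau * w, 0.0)
        out[:, :, i] = (u * s_new) @ vh
        kept.append(s_new)
    back = np.real(np.fft.ifft(out, axis=2))
    # mean spectrum across frequencies = tubal nuclear surrogate
    return back, np.mean(np.stack(kept), axis=0) / k


# ---------------------------------------------------------------------------
# Padding-based solvers
# ---------------------------------------------------------------------------


def _padded_as_irregular(x: IrregularTensor) -> tuple[IrregularTensor, RegularTensor]:
    reg = zero_pad(x)
    k = reg.data.shape[2]
    slices = [reg.data[:, :, i] for i in range(k)]
    return IrregularTensor(slices), reg


def _unpad_like(t: IrregularTensor, template: RegularTensor) -> IrregularTensor:
    return IrregularTensor(
        [
            t.slices[k][~template.pad_mask[k], :]
            for k in range(len(t.slices))
        ]
    )


def fill_gstrpca(
    X: IrregularTensor, cfg: SolverConfig | None = None
) -> tuple[IrregularTensor, IrregularTensor, SolverState]:
    """GSTRPCA applied to the zero-padded regular tensor.

    The identical ADMM loop runs with the K padded N_max x M slices as the
    slice set; outputs are un-padded back to the irregular shape (padded
    positions are discarded).
    """
    padded, reg = _padded_as_irregular(X)
    L, E, state = admm_loop(padded, cfg, _gsvt_step)
    return _unpad_like(L, reg), _unpad_like(E, reg), state


def t_strpca(
    X: IrregularTensor, cfg: SolverConfig | None = None
) -> tuple[IrregularTensor, IrregularTensor, SolverState]:
    """Weighted-threshold decomposition built on the t-SVD of the padded
    tensor: the same ADMM loop with a tubal SVT low-rank step."""
    padded, reg = _padded_as_irregular(X)

    def tubal_step(target: IrregularTensor, tau: float, scheme: WeightScheme):
        data = np.stack(target.slices, axis=2)
        back, spectrum = _tubal_weighted_svt(data, tau, scheme)
        out = IrregularTensor([back[:, :, i] for i in range(back.shape[2])])
        return out, [spectrum]

    L, E, state = admm_loop(padded, cfg, tubal_step)
    return _unpad_like(L, reg), _unpad_like(E, reg), state


METHODS = {
    "gstrpca": gstrpca,
    "fill": fill_gstrpca,
    "tsvd": t_strpca,
}
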