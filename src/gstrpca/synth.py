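"""Synthetic data with planted ground truth.

Two generators back every recovery and clustering test:

* :func:`plant_lowrank_sparse` — an irregular tensor X = L0 + E0 + noise
  with a low-rank part sharing one cell factor across slices (the premise
  that all omic layers reflect a single underlying cell state) and sparse
  gross corruption of known support.
* :func:`make_clustered_multiomics` — clustered, count-like multi-omics
  data: a planted cell-type partition with per-type mean profiles per slice,
  within-type noise, dropout zeros and sparse corruption, clipped at zero.

Defaults emulate the regime the package targets: K=2 layers with strongly
unbalanced feature counts, a handful of cell types, and expression
prevalence high enough to survive an 80% prevalence filter (i.e. the
post-filter regime of typical CITE-seq-style inputs).  Both generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor import DomainError, IrregularTensor


@dataclass(frozen=True)
class PlantSpec:
    """Low-rank + sparse planting parameters.

    row_dims/M/K describe the tensor shape; r the planted shared rank;
    p the Bernoulli sparse-corruption fraction; a the spike amplitude;
    sd the dense Gaussian noise level (0 = exact plant).
    """

    row_dims: tuple[int, ...] = (40, 200)
    n_cols: int = 60
    rank: int = 3
    sparse_frac: float = 0.05
    amplitude: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 0 or (
            self.rank > 0 and self.rank > min(min(self.row_dims), self.n_cols)
        ):
            raise DomainError(
                f"rank {self.rank} exceeds min(row_dims, M)="
                f"{min(min(self.row_dims), self.n_cols)}"
            )
        if not (0.0 <= self.sparse_frac < 1.0):
            raise DomainError("sparse_frac must be in [0, 1)")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be nonnegative")


def plant_lowrank_sparse(
    spec: PlantSpec,
) -> tuple[IrregularTensor, IrregularTensor, IrregularTensor]:
    """Draw (X, L0, E0) with X = L0 + E0 + Gaussian(sd) noise.

    L0 slice k = F_k G^T with a shared M x r cell factor G and per-slice
    N_k x r feature factors, all with unit-variance entries.  E0 has iid
    Bernoulli(p) support with amplitudes +/- a.
    """
    rng = np.random.default_rng(spec.seed)
    m, r = spec.n_cols, spec.rank
    cell_factor = rng.standard_normal((m, r)) if r > 0 else np.zeros((m, 0))

    l_slices, e_slices, x_slices = [], [], []
    for n_k in spec.row_dims:
        feat = rng.standard_normal((n_k, r)) if r > 0 else np.zeros((n_k, 0))
        l0 = feat @ cell_factor.T
        support = rng.random((n_k, m)) < spec.sparse_frac
        signs = rng.choice([-1.0, 1.0], size=(n_k, m))
        e0 = np.where(support, spec.amplitude * signs, 0.0)
        noise = (
            spec.noise_sd * rng.standard_normal((n_k, m))
            if spec.noise_sd > 0
            else 0.0
        )
        l_slices.append(l0)
        e_slices.append(e0)
        x_slices.append(l0 + e0 + noise)
    return (
        IrregularTensor(x_slices),
        IrregularTensor(l_slices),
        IrregularTensor(e_slices),
    )


@dataclass(frozen=True)
class ClusterSpec:
    """Clustered multi-omics generator parameters.

    delta is the between-type mean separation (sd of per-type mean shifts),
    within_sd the within-type noise, dropout the probability an entry is
    zeroed, corrupt_frac/corrupt_amp the sparse gross-corruption rate and
    size.  Nonnegativity is enforced by clipping at 0 (count-like data).
    """

    n_cells: int = 300
    n_types: int = 5
    proportions: tuple[float, ...] | None = None
    feature_counts: tuple[int, ...] = (30, 800)
    delta: float = 1.0
    within_sd: float = 0.5
    dropout: float = 0.1
    corrupt_frac: float = 0.01
    corrupt_amp: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise DomainError("need at least 2 cell types")
        if any(f < 1 for f in self.feature_counts):
            raise DomainError("feature counts must be >= 1")
        if self.proportions is not None:
            p = np.asarray(self.proportions, dtype=float)
            if len(p) != self.n_types or np.any(p <= 0) or abs(p.sum() - 1) > 1e-8:
                raise DomainError(
                    "proportions must be positive, one per type, summing to 1"
                )
        if not (0.0 <= self.dropout < 1.0):
            raise DomainError("dropout must be in [0, 1)")
        if not (0.0 <= self.corrupt_frac < 1.0):
            raise DomainError("corrupt_frac must be in [0, 1)")


def make_clustered_multiomics(
    spec: ClusterSpec,
) -> tuple[IrregularTensor, np.ndarray]:
    """Generate (X, labels_true) for a planted cell-type partition."""
    rng = np.random.default_rng(spec.seed)
    c = spec.n_types
    props = (
        np.full(c, 1.0 / c)
        if spec.proportions is None
        else np.asarray(spec.proportions, dtype=float)
    )
    counts = np.floor(props * spec.n_cells).astype(int)
    counts[: spec.n_cells - counts.sum()] += 1  # distribute the remainder
    labels = np.repeat(np.arange(c), counts)
    rng.shuffle(labels)

    slices = []
    for n_feat in spec.feature_counts:
        base = rng.uniform(1.0, 3.0, size=n_feat)  # baseline expression
        type_means = base[None, :] + spec.delta * rng.standard_normal((c, n_feat))
        x = type_means[labels] + spec.within_sd * rng.standard_normal(
            (spec.n_cells, n_feat)
        )
        x = x.T  # features x cells
        if spec.dropout > 0:
            x[rng.random(x.shape) < spec.dropout] = 0.0
        if spec.corrupt_frac > 0:
            hit = rng.random(x.shape) < spec.corrupt_frac
            x = np.where(
                hit, x + spec.corrupt_amp * rng.uniform(1.0, 2.0, x.shape), x
            )
        slices.append(np.clip(x, 0.0, None))
    return IrregularTensor(slices), labels
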