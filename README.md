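# gstrpca

Robust low-rank + sparse decomposition of **irregular tensors** — stacks of
feature × cell matrices that share their cell dimension but differ in
feature count — for integrating and clustering single-cell multi-omics data
(CITE-seq RNA + ADT, RNA + ATAC, …), with no zero-padding of the data.

## Who this is for

Analysts with K per-omic matrices X_k ∈ R^{N_k × M} over the same M cells
(e.g. 30 surface proteins and 800 genes for 300 cells) who want a joint
low-dimensional cell-state structure that is robust to gross entrywise
corruption (dropout spikes, technical artifacts), plus a clustering of the
cells and standard agreement scores against known labels.

## The model

The irregular tensor X = {X_1, …, X_K} is split into a low-rank part L and
a sparse part E:

```
min_{L,E}  ||L||_*  +  λ ||E||_1     s.t.  X = L + E
```

solved by ADMM.  The nuclear-norm proximal step uses a *joint* GSVD: one
shared orthonormal cell-space factor V (from the SVD of the vertically
stacked slices) with per-slice left factors U_k and spectra σ_k, so that
X_k = U_k diag(σ_k) Vᵀ exactly and a single per-component threshold acts
coherently across omic layers.  The sparse step is entrywise soft
thresholding.  λ defaults to sqrt(K / max(N_max, M)); thresholds can be
uniform (default) or inversely weighted by the shared spectrum.  Two
ablation engines — the same solver on the zero-padded regular tensor
(`fill`), and weighted tubal thresholding on the t-SVD of the padded tensor
(`tsvd`) — isolate the effect of the irregular treatment and of the GSVD.
See `docs/methods.md` for the full account.

## Worked example

Generate clustered synthetic CITE-seq-like data (5 cell types, 300 cells,
feature counts 30 and 800), filter, decompose, and score the clustering:

```python
from gstrpca import GSTRPCA, ClusterSpec, make_clustered_multiomics

X, labels = make_clustered_multiomics(ClusterSpec(seed=0))
model = GSTRPCA.from_raw(list(X.slices), threshold=0.8)   # two-stage filter
res = model.fit()
print(res.summary())
print(res.evaluate(labels, seed=0).metrics)
```

```
GSTRPCA decomposition results
==============================================
method:            gstrpca
tensor shape:      (25,636) x 300 x 2
lambda:            0.0560772
weight scheme:     uniform
iterations:        131 (max 500)
converged:         True
final residual:    9.756e-08 (tol 1e-07)
||L||_F:           1076
||E||_F:           460.376
E sparsity:        66.48% zeros
==============================================
{'acc': 1.0, 'nmi': 1.0, 'ari': 1.0, 'ami': 1.0}
```

The filter keeps 25 of 30 and 636 of 800 features (prevalence > 0.8); the
solver converges in 131 iterations to a feasible split X ≈ L + E; k-means
on the reconstruction recovers the planted 5-type partition perfectly
(accuracy, normalized mutual information, adjusted Rand index and adjusted
mutual information all 1.0 against the ground-truth labels).

The same flow from the shell:

```bash
gstrpca simulate  --preset clustered --seed 0 --out sim/
gstrpca decompose --input sim/X_slice0.mtx --input sim/X_slice1.mtx --out decomp/
gstrpca cluster   --decomposition decomp/ --k 5 --labels sim/labels.tsv \
                  --seed 0 --out metrics.json
gstrpca ablate    --input sim/X_slice0.mtx --input sim/X_slice1.mtx \
                  --labels sim/labels.tsv --out ablation.csv
```

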