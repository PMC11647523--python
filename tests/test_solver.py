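"""ADMM solver: update steps, stopping rule, and planted-problem recovery."""

import numpy as np
import pytest

from gstrpca import (
    DomainError,
    PlantSpec,
    SolverConfig,
    SolverState,
    WeightScheme,
    fro_norm,
    gstrpca,
    make_irregular,
    plant_lowrank_sparse,
    residual,
    update_E,
    update_L,
)
from gstrpca.tensor import zeros_like

UNIFORM = WeightScheme(kind="uniform")


def make_state(X, mu, L=None, E=None, Y=None):
    return SolverState(
        L=L or zeros_like(X), E=E or zeros_like(X), Y=Y or zeros_like(X), mu=mu
    )


class TestResidual:
    def test_perfect_split_gives_zero(self, small_tensor):
        assert residual(small_tensor, zeros_like(small_tensor), small_tensor) == 0.0

    def test_zero_iterates_give_one(self, small_tensor):
        z = zeros_like(small_tensor)
        assert residual(z, z, small_tensor) == pytest.approx(1.0)

    def test_matches_entrywise_oracle(self, small_tensor, rng):
        L = make_irregular([rng.normal(size=(4, 6)), rng.normal(size=(9, 6))])
        E = make_irregular([rng.normal(size=(4, 6)), rng.normal(size=(9, 6))])
        num = np.sqrt(
            sum(
                np.sum((l + e - x) ** 2)
                for l, e, x in zip(L.slices, E.slices, small_tensor.slices)
            )
        )
        assert residual(L, E, small_tensor) == pytest.approx(
            num / fro_norm(small_tensor), rel=1e-12
        )

    def test_zero_x_rejected(self, small_tensor):
        z = zeros_like(small_tensor)
        with pytest.raises(DomainError):
            residual(small_tensor, small_tensor, z)


class TestUpdateSteps:
    def test_update_l_vanishing_threshold_returns_x(self):
        X, _, _ = plant_lowrank_sparse(
            PlantSpec(row_dims=(6, 10), n_cols=8, rank=1, sparse_frac=0.0, seed=0)
        )
        cfg = SolverConfig(weights=UNIFORM)
        state = make_state(X, mu=1e12)
        out = update_L(state, X, cfg)
        assert fro_norm(out - X) / fro_norm(X) <= 1e-8

    def test_update_l_annihilation_at_tiny_mu(self, small_tensor):
        cfg = SolverConfig(weights=UNIFORM)
        state = make_state(small_tensor, mu=1e-9)
        assert fro_norm(update_L(state, small_tensor, cfg)) == 0.0

    def test_update_l_single_slice_matches_svt_oracle(self, rng):
        a = rng.normal(size=(10, 7))
        X = make_irregular([a])
        mu = 2.0
        u, s, vh = np.linalg.svd(a, full_matrices=False)
        svt = (u * np.maximum(s - 1.0 / mu, 0.0)) @ vh
        out = update_L(make_state(X, mu=mu), X, SolverConfig(weights=UNIFORM))
        np.testing.assert_allclose(out.slices[0], svt, atol=1e-8)

    def test_update_e_no_penalty_limit(self, small_tensor, rng):
        L = make_irregular([rng.normal(size=(4, 6)), rng.normal(size=(9, 6))])
        # lam/mu negligible -> E = X - L - Y/mu exactly (Y = 0 here)
        cfg = SolverConfig(lam=1e-15, weights=UNIFORM)
        out = update_E(make_state(small_tensor, mu=1e6, L=L), small_tensor, cfg)
        for o, x, l in zip(out.slices, small_tensor.slices, L.slices):
            np.testing.assert_allclose(o, x - l, atol=1e-8)

    def test_update_e_total_shrinkage(self, small_tensor):
        big_lam = small_tensor.abs_max() * 10
        cfg = SolverConfig(lam=big_lam, weights=UNIFORM)
        out = update_E(make_state(small_tensor, mu=1.0), small_tensor, cfg)
        assert fro_norm(out) == 0.0

    def test_update_e_matches_prox_grid_oracle(self, rng):
        x = rng.uniform(-3, 3, size=(3, 4))
        X = make_irregular([x])
        cfg = SolverConfig(lam=0.7, weights=UNIFORM)
        out = update_E(make_state(X, mu=1.0), X, cfg)
        grid = np.linspace(-10, 10, 20001)
        for i in range(3):
            for j in range(4):
                obj = 0.7 * np.abs(grid) + 0.5 * (grid - x[i, j]) ** 2
                assert abs(out.slices[0][i, j] - grid[np.argmin(obj)]) <= 1e-3


class TestFullSolve:
    def test_pure_lowrank_goes_to_l(self):
        X, L0, _ = plant_lowrank_sparse(
            PlantSpec(row_dims=(12, 30), n_cols=15, rank=2, sparse_frac=0.0, seed=1)
        )
        L, E, state = gstrpca(X)
        assert state.converged
        assert fro_norm(E) / fro_norm(X) <= 1e-3
        assert fro_norm(L - X) / fro_norm(X) <= 1e-3

    def test_pure_sparse_goes_to_e(self):
        X, _, E0 = plant_lowrank_sparse(
            PlantSpec(row_dims=(12, 30), n_cols=15, rank=0, sparse_frac=0.01, seed=2)
        )
        L, E, state = gstrpca(X, SolverConfig(lam=0.01))
        assert fro_norm(L) / fro_norm(X) <= 1e-2
        assert fro_norm(E - E0) / fro_norm(E0) <= 1e-2

    def test_planted_recovery_single_seed(self):
        X, L0, E0 = plant_lowrank_sparse(PlantSpec(seed=1))
        L, E, state = gstrpca(X)
        assert state.converged
        assert fro_norm(L - L0) / fro_norm(L0) <= 1e-2
        assert fro_norm(E - E0) / (fro_norm(E0) + 1) <= 1e-2

    def test_convergence_report_is_consistent(self):
        X, _, _ = plant_lowrank_sparse(PlantSpec(seed=3))
        cfg = SolverConfig()
        _, _, state = gstrpca(X, cfg)
        assert len(state.history) == state.iter <= cfg.max_iter
        assert state.converged
        assert state.history[-1]["residual"] < cfg.tol

    def test_zero_tensor_rejected(self):
        z = make_irregular([np.zeros((3, 4))])
        with pytest.raises(DomainError):
            gstrpca(z)

    def test_history_mu_follows_schedule(self):
        X, _, _ = plant_lowrank_sparse(
            PlantSpec(row_dims=(8, 12), n_cols=10, rank=1, seed=4)
        )
        cfg = SolverConfig(mu0=1e-3, rho=1.1)
        _, _, state = gstrpca(X, cfg)
        mus = [h["mu"] for h in state.history[:20]]
        np.testing.assert_allclose(
            mus, [1e-3 * 1.1**i for i in range(len(mus))], rtol=1e-10
        )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lam": -1.0},
            {"mu0": 0.0},
            {"rho": 0.9},
            {"mu_max": 1e-9},
            {"tol": 0.0},
            {"max_iter": 0},
            {"init": "warm"},
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(DomainError):
            SolverConfig(**kwargs)
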