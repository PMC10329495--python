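"""Fused-Laplacian optimizer: objective, block updates, full fit."""

import numpy as np
import pytest

from schoml.fusion import (
    FusionState,
    HighOrderLaplacianFusion,
    fit_fusion,
    objective_value,
    solve_simplex_qp,
    update_h,
    update_lambda,
    update_lambda_diag,
    update_mu,
    update_w_factor,
)
from schoml.graphs import GraphConfig, build_laplacian_stack

from oracles import (
    make_random_stack,
    objective_dense,
    random_valid_state,
    simplex_lattice,
)


def _stack_and_state(rng, n=15, V=2, c=3):
    stack = make_random_stack(rng, n=n, V=V)
    state = random_valid_state(rng, n, c, V)
    return stack, state


class TestObjective:
    def test_matches_dense_oracle(self, rng):
        for _ in range(5):
            stack, state = _stack_and_state(rng)
            expected = objective_dense(
                state.lam, state.mu, state.W, state.Lambda, state.H, stack.laplacians
            )
            assert objective_value(state, stack) == pytest.approx(expected, rel=1e-12)

    def test_zero_lambda_diag_trace_term_is_c(self, rng):
        stack, state = _stack_and_state(rng, c=3)
        state.Lambda = np.zeros(3)
        n = stack.n_cells
        G = state.lam * stack.mixed(1, state.mu) + (1 - state.lam) * stack.mixed(2, state.mu)
        frob = float(np.sum((np.eye(n) - G) ** 2))
        assert objective_value(state, stack) == pytest.approx(3.0 + frob)

    def test_nonnegative_on_random_states(self, rng):
        for _ in range(10):
            stack, state = _stack_and_state(rng)
            assert objective_value(state, stack) >= 0.0


class TestLambdaUpdate:
    def test_identical_mixtures_keep_previous(self, rng):
        X = rng.standard_normal((12, 4))
        stack = build_laplacian_stack([X, X.copy()], GraphConfig(k=3))
        # duplicate modality and uniform mu: same mixture at both orders?
        # no — orders differ; instead collapse orders by a 1-order stack
        stack1 = build_laplacian_stack([X], GraphConfig(k=3, max_order=1))
        state = random_valid_state(rng, 12, 2, 1)
        state.lam = 0.37
        assert update_lambda(state, stack1) == pytest.approx(0.37)

    def test_beats_fine_grid(self, rng):
        for _ in range(5):
            stack, state = _stack_and_state(rng)
            lam_star = update_lambda(state, stack)
            assert 0.0 <= lam_star <= 1.0
            state_star = FusionState(
                lam=lam_star, mu=state.mu, W=state.W, Lambda=state.Lambda, H=state.H
            )
            best = objective_value(state_star, stack)
            for lam in np.linspace(0, 1, 1001):
                trial = FusionState(
                    lam=float(lam), mu=state.mu, W=state.W, Lambda=state.Lambda, H=state.H
                )
                assert best <= objective_value(trial, stack) + 1e-9


class TestWFactorUpdate:
    def test_never_increases_objective(self, rng):
        for _ in range(5):
            stack, state = _stack_and_state(rng)
            before = objective_value(state, stack)
            state.W = update_w_factor(state, stack)
            after = objective_value(state, stack)
            assert after <= before + 1e-9
            np.testing.assert_allclose(state.W.T @ state.W, np.eye(3), atol=1e-8)

    def test_achieves_eigenvalue_lower_bound(self, rng):
        # tr(Lambda W^T B W) after the update equals the rearrangement bound:
        # largest Lambda paired with smallest eigenvalues of B
        stack, state = _stack_and_state(rng, c=3)
        W = update_w_factor(state, stack)
        G = state.lam * stack.mixed(1, state.mu) + (1 - state.lam) * stack.mixed(2, state.mu)
        B = G - 0.5 * state.H @ state.H.T
        B = (B + B.T) / 2
        vals = np.linalg.eigvalsh(B)
        achieved = float(np.trace(np.diag(state.Lambda) @ W.T @ B @ W))
        bound = float(np.sum(np.sort(state.Lambda)[::-1] * vals[:3]))
        assert achieved == pytest.approx(bound, abs=1e-8)

    def test_identity_lambda_gives_ascending_eigenvectors(self, rng):
        stack, state = _stack_and_state(rng, c=2)
        state.Lambda = np.ones(2)
        W = update_w_factor(state, stack)
        G = state.lam * stack.mixed(1, state.mu) + (1 - state.lam) * stack.mixed(2, state.mu)
        B = (G - 0.5 * state.H @ state.H.T)
        B = (B + B.T) / 2
        vals, vecs = np.linalg.eigh(B)
        # compare spanned subspaces column by column via Rayleigh quotients
        np.testing.assert_allclose(
            np.einsum("ij,ij->j", W, B @ W), vals[:2], atol=1e-8
        )


class TestLambdaDiagUpdate:
    def test_matches_clamped_formula(self, rng):
        for _ in range(5):
            stack, state = _stack_and_state(rng)
            Lam = update_lambda_diag(state, stack)
            G = state.lam * stack.mixed(1, state.mu) + (1 - state.lam) * stack.mixed(
                2, state.mu
            )
            C = state.W.T @ (G - 0.5 * state.H @ state.H.T) @ state.W - np.eye(3)
            np.testing.assert_allclose(Lam, np.clip(-np.diag(C), 0.0, 1.0), atol=1e-10)

    def test_beats_coordinate_grid(self, rng):
        stack, state = _stack_and_state(rng, c=2)
        state.Lambda = update_lambda_diag(state, stack)
        best = objective_value(state, stack)
        grid = np.linspace(0, 1, 2001)
        for i in range(2):
            for x in grid:
                trial = state.Lambda.copy()
                trial[i] = x
                cand = FusionState(
                    lam=state.lam, mu=state.mu, W=state.W, Lambda=trial, H=state.H
                )
                assert best <= objective_value(cand, stack) + 1e-9


class TestHUpdate:
    def test_trace_equals_smallest_eigenvalues(self, rng):
        stack, state = _stack_and_state(rng, c=3)
        H = update_h(state)
        n = stack.n_cells
        M = np.eye(n) - state.W @ np.diag(state.Lambda) @ state.W.T
        achieved = float(np.trace(H.T @ M @ H))
        expected = float(np.sum(np.linalg.eigvalsh(M)[:3]))
        assert achieved == pytest.approx(expected, abs=1e-8)
        np.testing.assert_allclose(H.T @ H, np.eye(3), atol=1e-10)

    def test_full_lambda_annihilates_trace(self, rng):
        stack, state = _stack_and_state(rng, c=3)
        state.Lambda = np.ones(3)
        H = update_h(state)
        M = np.eye(stack.n_cells) - state.W @ state.W.T
        assert float(np.trace(H.T @ M @ H)) == pytest.approx(0.0, abs=1e-10)


class TestMuUpdate:
    def test_single_modality_trivial(self, rng):
        stack, state = _stack_and_state(rng, V=1)
        np.testing.assert_array_equal(update_mu(state, stack), [1.0])

    def test_identical_modalities_tie_break_uniform(self, rng):
        X = rng.standard_normal((12, 4))
        stack = build_laplacian_stack([X, X.copy()], GraphConfig(k=3))
        state = random_valid_state(rng, 12, 2, 2)
        np.testing.assert_allclose(update_mu(state, stack), [0.5, 0.5], atol=1e-8)

    @pytest.mark.parametrize("V", [2, 3])
    def test_beats_simplex_lattice(self, rng, V):
        stack, state = _stack_and_state(rng, n=18, V=V)
        mu_star = update_mu(state, stack)
        assert mu_star.min() >= -1e-12
        assert mu_star.sum() == pytest.approx(1.0)
        state.mu = mu_star
        best = objective_value(state, stack)
        for mu in simplex_lattice(V, step=0.05):
            trial = FusionState(
                lam=state.lam, mu=mu, W=state.W, Lambda=state.Lambda, H=state.H
            )
            assert best <= objective_value(trial, stack) + 1e-9

    def test_qp_solver_simple_cases(self):
        # strictly convex, interior optimum: min mu'Imu  ->  uniform
        np.testing.assert_allclose(
            solve_simplex_qp(np.eye(3), np.zeros(3)), np.full(3, 1 / 3), atol=1e-10
        )
        # linear preference pins a vertex
        mu = solve_simplex_qp(np.zeros((2, 2)), np.array([1.0, 0.0]))
        np.testing.assert_allclose(mu, [0.0, 1.0], atol=1e-10)


class TestFit:
    def test_trace_monotone_and_bounded(self, rng):
        for _ in range(5):
            stack = make_random_stack(rng, n=15, V=2)
            state = fit_fusion(stack, n_components=3)
            trace = np.array(state.objective_trace)
            assert np.all(np.diff(trace) <= 1e-9 * np.maximum(1.0, np.abs(trace[:-1])))
            assert trace[-1] >= -1e-12
            assert trace[0] >= trace[-1]

    def test_orthonormality_after_fit(self, rng):
        stack = make_random_stack(rng, n=15, V=2)
        state = fit_fusion(stack, n_components=3)
        np.testing.assert_allclose(state.W.T @ state.W, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(state.H.T @ state.H, np.eye(3), atol=1e-8)
        assert np.all(state.Lambda >= 0) and np.all(state.Lambda <= 1)
        assert state.mu.min() >= 0 and state.mu.sum() == pytest.approx(1.0)
        assert 0.0 <= state.lam <= 1.0

    def test_separated_blobs_recovered(self, rng, blob_modalities):
        from schoml.clustering import correlation_distance, hierarchical_cluster
        from schoml.metrics import ari
        from schoml.preprocess import preprocess_modality

        mods, labels = blob_modalities
        processed = [preprocess_modality(m) for m in mods]
        stack = build_laplacian_stack(processed, GraphConfig(k=5))
        state = fit_fusion(stack, n_components=3)
        pred = hierarchical_cluster(correlation_distance(state.H), 3)
        assert ari(labels, pred) == 1.0

    def test_spectral_init_deterministic_across_seeds(self, rng):
        stack = make_random_stack(rng, n=15, V=2)
        H1 = HighOrderLaplacianFusion(n_components=2, random_state=1).fit(stack).embedding_
        H2 = HighOrderLaplacianFusion(n_components=2, random_state=99).fit(stack).embedding_
        np.testing.assert_array_equal(H1, H2)

    def test_degenerate_single_view_is_spectral_embedding(self, rng, blob_modalities):
        mods, _ = blob_modalities
        stack = build_laplacian_stack([mods[0]], GraphConfig(k=5, max_order=1))
        state = fit_fusion(stack, n_components=3)
        L = stack.laplacians[0][0]
        vals, vecs = np.linalg.eigh(L)
        E = vecs[:, :3]
        # same subspace: projectors agree
        np.testing.assert_allclose(
            state.H @ state.H.T, E @ E.T, atol=1e-6
        )
        np.testing.assert_array_equal(state.mu, [1.0])

    def test_bad_n_components_raises(self, rng):
        stack = make_random_stack(rng, n=8, V=1)
        with pytest.raises(ValueError, match="n_components"):
            HighOrderLaplacianFusion(n_components=8).fit(stack)
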