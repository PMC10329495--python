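"""Fused-Laplacian optimization and the common low-dimensional embedding.

Given per-modality Laplacians at orders 1 and 2, the model approximates a
fused Laplacian by the low-rank factorization I - W Lambda W^T and learns a
joint embedding H by alternating minimization of

    tr(H^T (I - W Lambda W^T) H)
        + || I - W Lambda W^T - (lam * L_mu^(1) + (1 - lam) * L_mu^(2)) ||_F^2

subject to W^T W = H^T H = I_c, 0 <= Lambda_kk <= 1, 0 <= lam <= 1, and
mu on the probability simplex, where L_mu^(i) = sum_p mu_p L_p^(i) mixes the
modalities at order i. Every block update below is the exact minimizer of
this objective in its own variable, so the objective is non-increasing and
bounded below by zero; the loop stops on a relative-change tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator

from .graphs import LaplacianStack

__all__ = [
    "FusionState",
    "HighOrderLaplacianFusion",
    "fit_fusion",
    "objective_value",
    "update_lambda",
    "update_w_factor",
    "update_lambda_diag",
    "update_h",
    "update_mu",
    "solve_simplex_qp",
]


@dataclass
class FusionState:
    """Optimizer variables and the objective trace.

    lam : order-mixing weight in [0, 1]
    mu : modality weights on the simplex
    W : n x c orthonormal eigen-factor of the fused Laplacian
    Lambda : length-c diagonal of the factor weights, each in [0, 1]
    H : n x c orthonormal embedding
    """

    lam: float
    mu: np.ndarray
    W: np.ndarray
    Lambda: np.ndarray
    H: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _coerce_stack(stack) -> LaplacianStack:
    if isinstance(stack, LaplacianStack):
        return stack
    laps = [[np.asarray(L, dtype=float) for L in mats] for mats in stack]
    return LaplacianStack(laplacians=laps, sigmas=[float("nan")] * len(laps))


def _mixed_orders(stack: LaplacianStack, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(L_mu^(1), L_mu^(2)); a single-order stack reuses order 1 for order 2."""
    L1 = stack.mixed(1, mu)
    L2 = stack.mixed(2, mu) if stack.n_orders >= 2 else L1
    return L1, L2


def _fused_low_rank(W: np.ndarray, Lambda: np.ndarray) -> np.ndarray:
    """I - W Lambda W^T."""
    n = W.shape[0]
    return np.eye(n) - (W * Lambda) @ W.T


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic sign: each column's largest-magnitude entry positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def objective_value(state: FusionState, stack) -> float:
    """Value of the fusion objective at the current state (always >= 0)."""
    stack = _coerce_stack(stack)
    L1, L2 = _mixed_orders(stack, state.mu)
    M = _fused_low_rank(state.W, state.Lambda)
    G = state.lam * L1 + (1.0 - state.lam) * L2
    trace_term = float(np.sum(state.H * (M @ state.H)))
    frob_term = float(np.sum((M - G) ** 2))
    return trace_term + frob_term


def update_lambda(state: FusionState, stack) -> float:
    """Closed-form order weight: minimize a*lam^2 + b*lam, clamped to [0, 1].

    a = ||L_mu^(1) - L_mu^(2)||_F^2; when a = 0 the objective is flat in lam
    and the previous value is kept.
    """
    stack = _coerce_stack(stack)
    L1, L2 = _mixed_orders(stack, state.mu)
    diff = L1 - L2
    a = float(np.sum(diff**2))
    if a <= 1e-12 * (np.sum(L1**2) + np.sum(L2**2) + 1e-30):
        return float(state.lam)
    M = _fused_low_rank(state.W, state.Lambda)
    b = 2.0 * float(np.sum((L2 - M) * diff))
    return float(np.clip(-b / (2.0 * a), 0.0, 1.0))


def _eig_smallest(B: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
    B = (B + B.T) / 2.0
    vals, vecs = eigh(B, subset_by_index=[0, c - 1])
    return vals, _fix_signs(vecs)


def update_w_factor(state: FusionState, stack) -> np.ndarray:
    """Eigen-factor update: c smallest eigenvectors of B = G - 0.5 H H^T.

    Columns are assigned so that larger Lambda_kk pairs with smaller
    eigenvalue (the exact minimizer of tr(Lambda W^T B W) over orthonormal
    W, by the rearrangement inequality); with Lambda = I this is the plain
    ascending order.
    """
    stack = _coerce_stack(stack)
    L1, L2 = _mixed_orders(stack, state.mu)
    G = state.lam * L1 + (1.0 - state.lam) * L2
    B = G - 0.5 * state.H @ state.H.T
    c = state.W.shape[1]
    _, vecs = _eig_smallest(B, c)
    # position of each Lambda entry in descending order (stable)
    order = np.argsort(-state.Lambda, kind="stable")
    W = np.empty_like(vecs)
    W[:, order] = vecs
    return W


def update_lambda_diag(state: FusionState, stack) -> np.ndarray:
    """Factor weights: Lambda_kk = clip(-C_kk, 0, 1) with
    C = W^T (G - 0.5 H H^T) W - I."""
    stack = _coerce_stack(stack)
    L1, L2 = _mixed_orders(stack, state.mu)
    G = state.lam * L1 + (1.0 - state.lam) * L2
    WtB = state.W.T @ (G - 0.5 * state.H @ state.H.T)
    C_diag = np.einsum("ij,ji->i", WtB, state.W) - 1.0
    return np.clip(-C_diag, 0.0, 1.0)


def update_h(state: FusionState, stack=None) -> np.ndarray:
    """Embedding update: c smallest eigenvectors of I - W Lambda W^T.

    That matrix's spectrum is {1 - Lambda_kk} on col(W) and 1 on its
    complement, so the minimizer is the W columns reordered by descending
    Lambda; computed analytically for determinism.
    """
    order = np.argsort(-state.Lambda, kind="stable")
    return state.W[:, order].copy()


def solve_simplex_qp(Q: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Exact minimizer of mu^T Q mu + f^T mu over the probability simplex.

    Q must be PSD. Solved by enumerating KKT support sets (the number of
    modalities is small); ties within 1e-10 are broken toward the uniform
    vector so symmetric inputs give symmetric weights.
    """
    Q = np.asarray(Q, dtype=float)
    f = np.asarray(f, dtype=float)
    V = len(f)
    if V == 1:
        return np.array([1.0])
    uniform = np.full(V, 1.0 / V)
    candidates: list[np.ndarray] = []
    for size in range(1, V + 1):
        for S in combinations(range(V), size):
            S = list(S)
            m = len(S)
            A = np.zeros((m + 1, m + 1))
            A[:m, :m] = 2.0 * Q[np.ix_(S, S)]
            A[:m, m] = 1.0
            A[m, :m] = 1.0
            rhs = np.concatenate([-f[S], [1.0]])
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            mu_S = sol[:m]
            if np.any(mu_S < -1e-9):
                continue
            if abs(mu_S.sum() - 1.0) > 1e-8:
                continue
            mu = np.zeros(V)
            mu[S] = np.clip(mu_S, 0.0, None)
            mu /= mu.sum()
            candidates.append(mu)
    if not candidates:  # numerical fallback: best vertex
        objs = [Q[p, p] + f[p] for p in range(V)]
        mu = np.zeros(V)
        mu[int(np.argmin(objs))] = 1.0
        return mu
    objs = np.array([mu @ Q @ mu + f @ mu for mu in candidates])
    best = objs.min()
    tol = 1e-10 * (1.0 + abs(best))
    tied = [mu for mu, o in zip(candidates, objs) if o <= best + tol]
    dists = [float(np.sum((mu - uniform) ** 2)) for mu in tied]
    return tied[int(np.argmin(dists))]


def update_mu(state: FusionState, stack) -> np.ndarray:
    """Modality weights via the simplex-constrained quadratic program.

    With G_p = lam * L_p^(1) + (1 - lam) * L_p^(2), the objective's
    mu-dependent part is mu^T Q mu + f^T mu with Q_pq = tr(G_p G_q) and
    f_p = 2 tr((W Lambda W^T - I) G_p).
    """
    stack = _coerce_stack(stack)
    V = stack.n_modalities
    if V == 1:
        return np.array([1.0])
    Gs = []
    for p in range(stack.n_modalities):
        Lp1 = stack.laplacians[p][0]
        Lp2 = stack.laplacians[p][1] if stack.n_orders >= 2 else Lp1
        Gs.append(state.lam * Lp1 + (1.0 - state.lam) * Lp2)
    Q = np.array([[float(np.sum(Gp * Gq)) for Gq in Gs] for Gp in Gs])
    M = _fused_low_rank(state.W, state.Lambda)  # I - W Lambda W^T
    f = np.array([-2.0 * float(np.sum(M * Gp)) for Gp in Gs])
    return solve_simplex_qp(Q, f)


class HighOrderLaplacianFusion(BaseEstimator):
    """Alternating minimizer of the fused-Laplacian objective.

    Parameters
    ----------
    n_components : int
        Embedding dimension c (typically the expected cluster number).
    max_iter : int
        Maximum number of full update cycles.
    tol : float
        Relative objective-change stopping tolerance.
    init : {"spectral", "random"}
        "spectral" starts W and H at the c smallest eigenvectors of the
        uniformly averaged order-1 Laplacian (deterministic); "random" uses
        a random orthonormal matrix.
    random_state : int or None
        Seed for random initialization only.
    check_monotone : bool
        Assert per-step monotone non-increase of the objective (cheap; a
        violation beyond tolerance indicates a bug).

    Attributes
    ----------
    embedding_ : ndarray of shape (n, c)
        The learned embedding H.
    W_, Lambda_, lambda_, mu_ : fitted factor, weights.
    objective_trace_ : list of float, non-increasing.
    """

    def __init__(
        self,
        n_components: int = 2,
        max_iter: int = 100,
        tol: float = 1e-6,
        init: str = "spectral",
        random_state: int | None = None,
        check_monotone: bool = True,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.init = init
        self.random_state = random_state
        self.check_monotone = check_monotone

    def _initial_state(self, stack: LaplacianStack) -> FusionState:
        n, c = stack.n_cells, self.n_components
        if not 1 <= c < n:
            raise ValueError(f"n_components={c} must satisfy 1 <= c < n={n}")
        V = stack.n_modalities
        mu0 = np.full(V, 1.0 / V)
        if self.init == "spectral":
            Lbar = stack.mixed(1, mu0)
            _, W0 = _eig_smallest(Lbar, c)
        elif self.init == "random":
            rng = np.random.default_rng(self.random_state)
            W0, _ = np.linalg.qr(rng.standard_normal((n, c)))
            W0 = _fix_signs(W0)
        else:
            raise ValueError(f"unknown init {self.init!r}")
        return FusionState(
            lam=0.5, mu=mu0, W=W0, Lambda=np.ones(c), H=W0.copy(), objective_trace=[]
        )

    def fit(self, stack, y=None) -> "HighOrderLaplacianFusion":
        stack = _coerce_stack(stack)
        state = self._initial_state(stack)
        prev = objective_value(state, stack)
        state.objective_trace.append(prev)

        def _step(name, apply):
            nonlocal prev
            apply()
            if self.check_monotone:
                now = objective_value(state, stack)
                if now > prev + 1e-9 * max(1.0, abs(prev)):
                    raise RuntimeError(
                        f"objective increased during {name} update: {prev} -> {now}"
                    )
                prev = now

        for it in range(1, self.max_iter + 1):
            _step("lam", lambda: setattr(state, "lam", update_lambda(state, stack)))
            _step("W", lambda: setattr(state, "W", update_w_factor(state, stack)))
            _step("Lambda", lambda: setattr(state, "Lambda", update_lambda_diag(state, stack)))
            _step("H", lambda: setattr(state, "H", update_h(state)))
            _step("mu", lambda: setattr(state, "mu", update_mu(state, stack)))
            obj = objective_value(state, stack) if not self.check_monotone else prev
            last = state.objective_trace[-1]
            state.objective_trace.append(obj)
            state.n_iter = it
            prev = obj
            if abs(last - obj) <= self.tol * max(1.0, abs(last)):
                state.converged = True
                break

        self.state_ = state
        self.embedding_ = state.H
        self.W_ = state.W
        self.Lambda_ = state.Lambda
        self.lambda_ = state.lam
        self.mu_ = state.mu
        self.objective_trace_ = state.objective_trace
        self.n_iter_ = state.n_iter
        self.converged_ = state.converged
        return self

    def fit_transform(self, stack, y=None) -> np.ndarray:
        return self.fit(stack).embedding_


def fit_fusion(stack, n_components: int, **kwargs) -> FusionState:
    """Functional wrapper: run the optimizer and return its state."""
    est = HighOrderLaplacianFusion(n_components=n_components, **kwargs)
    est.fit(stack)
    return est.state_
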