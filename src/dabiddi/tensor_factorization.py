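"""Constrained CP factorization of a multi-view drug-similarity tensor.

The tensor chi (n_drugs x n_drugs x n_views) stacks symmetric similarity
matrices (structural, biological, target views).  It is decomposed into
factor matrices U, V (n_drugs x R) and W (n_views x R) by minimizing

    || chi - U o V o W ||_F^2  +  lambda1 ||U||_{2,1}  +  lambda2 tr(U^T L U)

where o is the CP outer product, the L2,1 norm sums the Euclidean norms of
the rows of U (row sparsity), and L is the graph Laplacian of the mean
similarity slice (smoothness of drug embeddings over the similarity graph).

Solver: block-coordinate descent — exact least squares for V and W via the
Khatri-Rao normal equations, and a proximal-gradient step (row-wise
shrinkage for the L2,1 term) for U with backtracking, so the objective
trace is non-increasing.  After fitting, columns of U are normalized to
unit norm with the scale pushed into W (canonical form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CTFConfig", "FactorSet", "build_similarity_tensor", "build_laplacian",
    "ctf_objective", "ctf_fit", "drug_ctf_embedding",
]


@dataclass(frozen=True)
class CTFConfig:
    rank: int = 16
    lambda1: float = 0.01
    lambda2: float = 0.01
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FactorSet:
    U: np.ndarray
    V: np.ndarray
    W: np.ndarray

    @property
    def rank(self) -> int:
        return self.U.shape[1]

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ir,jr,vr->ijv", self.U, self.V, self.W)


def build_similarity_tensor(slices, names=None) -> np.ndarray:
    """Stack per-view similarity matrices into chi, validating invariants."""
    chi = np.stack([np.asarray(s, dtype=float) for s in slices], axis=2)
    n = chi.shape[0]
    if chi.shape[1] != n:
        raise ValueError("similarity slices must be square")
    for v in range(chi.shape[2]):
        s = chi[:, :, v]
        if not np.allclose(s, s.T, atol=1e-8):
            raise ValueError(f"similarity slice {v} is not symmetric")
    if chi.min() < -1e-9 or chi.max() > 1 + 1e-9:
        raise ValueError("similarity entries must lie in [0, 1]")
    return np.clip(chi, 0.0, 1.0)


def build_laplacian(S: np.ndarray) -> np.ndarray:
    """Graph Laplacian L = D - S of a symmetric non-negative similarity."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    if S.min() < 0:
        raise ValueError("S must be non-negative")
    return np.diag(S.sum(axis=1)) - S


def _l21(U: np.ndarray) -> float:
    return float(np.linalg.norm(U, axis=1).sum())


def ctf_objective(chi: np.ndarray, factors: FactorSet, lambda1: float,
                  lambda2: float, L: np.ndarray = None) -> float:
    """The three-term CTF objective at the given factors."""
    chi = np.asarray(chi, dtype=float)
    resid = chi - factors.reconstruct()
    obj = float(np.sum(resid**2)) + lambda1 * _l21(factors.U)
    if lambda2 > 0:
        if L is None:
            raise ValueError("Laplacian required when lambda2 > 0")
        obj += lambda2 * float(np.trace(factors.U.T @ L @ factors.U))
    return obj


def _ls_update(chi: np.ndarray, A: np.ndarray, B: np.ndarray,
               mode: str) -> np.ndarray:
    """Exact least-squares CP update for one factor (V or W)."""
    if mode == "V":
        M = np.einsum("ijv,ir,vr->jr", chi, A, B)  # A=U, B=W
    else:  # W
        M = np.einsum("ijv,ir,jr->vr", chi, A, B)  # A=U, B=V
    G = (A.T @ A) * (B.T @ B)
    return np.linalg.solve(G + 1e-12 * np.eye(G.shape[0]), M.T).T


def _row_shrink(U: np.ndarray, t: float) -> np.ndarray:
    """Proximal operator of t * ||.||_{2,1} (row-wise soft threshold)."""
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    with np.errstate(over="ignore"):
        scale = np.maximum(0.0, 1.0 - t / np.maximum(norms, 1e-30))
    return U * scale


def ctf_fit(chi: np.ndarray, config: CTFConfig = CTFConfig(),
            L: np.ndarray = None):
    """Fit the constrained factorization; returns (FactorSet, objective trace).

    The Laplacian defaults to L = D - S with S the mean of the tensor's
    views.  The recorded objective never increases (up to 1e-8 slack).
    """
    chi = np.asarray(chi, dtype=float)
    n = chi.shape[0]
    R = config.rank
    if R > n:
        raise ValueError("rank may not exceed the number of drugs")
    if L is None:
        L = build_laplacian(chi.mean(axis=2)) if config.lambda2 > 0 else None

    # spectral initialization: top-R eigenvectors of the summed views,
    # scaled by |eigenvalue|^(1/2), with a small seeded perturbation
    rng = np.random.default_rng(config.seed)
    Ssum = chi.sum(axis=2)
    Ssum = (Ssum + Ssum.T) / 2
    evals, evecs = np.linalg.eigh(Ssum)
    order = np.argsort(-np.abs(evals))[:R]
    base = evecs[:, order] * np.sqrt(np.abs(evals[order]))[None, :]
    factors = FactorSet(
        U=base + 0.01 * rng.standard_normal((n, R)),
        V=base + 0.01 * rng.standard_normal((n, R)),
        W=rng.uniform(0.1, 1.0, size=(chi.shape[2], R)),
    )
    factors.W = _ls_update(chi, factors.U, factors.V, "W")

    def objective(U=None):
        f = factors if U is None else FactorSet(U, factors.V, factors.W)
        return ctf_objective(chi, f, config.lambda1, config.lambda2, L)

    trace = [objective()]
    for _ in range(config.max_iter):
        U, V, W = factors.U, factors.V, factors.W
        K_gram = (V.T @ V) * (W.T @ W)
        M = np.einsum("ijv,jr,vr->ir", chi, V, W)
        if config.lambda1 == 0:
            # smooth subproblem: U K + lambda2 L U = M (exact solve)
            if config.lambda2 > 0:
                from scipy.linalg import solve_sylvester
                U_new = solve_sylvester(config.lambda2 * L,
                                        K_gram + 1e-12 * np.eye(R), M)
            else:
                U_new = np.linalg.solve(
                    K_gram + 1e-12 * np.eye(R), M.T).T
            if objective(U_new) > objective() + 1e-12:  # safeguard
                U_new = U
        else:
            # proximal-gradient steps (row shrinkage for the L2,1 term)
            lip = 2.0 * np.linalg.norm(K_gram, 2)
            if config.lambda2 > 0:
                lip += 2.0 * config.lambda2 * np.linalg.norm(L, 2)
            U_new = U
            for _inner in range(10):
                grad = 2.0 * (U_new @ K_gram - M)
                if config.lambda2 > 0:
                    grad = grad + 2.0 * config.lambda2 * (L @ U_new)
                step = 1.0 / max(lip, 1e-12)
                cur = objective(U_new)
                for _bt in range(30):
                    cand = _row_shrink(U_new - step * grad,
                                       step * config.lambda1)
                    if objective(cand) <= cur + 1e-12:
                        U_new = cand
                        break
                    step *= 0.5
                else:
                    break
        factors.U = U_new
        # --- V, W: exact least squares -----------------------------------
        factors.V = _ls_update(chi, factors.U, factors.W, "V")
        factors.W = _ls_update(chi, factors.U, factors.V, "W")
        trace.append(objective())
        prev, curr = trace[-2], trace[-1]
        if abs(prev - curr) <= config.tol * max(abs(prev), 1e-12):
            break

    # canonical form: unit-norm columns of U, scales pushed into W
    norms = np.linalg.norm(factors.U, axis=0)
    nonzero = norms > 1e-12
    factors.U[:, nonzero] /= norms[nonzero]
    factors.W[:, nonzero] *= norms[nonzero]
    return factors, np.asarray(trace)


def drug_ctf_embedding(factors: FactorSet) -> np.ndarray:
    """Per-drug latent vectors: the rows of U (n_drugs x R)."""
    return factors.U.copy()
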