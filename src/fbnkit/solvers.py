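"""Proximal operators and the ADMM solver for sparse low-rank regression.

The network estimators minimise

    J(A) = ||X - X A||_F^2 + lam1 ||A||_1 + lam2 ||A||_*      s.t. diag(A) = 0

over the m x m coefficient matrix A, where X is the t x m (z-scored)
region-by-time matrix.  Both penalties are nonsmooth, so the problem is
split ADMM-style with two auxiliary copies of A: B carries the l1 penalty
plus the zero-diagonal constraint (prox = entrywise soft-threshold followed
by zeroing the diagonal) and C carries the trace-norm penalty (prox =
singular-value thresholding).  The consensus constraints A = B and A = C are
enforced through scaled dual variables; the A-update is a ridge-regularised
least-squares solve with a precomputed Cholesky factorisation.

The problem is convex, so the splitting converges to the global optimum;
stopping follows the usual combined absolute/relative residual rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = ["soft_threshold", "singular_value_threshold", "SolverReport", "admm_sparse_lowrank"]


def soft_threshold(M: np.ndarray, tau: float) -> np.ndarray:
    """Entrywise sign(M) * max(|M| - tau, 0); prox of tau*||.||_1."""
    if tau < 0:
        raise ValueError("threshold must be >= 0")
    M = np.asarray(M, dtype=float)
    return np.sign(M) * np.maximum(np.abs(M) - tau, 0.0)


def singular_value_threshold(M: np.ndarray, tau: float) -> np.ndarray:
    """Shrink singular values by tau; prox of tau*||.||_* (trace norm)."""
    if tau < 0:
        raise ValueError("threshold must be >= 0")
    M = np.asarray(M, dtype=float)
    try:
        u, s, vt = np.linalg.svd(M, full_matrices=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"SVD failed during singular value thresholding: {exc}")
    return (u * np.maximum(s - tau, 0.0)) @ vt


@dataclass
class SolverReport:
    """Diagnostics of one ADMM run."""

    objective_trajectory: list[float] = field(default_factory=list)
    iterations: int = 0
    primal_residual: float = np.inf
    dual_residual: float = np.inf
    converged: bool = False

    @property
    def final_objective(self) -> float:
        return self.objective_trajectory[-1] if self.objective_trajectory else np.inf

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "final_objective": self.final_objective,
            "primal_residual": self.primal_residual,
            "dual_residual": self.dual_residual,
            "converged": self.converged,
        }


def objective(X: np.ndarray, A: np.ndarray, lam1: float, lam2: float) -> float:
    """J(A) = ||X - XA||_F^2 + lam1 ||A||_1 + lam2 ||A||_*."""
    fit = np.linalg.norm(X - X @ A, "fro") ** 2
    val = fit + lam1 * np.abs(A).sum()
    if lam2 > 0:
        val += lam2 * np.linalg.svd(A, compute_uv=False).sum()
    return float(val)


def admm_sparse_lowrank(
    X: np.ndarray,
    lam1: float,
    lam2: float,
    rho: float = 1.0,
    max_iter: int = 2000,
    eps_abs: float = 1e-6,
    eps_rel: float = 1e-6,
) -> tuple[np.ndarray, SolverReport]:
    """Solve the zero-diagonal sparse low-rank regression for one subject.

    Returns the sparse iterate B (exact zeros, zero diagonal) and a report.
    """
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be >= 0")
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    G = X.T @ X
    eye = np.eye(m)

    def factor(rho_val: float):
        # A-update system (2 G + 2 rho I) A = 2 G + rho (B - U + C - V)
        return scipy.linalg.cho_factor(2.0 * G + 2.0 * rho_val * eye, lower=True)

    chol = factor(rho)
    B = np.zeros((m, m))
    C = np.zeros((m, m))
    U = np.zeros((m, m))
    V = np.zeros((m, m))
    report = SolverReport()
    sqrt2m = np.sqrt(2.0) * m

    for it in range(1, max_iter + 1):
        A = scipy.linalg.cho_solve(chol, 2.0 * G + rho * (B - U + C - V))

        B_old, C_old = B, C
        B = soft_threshold(A + U, lam1 / rho)
        np.fill_diagonal(B, 0.0)
        C = singular_value_threshold(A + V, lam2 / rho)

        U = U + A - B
        V = V + A - C

        r = np.sqrt(np.linalg.norm(A - B, "fro") ** 2 + np.linalg.norm(A - C, "fro") ** 2)
        s = rho * np.sqrt(
            np.linalg.norm(B - B_old, "fro") ** 2 + np.linalg.norm(C - C_old, "fro") ** 2
        )
        report.objective_trajectory.append(objective(X, B, lam1, lam2))
        report.iterations = it
        report.primal_residual = float(r)
        report.dual_residual = float(s)

        norm_ax = np.sqrt(2.0) * np.linalg.norm(A, "fro")
        norm_bc = np.sqrt(np.linalg.norm(B, "fro") ** 2 + np.linalg.norm(C, "fro") ** 2)
        norm_uv = rho * np.sqrt(np.linalg.norm(U, "fro") ** 2 + np.linalg.norm(V, "fro") ** 2)
        eps_pri = sqrt2m * eps_abs + eps_rel * max(norm_ax, norm_bc)
        eps_dual = sqrt2m * eps_abs + eps_rel * norm_uv
        if r <= eps_pri and s <= eps_dual:
            report.converged = True
            break

        # residual balancing: scale rho (and the scaled duals) when the
        # primal and dual residuals drift apart by more than 10x
        if r > 10.0 * s:
            rho *= 2.0
            U /= 2.0
            V /= 2.0
            chol = factor(rho)
        elif s > 10.0 * r:
            rho /= 2.0
            U *= 2.0
            V *= 2.0
            chol = factor(rho)

    return B, report
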