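"""Stiefel-manifold geometry and Riemannian minimizers.

The Stiefel manifold St(n, R) is the set of n x R matrices with orthonormal
columns.  Each embedding sub-problem is a smooth minimization over such a
manifold; this module provides the geometric primitives (random point, tangent
projection, QR retraction) and two Riemannian optimizers: a limited-memory
BFGS (the workhorse) and a steepest-descent/Armijo baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StiefelPoint",
    "OptimizerOptions",
    "OptimizerTrace",
    "OptimizerError",
    "random_stiefel",
    "tangent_project",
    "qr_retract",
    "lrbfgs_minimize",
    "steepest_descent_armijo",
]

_ORTHO_TOL = 1e-10


class OptimizerError(RuntimeError):
    """Raised when an optimizer encounters a non-finite value; carries the trace."""

    def __init__(self, message: str, trace: "OptimizerTrace | None" = None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class StiefelPoint:
    """An element of St(n, R): an n x R matrix with orthonormal columns."""

    matrix: np.ndarray

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2:
            raise ValueError("StiefelPoint requires a 2-d matrix")
        n, r = mat.shape
        if r > n:
            raise ValueError(f"invalid dimensions: R={r} exceeds n={n}")
        gram_err = np.max(np.abs(mat.T @ mat - np.eye(r)))
        if gram_err > _ORTHO_TOL:
            raise ValueError(
                f"columns not orthonormal: max |X'X - I| = {gram_err:.3e}"
            )
        object.__setattr__(self, "matrix", mat)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def R(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class OptimizerOptions:
    """Knobs shared by both Riemannian minimizers.

    ``memory_size`` is the LRBFGS history length (ignored by steepest
    descent).  The line search is backtracking Armijo: start at
    ``initial_step``, multiply by ``contraction`` until the sufficient
    decrease condition with constant ``sufficient_decrease`` holds.
    """

    memory_size: int = 8
    max_iters: int = 200
    grad_tol: float = 1e-6
    initial_step: float = 1.0
    contraction: float = 0.5
    sufficient_decrease: float = 1e-4
    max_backtracks: int = 50

    def __post_init__(self):
        if self.memory_size < 1:
            raise ValueError("memory_size must be >= 1")
        if not 0.0 < self.contraction < 1.0:
            raise ValueError("contraction must lie in (0, 1)")
        if not 0.0 < self.sufficient_decrease < 1.0:
            raise ValueError("sufficient_decrease must lie in (0, 1)")
        if self.grad_tol < 0:
            raise ValueError("grad_tol must be nonnegative")


@dataclass
class OptimizerTrace:
    """Per-iteration diagnostics of a single minimization run."""

    objective: list[float] = field(default_factory=list)
    grad_norm: list[float] = field(default_factory=list)
    step_size: list[float] = field(default_factory=list)
    termination: str = ""

    @property
    def iterations(self) -> int:
        return len(self.step_size)


def _qr_positive(mat: np.ndarray) -> np.ndarray:
    """Thin QR factor with the sign fix making diag(R) nonnegative."""
    q, r = np.linalg.qr(mat)
    diag = np.diag(r)
    if np.min(np.abs(diag)) < 1e-12 * max(1.0, np.max(np.abs(diag), initial=0.0)):
        raise np.linalg.LinAlgError("matrix numerically rank-deficient in QR retraction")
    signs = np.where(diag < 0, -1.0, 1.0)
    return q * signs


def random_stiefel(n: int, R: int, seed: int) -> StiefelPoint:
    """Uniform-ish random point: QR of an n x R standard-normal matrix.

    Deterministic given ``seed``.  The nonnegative-diagonal sign convention
    makes the factorization unique.
    """
    if R > n:
        raise ValueError(f"invalid dimensions: R={R} exceeds n={n}")
    rng = np.random.default_rng(seed)
    gauss = rng.standard_normal((n, R))
    return StiefelPoint(_qr_positive(gauss))


def tangent_project(X: StiefelPoint, G: np.ndarray) -> np.ndarray:
    """Orthogonal projection of an ambient matrix onto the tangent space at X.

    Returns ``G - X sym(X'G)`` with sym(A) = (A + A')/2; the result V
    satisfies sym(X'V) = 0.
    """
    G = np.asarray(G, dtype=float)
    if G.shape != X.matrix.shape:
        raise ValueError(f"shape mismatch: expected {X.matrix.shape}, got {G.shape}")
    xtg = X.matrix.T @ G
    return G - X.matrix @ ((xtg + xtg.T) / 2.0)


def qr_retract(X: StiefelPoint, V: np.ndarray) -> StiefelPoint:
    """QR retraction: map X + V back onto the manifold."""
    V = np.asarray(V, dtype=float)
    if V.shape != X.matrix.shape:
        raise ValueError(f"shape mismatch: expected {X.matrix.shape}, got {V.shape}")
    return StiefelPoint(_qr_positive(X.matrix + V))


def _inner(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum(a * b))


def _check_finite(value: float, what: str, trace: OptimizerTrace):
    if not np.isfinite(value):
        raise OptimizerError(f"non-finite {what} encountered during search", trace)


def _armijo_search(f, X, direction, f0, slope, opts, trace):
    """Backtracking line search; returns (step, new point, new value) or None."""
    step = opts.initial_step
    for _ in range(opts.max_backtracks):
        try:
            candidate = qr_retract(X, step * direction)
        except np.linalg.LinAlgError:
            step *= opts.contraction
            continue
        f_new = float(f(candidate.matrix))
        _check_finite(f_new, "objective", trace)
        if f_new <= f0 + opts.sufficient_decrease * step * slope:
            return step, candidate, f_new
        step *= opts.contraction
    return None


def _riemannian_grad(grad, X, trace):
    egrad = np.asarray(grad(X.matrix), dtype=float)
    if not np.all(np.isfinite(egrad)):
        raise OptimizerError("non-finite gradient encountered during search", trace)
    return tangent_project(X, egrad)


def steepest_descent_armijo(
    f, grad, X0: StiefelPoint, opts: OptimizerOptions | None = None
) -> tuple[StiefelPoint, OptimizerTrace]:
    """Riemannian steepest descent with Armijo backtracking line search.

    ``f`` maps an n x R array to a scalar; ``grad`` returns the Euclidean
    gradient as an n x R array.  The search direction is the negated
    Riemannian gradient, followed by a QR retraction.
    """
    opts = opts or OptimizerOptions()
    trace = OptimizerTrace()
    X = X0
    f_curr = float(f(X.matrix))
    _check_finite(f_curr, "objective", trace)
    trace.objective.append(f_curr)

    for _ in range(opts.max_iters):
        rgrad = _riemannian_grad(grad, X, trace)
        gnorm = float(np.linalg.norm(rgrad))
        trace.grad_norm.append(gnorm)
        if gnorm <= opts.grad_tol:
            trace.termination = "grad_tol"
            return X, trace

        direction = -rgrad
        slope = -gnorm**2
        result = _armijo_search(f, X, direction, f_curr, slope, opts, trace)
        if result is None:
            trace.termination = "line_search_failure"
            return X, trace
        step, X, f_curr = result
        trace.step_size.append(step)
        trace.objective.append(f_curr)

    trace.grad_norm.append(float(np.linalg.norm(_riemannian_grad(grad, X, trace))))
    trace.termination = "max_iters"
    return X, trace


def lrbfgs_minimize(
    f, grad, X0: StiefelPoint, opts: OptimizerOptions | None = None
) -> tuple[StiefelPoint, OptimizerTrace]:
    """Limited-memory Riemannian BFGS over a Stiefel manifold.

    Standard two-loop recursion on Riemannian gradients.  History pairs
    (s_k, y_k) are carried to the new tangent space by projection-based
    vector transport; pairs with non-positive curvature <s, y> are dropped,
    which keeps the implicit inverse-Hessian approximation positive
    definite (a cheap stand-in for the Wolfe curvature condition).
    Globalized by Armijo backtracking along the quasi-Newton direction,
    falling back to steepest descent when the direction fails to descend.
    """
    opts = opts or OptimizerOptions()
    trace = OptimizerTrace()
    X = X0
    f_curr = float(f(X.matrix))
    _check_finite(f_curr, "objective", trace)
    trace.objective.append(f_curr)

    rgrad = _riemannian_grad(grad, X, trace)
    history: list[tuple[np.ndarray, np.ndarray, float]] = []  # (s, y, rho)

    for _ in range(opts.max_iters):
        gnorm = float(np.linalg.norm(rgrad))
        trace.grad_norm.append(gnorm)
        if gnorm <= opts.grad_tol:
            trace.termination = "grad_tol"
            return X, trace

        # Two-loop recursion for the quasi-Newton direction.
        q = rgrad.copy()
        alphas = []
        for s, y, rho in reversed(history):
            a = rho * _inner(s, q)
            alphas.append(a)
            q -= a * y
        if history:
            s_last, y_last, _ = history[-1]
            gamma = _inner(s_last, y_last) / _inner(y_last, y_last)
            q *= gamma
        for (s, y, rho), a in zip(history, reversed(alphas)):
            b = rho * _inner(y, q)
            q += (a - b) * s
        direction = -q

        slope = _inner(rgrad, direction)
        if slope >= 0:  # not a descent direction: reset to steepest descent
            history.clear()
            direction = -rgrad
            slope = -gnorm**2

        result = _armijo_search(f, X, direction, f_curr, slope, opts, trace)
        if result is None and history:
            history.clear()
            direction = -rgrad
            slope = -gnorm**2
            result = _armijo_search(f, X, direction, f_curr, slope, opts, trace)
        if result is None:
            trace.termination = "line_search_failure"
            return X, trace

        step, X_new, f_new = result
        trace.step_size.append(step)
        trace.objective.append(f_new)

        rgrad_new = _riemannian_grad(grad, X_new, trace)
        # Transport step and gradient difference to the new tangent space.
        s_new = tangent_project(X_new, step * direction)
        y_new = rgrad_new - tangent_project(X_new, rgrad)
        sy = _inner(s_new, y_new)
        history = [
            (tangent_project(X_new, s), tangent_project(X_new, y), rho)
            for s, y, rho in history
        ]
        history = [
            (s, y, 1.0 / _inner(s, y))
            for s, y, _ in history
            if _inner(s, y) > 1e-14
        ]
        if sy > 1e-14:
            history.append((s_new, y_new, 1.0 / sy))
        if len(history) > opts.memory_size:
            history = history[-opts.memory_size :]

        X, f_curr, rgrad = X_new, f_new, rgrad_new

    trace.grad_norm.append(float(np.linalg.norm(rgrad)))
    trace.termination = "max_iters"
    return X, trace
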