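"""Epsilon-insensitive support vector regression on precomputed kernels.

Solves the SVR dual

    max  -1/2 (a - a*)' K (a - a*) - eps (a + a*)' 1 + (a - a*)' y
    s.t. 0 <= a_i, a*_i <= C,   (a - a*)' 1 = 0

by sequential minimal optimization (SMO). Because a_i * a*_i = 0 at the
optimum, the solver works with the net multipliers beta = a - a* in the
box [-C, C], turning the dual into a box-constrained concave problem with
an L1 term and a single equality constraint (one shared bias b0). Each
iteration selects the maximal KKT-violating pair — the row forcing the
largest lower bound on b0 against the row forcing the smallest upper
bound — and minimizes the two-variable piecewise-quadratic subproblem
exactly (breakpoints where a multiplier changes sign included), so the
dual objective is monotone. Ties break at the lowest row index, making
the solver fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SVRProblem",
    "SVRModel",
    "KKTReport",
    "SVRConvergenceError",
    "fit_epsilon_svr",
    "svr_predict",
    "kkt_report",
    "dual_objective",
]

_SNAP = 1e-12


@dataclass
class SVRProblem:
    """An SVR training instance on a precomputed (PSD) kernel."""

    K: np.ndarray
    y: np.ndarray
    C: float
    eps: float
    tol: float = 1e-3
    max_passes: int = 10_000

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if self.K.shape[0] != self.y.shape[0]:
            raise ValueError("K row count must match len(y)")
        if not np.allclose(self.K, self.K.T, atol=1e-9):
            raise ValueError("K must be symmetric")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.eps < 0:
            raise ValueError("eps must be nonnegative")


@dataclass
class SVRModel:
    """Dual solution: net multipliers, bias, and convergence diagnostics."""

    beta_dual: np.ndarray
    b0: float
    objective_value: float
    n_iterations: int
    max_kkt_violation: float
    C: float
    eps: float
    sv_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sv_indices = np.nonzero(self.beta_dual != 0.0)[0]

    @property
    def n_support_vectors(self) -> int:
        return len(self.sv_indices)


class SVRConvergenceError(RuntimeError):
    """SMO did not reach the KKT tolerance; carries the best iterate."""

    def __init__(self, message: str, model: SVRModel):
        super().__init__(message)
        self.model = model


def dual_objective(K: np.ndarray, y: np.ndarray, beta: np.ndarray, eps: float) -> float:
    """Dual objective (to be maximized) at net multipliers beta."""
    return float(-0.5 * beta @ K @ beta - eps * np.abs(beta).sum() + beta @ y)


def _bias_bounds(beta, g, C, eps):
    """Per-row admissible interval [b_lo_i, b_hi_i] for the shared bias.

    Derived from the KKT conditions with residual r_i = y_i - (K beta)_i - b:
    beta_i in (0, C) forces r_i = eps, beta_i = C allows r_i >= eps, and
    mirrored for the negative side; beta_i = 0 allows |r_i| <= eps.
    """
    v_minus = -g - eps  # bias making r_i = +eps
    v_plus = -g + eps   # bias making r_i = -eps
    at_upper = beta >= C - _SNAP
    at_lower = beta <= -C + _SNAP
    pos = beta > 0
    neg = beta < 0
    b_lo = np.where(pos, v_minus, np.where(neg, v_plus, v_minus))
    b_hi = np.where(pos, v_minus, np.where(neg, v_plus, v_plus))
    b_lo = np.where(at_upper, -np.inf, b_lo)
    b_hi = np.where(at_lower, np.inf, b_hi)
    return b_lo, b_hi


def _pair_step(beta_i, beta_j, g_i, g_j, eta, C, eps):
    """Exact minimizer of the two-variable subproblem along beta_i + delta,
    beta_j - delta (the equality constraint is preserved)."""
    L = max(-C - beta_i, beta_j - C)
    H = min(C - beta_i, beta_j + C)
    if H <= L:
        return 0.0
    grad = g_i - g_j

    def phi(d):
        return (
            0.5 * eta * d * d
            + grad * d
            + eps * (abs(beta_i + d) - abs(beta_i) + abs(beta_j - d) - abs(beta_j))
        )

    cands = [L, H]
    for bp in (-beta_i, beta_j):
        if L < bp < H:
            cands.append(bp)
    if eta > 1e-14:
        for s_i in (-1.0, 1.0):
            for s_j in (-1.0, 1.0):
                d = -(grad + eps * (s_i - s_j)) / eta
                if L < d < H:
                    cands.append(d)
    best, best_val = 0.0, 0.0
    for d in cands:
        val = phi(d)
        if val < best_val - 0.0:
            best, best_val = d, val
    return best


def fit_epsilon_svr(prob: SVRProblem, seed: int | None = None) -> SVRModel:
    """Fit the epsilon-SVR dual by SMO on the precomputed kernel.

    ``seed`` is accepted for interface uniformity; the solver itself is
    deterministic (maximal-violating-pair selection with lowest-index
    tie-break).
    """
    K, y, C, eps = prob.K, prob.y, prob.C, prob.eps
    n = len(y)
    beta = np.zeros(n)
    g = -y.copy()  # gradient of the smooth part: K beta - y
    max_iter = prob.max_passes * max(n, 1)

    it = 0
    violation = np.inf
    while it < max_iter:
        b_lo, b_hi = _bias_bounds(beta, g, C, eps)
        i = int(np.argmax(b_lo))
        j = int(np.argmin(b_hi))
        violation = b_lo[i] - b_hi[j]
        if violation <= prob.tol:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        delta = _pair_step(beta[i], beta[j], g[i], g[j], eta, C, eps)
        if delta == 0.0:
            # numerically stalled pair: try the runner-up on each side
            delta, i, j = _fallback_step(beta, g, b_lo, b_hi, K, C, eps, i, j)
            if delta == 0.0:
                break
        beta[i] += delta
        beta[j] -= delta
        for idx in (i, j):
            if abs(beta[idx]) < _SNAP:
                beta[idx] = 0.0
            elif abs(beta[idx] - C) < _SNAP:
                beta[idx] = C
            elif abs(beta[idx] + C) < _SNAP:
                beta[idx] = -C
        g += delta * (K[:, i] - K[:, j])
        it += 1

    b0 = _bias_from_solution(beta, g, C, eps)
    model = SVRModel(
        beta_dual=beta,
        b0=b0,
        objective_value=dual_objective(K, y, beta, eps),
        n_iterations=it,
        max_kkt_violation=max(float(violation), 0.0),
        C=C,
        eps=eps,
    )
    if violation > prob.tol:
        raise SVRConvergenceError(
            f"SMO did not converge: KKT violation {violation:.3g} > tol "
            f"{prob.tol:.3g} after {it} pair updates",
            model,
        )
    return model


def _fallback_step(beta, g, b_lo, b_hi, K, C, eps, i0, j0):
    order_i = np.argsort(-b_lo)[:4]
    order_j = np.argsort(b_hi)[:4]
    for i in order_i:
        for j in order_j:
            if i == j or (i == i0 and j == j0):
                continue
            if b_lo[i] - b_hi[j] <= 0:
                continue
            eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
            d = _pair_step(beta[i], beta[j], g[i], g[j], eta, C, eps)
            if d != 0.0:
                return d, int(i), int(j)
    return 0.0, i0, j0


def _bias_from_solution(beta, g, C, eps):
    free = (np.abs(beta) > 0) & (np.abs(beta) < C)
    if free.any():
        vals = np.where(beta > 0, -g - eps, -g + eps)
        return float(vals[free].mean())
    b_lo, b_hi = _bias_bounds(beta, g, C, eps)
    lo, hi = b_lo.max(), b_hi.min()
    if not np.isfinite(lo):
        lo = hi
    if not np.isfinite(hi):
        hi = lo
    return float((lo + hi) / 2.0)


def svr_predict(model: SVRModel, K_cross: np.ndarray) -> np.ndarray:
    """Predict from the dual solution: f = K_cross beta + b0."""
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != len(model.beta_dual):
        raise ValueError(
            f"K_cross has {K_cross.shape[1]} columns but the model was trained "
            f"on {len(model.beta_dual)} rows"
        )
    return K_cross @ model.beta_dual + model.b0


@dataclass
class KKTReport:
    max_violation: float
    residuals: np.ndarray
    classification: np.ndarray  # "inside" / "margin" / "bound"


def kkt_report(model: SVRModel, prob: SVRProblem) -> KKTReport:
    """Check complementary slackness of a (purportedly) fitted model.

    For each training row with residual r_i = y_i - f_i:
    beta_i = 0 requires |r_i| <= eps; 0 < |beta_i| < C pins r_i at the
    tube edge sign(beta_i) * eps; |beta_i| = C requires the residual to
    be at or beyond the tube edge.
    """
    beta, C, eps = model.beta_dual, model.C, model.eps
    f = prob.K @ beta + model.b0
    r = prob.y - f
    viol = np.empty_like(r)
    cls = np.empty(len(r), dtype=object)
    inside = beta == 0.0
    at_bound = np.abs(beta) >= C - _SNAP
    free = ~inside & ~at_bound
    viol[inside] = np.maximum(np.abs(r[inside]) - eps, 0.0)
    viol[free] = np.abs(r[free] - np.sign(beta[free]) * eps)
    upper = at_bound & (beta > 0)
    lower = at_bound & (beta < 0)
    viol[upper] = np.maximum(eps - r[upper], 0.0)
    viol[lower] = np.maximum(r[lower] + eps, 0.0)
    cls[inside] = "inside"
    cls[free] = "margin"
    cls[at_bound] = "bound"
    return KKTReport(
        max_violation=float(viol.max()) if len(r) else 0.0,
        residuals=r,
        classification=cls,
    )
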