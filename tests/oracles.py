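"""Independent reference solvers used to pin the shrinkage operators.

Both routes deliberately avoid the formulas under test: the structured
prox is solved as an explicit quadratic program (epigraph variables and
linear inequalities, SLSQP), and the nuclear-norm prox through the
Burer-Monteiro factorization ``tau/2 (||U||^2 + ||V||^2) +
1/2 ||U V^T - M||^2`` minimized by L-BFGS with random restarts (its
global minimum coincides with the convex optimum at full factor rank).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def prox_oracle_qp(h, groups, w_g, mu):
    """argmin (mu/2)||h - s||^2 + sum_g w_g ||s_g||_inf by SLSQP.

    Epigraph form: variables (s, t); minimize (mu/2)||h - s||^2 + w^T t
    subject to -t_g <= s_p <= t_g for every pixel p of every group g.
    """
    h = np.asarray(h, dtype=float)
    m = h.size
    G = groups.n_groups
    nv = m + G
    rows = []
    for gi in range(G):
        for p in groups.indices[gi]:
            r = np.zeros(nv)
            r[m + gi] = 1.0
            r[p] = -1.0
            rows.append(r)
            r = np.zeros(nv)
            r[m + gi] = 1.0
            r[p] = 1.0
            rows.append(r)
    A = np.array(rows)

    def fun(z):
        s = z[:m]
        return 0.5 * mu * np.sum((h - s) ** 2) + np.dot(w_g, z[m:])

    def jac(z):
        return np.concatenate([mu * (z[:m] - h), w_g])

    cons = [{"type": "ineq", "fun": lambda z: A @ z, "jac": lambda z: A}]
    z0 = np.concatenate([np.zeros(m), np.full(G, np.abs(h).max() + 1.0)])
    res = minimize(
        fun, z0, jac=jac, method="SLSQP", constraints=cons,
        options={"maxiter": 500, "ftol": 1e-14},
    )
    # polish: SLSQP sometimes stops with a line-search warning right at
    # the optimum; a warm restart either improves or confirms the point
    res2 = minimize(
        fun, res.x, jac=jac, method="SLSQP", constraints=cons,
        options={"maxiter": 500, "ftol": 1e-14},
    )
    best = res2 if res2.fun <= res.fun else res
    return best.x[:m]


def svt_oracle(M, tau, seed=0, restarts=3):
    """argmin tau ||X||_* + 1/2 ||X - M||_F^2 via factored minimization."""
    M = np.asarray(M, dtype=float)
    m, n = M.shape
    r = min(m, n)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        z0 = rng.normal(scale=0.5, size=(m + n) * r)

        def fun(z):
            U = z[: m * r].reshape(m, r)
            V = z[m * r:].reshape(n, r)
            R = U @ V.T - M
            f = 0.5 * tau * (np.sum(U * U) + np.sum(V * V)) + 0.5 * np.sum(R * R)
            g = np.concatenate(
                [(tau * U + R @ V).ravel(), (tau * V + R.T @ U).ravel()]
            )
            return f, g

        res = minimize(
            fun, z0, jac=True, method="L-BFGS-B",
            options={"maxiter": 3000, "ftol": 1e-16, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    U = best.x[: m * r].reshape(m, r)
    V = best.x[m * r:].reshape(n, r)
    return U @ V.T


def finite_difference_jacobian(warp_fn, tau, eps=1e-5):
    """Central finite differences of a vectorized warp in each parameter."""
    tau = np.asarray(tau, dtype=float)
    cols = []
    for k in range(tau.size):
        tp = tau.copy()
        tp[k] += eps
        tm = tau.copy()
        tm[k] -= eps
        cols.append((warp_fn(tp) - warp_fn(tm)) / (2 * eps))
    return np.column_stack(cols)
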