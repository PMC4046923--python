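"""Numba kernels for compositionally adjusting a substitution matrix.

The adjusted joint distribution Q minimizes KL(Q || Q0) subject to

* row marginals  = query composition c1,
* column marginals = subject composition c2,
* relative entropy D(Q || c1 x c2) = H_target (the base matrix entropy).

The stationarity condition of the Lagrangian gives, for a multiplier nu
on the entropy constraint,

    q_ab  proportional to  [q0_ab * (c1_a c2_b)^nu]^(1/(1+nu)) * exp(A_a + B_b),

so for fixed nu the problem is a matrix-scaling (Sinkhorn) problem in
(A, B), and nu is a scalar root-finding problem on the achieved relative
entropy, which is monotone decreasing in nu (nu -> inf collapses Q onto
the independent product, entropy -> 0).  The multiplicative form keeps
every q_ab strictly positive, so no clamping of negative entries is ever
required.  The scalar root is found by bracketing plus the Illinois
variant of regula falsi; Sinkhorn iterations are warm-started between
nu evaluations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LN2 = 0.6931471805599453


@njit(cache=True)
def _scale_to_marginals(K, c1, c2, u, v, max_iter, tol):
    """Sinkhorn scaling of kernel K to marginals (c1, c2), in place on u, v.

    Returns the final row-marginal residual (max abs).
    """
    n = K.shape[0]
    err = 1.0
    for _ in range(max_iter):
        # v-update
        for j in range(n):
            s = 0.0
            for i in range(n):
                s += K[i, j] * u[i]
            v[j] = c2[j] / s
        # u-update
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += K[i, j] * v[j]
            u[i] = c1[i] / s
        # column residual (rows are exact right after the u-update)
        err = 0.0
        for j in range(n):
            s = 0.0
            for i in range(n):
                s += K[i, j] * u[i] * v[j]
            d = abs(s - c2[j])
            if d > err:
                err = d
        if err < tol:
            break
    return err


@njit(cache=True)
def _entropy_at_nu(logq0, logpp, c1, c2, nu, u, v, inner_iter, inner_tol):
    """Solve the Sinkhorn subproblem at a fixed nu; return (q, H_bits, err)."""
    n = logq0.shape[0]
    K = np.empty((n, n))
    denom = 1.0 + nu
    for i in range(n):
        for j in range(n):
            K[i, j] = np.exp((logq0[i, j] + nu * logpp[i, j]) / denom)
    err = _scale_to_marginals(K, c1, c2, u, v, inner_iter, inner_tol)
    q = np.empty((n, n))
    H = 0.0
    for i in range(n):
        for j in range(n):
            qij = K[i, j] * u[i] * v[j]
            q[i, j] = qij
            H += qij * (np.log(qij) - logpp[i, j])
    return q, H / LN2, err


@njit(cache=True)
def adjust_joint(q0, c1, c2, h_target, max_outer=100, tol=1e-10,
                 inner_iter=2000, inner_tol=1e-12):
    """Entropy-constrained compositional adjustment.

    Returns (q, converged).  On bracketing or iteration failure the last
    iterate is returned with converged = False; callers fall back to the
    base matrix in that case.
    """
    n = q0.shape[0]
    logq0 = np.log(q0)
    logpp = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            logpp[i, j] = np.log(c1[i]) + np.log(c2[j])
    u = np.ones(n)
    v = np.ones(n)

    q, h, err = _entropy_at_nu(logq0, logpp, c1, c2, 0.0, u, v, inner_iter, inner_tol)
    f0 = h - h_target
    if abs(f0) < tol and err < inner_tol * 10:
        return q, True

    # bracket the root: f is decreasing in nu
    if f0 > 0.0:
        a, fa = 0.0, f0
        b = 0.25
        fb = f0
        for _ in range(60):
            q, h, err = _entropy_at_nu(logq0, logpp, c1, c2, b, u, v, inner_iter, inner_tol)
            fb = h - h_target
            if fb < 0.0:
                break
            a, fa = b, fb
            b *= 2.0
        if fb >= 0.0:
            return q, False
    else:
        b, fb = 0.0, f0
        a = -0.25
        fa = f0
        ok = False
        for _ in range(60):
            q, h, err = _entropy_at_nu(logq0, logpp, c1, c2, a, u, v, inner_iter, inner_tol)
            fa = h - h_target
            if fa > 0.0:
                ok = True
                break
            b, fb = a, fa
            a = -1.0 + (1.0 + a) * 0.5
            if 1.0 + a < 1e-6:
                break
        if not ok:
            return q, False

    # Illinois regula falsi on [a, b]
    side = 0
    nu = 0.5 * (a + b)
    for _ in range(max_outer):
        nu = (a * fb - b * fa) / (fb - fa)
        if nu <= a or nu >= b:  # a < b always holds by construction
            nu = 0.5 * (a + b)
        q, h, err = _entropy_at_nu(logq0, logpp, c1, c2, nu, u, v, inner_iter, inner_tol)
        f = h - h_target
        if abs(f) < tol:
            return q, err < 1e-8
        if f * fa < 0.0:
            b, fb = nu, f
            if side == -1:
                fa *= 0.5
            side = -1
        else:
            a, fa = nu, f
            if side == 1:
                fb *= 0.5
            side = 1
    return q, False
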