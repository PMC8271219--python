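"""Numba kernels for ensemble steady-state search and stochastic simulation.

The ensemble stage integrates ~10^5-10^6 trajectories of a small shifted-Hill
ODE system, which is far too many for per-call scipy solvers. The strategy
here is: (1) an adaptive embedded Runge-Kutta (Bogacki-Shampine 3(2), FSAL)
carries each trajectory into the basin of an attractor, stopping on a
relative-residual test; (2) a damped Newton iteration with the analytic
Jacobian polishes the point to near machine precision, which makes the
deduplication of attractors across initial conditions unambiguous. Stability
of the polished roots is certified afterwards (in Python) via Jacobian
eigenvalues.

All kernels take the flat parameter representation: per-node ``g``/``k``
arrays and per-edge ``src``/``tgt``/``lam``/``nh``/``x0e`` arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Relative-residual scales: a point is "settled" when
# max_i |dX_i/dt| / max(X_i, 1) drops below the tolerance.
_SETTLE_COARSE = 1e-3  # hand over to Newton
_SETTLE_FINE = 1e-6  # acceptable without Newton polish
_NEWTON_TOL = 1e-10


@njit(cache=True)
def rhs(x, g, k, src, tgt, lam, nh, x0e, out):
    """dX/dt for the shifted-Hill system, written into ``out``."""
    n = x.shape[0]
    for i in range(n):
        out[i] = 1.0
    for e in range(src.shape[0]):
        u = x[src[e]] / x0e[e]
        p = 1.0
        for _ in range(int(nh[e])):
            p *= u
        out[tgt[e]] *= lam[e] + (1.0 - lam[e]) / (1.0 + p)
    for i in range(n):
        out[i] = g[i] * out[i] - k[i] * x[i]


@njit(cache=True)
def jacobian(x, g, k, src, tgt, lam, nh, x0e):
    """Analytic Jacobian of the shifted-Hill system at ``x``."""
    n = x.shape[0]
    ne = src.shape[0]
    h = np.empty(ne)
    dh = np.empty(ne)
    prod = np.ones(n)
    for e in range(ne):
        u = x[src[e]] / x0e[e]
        m = int(nh[e])
        p = 1.0
        pm1 = 1.0  # u^(m-1)
        for q in range(m):
            if q == m - 1:
                pm1 = p
            p *= u
        denom = 1.0 + p
        h[e] = lam[e] + (1.0 - lam[e]) / denom
        dh[e] = -(1.0 - lam[e]) * m * pm1 / (x0e[e] * denom * denom)
        prod[tgt[e]] *= h[e]
    jac = np.zeros((n, n))
    for e in range(ne):
        i = tgt[e]
        # product of the other incoming multipliers times dH_e/dx_src
        jac[i, src[e]] += g[i] * (prod[i] / h[e]) * dh[e]
    for i in range(n):
        jac[i, i] -= k[i]
    return jac


@njit(cache=True)
def _rel_residual(x, f):
    res = 0.0
    for i in range(x.shape[0]):
        d = x[i] if x[i] > 1.0 else 1.0
        r = abs(f[i]) / d
        if r > res:
            res = r
    return res


@njit(cache=True)
def integrate_settle(x, g, k, src, tgt, lam, nh, x0e, t_budget, settle_rel, rtol, atol):
    """Advance ``x`` in place until the relative residual settles or the time
    budget is spent. Returns True when settled."""
    n = x.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    xtmp = np.empty(n)
    xnew = np.empty(n)
    rhs(x, g, k, src, tgt, lam, nh, x0e, k1)
    t = 0.0
    h = 0.01
    while t < t_budget:
        if _rel_residual(x, k1) < settle_rel:
            return True
        if h > t_budget - t:
            h = t_budget - t
        for i in range(n):
            v = x[i] + 0.5 * h * k1[i]
            xtmp[i] = v if v > 0.0 else 0.0
        rhs(xtmp, g, k, src, tgt, lam, nh, x0e, k2)
        for i in range(n):
            v = x[i] + 0.75 * h * k2[i]
            xtmp[i] = v if v > 0.0 else 0.0
        rhs(xtmp, g, k, src, tgt, lam, nh, x0e, k3)
        for i in range(n):
            v = x[i] + h * (2.0 / 9.0 * k1[i] + 1.0 / 3.0 * k2[i] + 4.0 / 9.0 * k3[i])
            xnew[i] = v if v > 0.0 else 0.0
        rhs(xnew, g, k, src, tgt, lam, nh, x0e, k4)
        errnorm = 0.0
        for i in range(n):
            err = h * (
                -5.0 / 72.0 * k1[i] + 1.0 / 12.0 * k2[i] + 1.0 / 9.0 * k3[i] - 1.0 / 8.0 * k4[i]
            )
            ax = abs(x[i])
            axn = abs(xnew[i])
            sc = atol + rtol * (ax if ax > axn else axn)
            e = abs(err) / sc
            if e > errnorm:
                errnorm = e
        if errnorm <= 1.0:
            t += h
            for i in range(n):
                x[i] = xnew[i]
                k1[i] = k4[i]  # FSAL
        if errnorm > 1e-12:
            fac = 0.9 * errnorm ** (-1.0 / 3.0)
        else:
            fac = 5.0
        if fac > 5.0:
            fac = 5.0
        elif fac < 0.2:
            fac = 0.2
        h *= fac
        if h < 1e-10:
            h = 1e-10
    rhs(x, g, k, src, tgt, lam, nh, x0e, k1)
    return _rel_residual(x, k1) < settle_rel


@njit(cache=True)
def newton_polish(x, g, k, src, tgt, lam, nh, x0e, tol, max_iter):
    """Damped Newton root polish in place; True on convergence to ``tol``."""
    n = x.shape[0]
    f = np.empty(n)
    for _ in range(max_iter):
        rhs(x, g, k, src, tgt, lam, nh, x0e, f)
        res = _rel_residual(x, f)
        if res < tol:
            return True
        jac = jacobian(x, g, k, src, tgt, lam, nh, x0e)
        dx = np.linalg.lstsq(jac, f)[0]
        # backtrack: keep the iterate non-negative and the residual decreasing
        step = 1.0
        ok = False
        for _bt in range(12):
            good = True
            for i in range(n):
                if x[i] - step * dx[i] < 0.0:
                    good = False
                    break
            if good:
                for i in range(n):
                    f[i] = x[i] - step * dx[i]  # reuse f as candidate
                ok = True
                break
            step *= 0.5
        if not ok:
            return False
        for i in range(n):
            x[i] = f[i]
    rhs(x, g, k, src, tgt, lam, nh, x0e, f)
    return _rel_residual(x, f) < tol


@njit(cache=True)
def find_steady_state(x, g, k, src, tgt, lam, nh, x0e, t_coarse, t_max):
    """Integrate-then-polish search from one initial condition (in place).

    Returns (converged, residual). A point counts as converged when Newton
    reaches _NEWTON_TOL or, failing that, when continued integration settles
    to _SETTLE_FINE within the t_max budget.
    """
    f = np.empty(x.shape[0])
    settled = integrate_settle(
        x, g, k, src, tgt, lam, nh, x0e, t_coarse, _SETTLE_COARSE, 1e-4, 1e-9
    )
    if settled and newton_polish(x, g, k, src, tgt, lam, nh, x0e, _NEWTON_TOL, 50):
        rhs(x, g, k, src, tgt, lam, nh, x0e, f)
        return True, _rel_residual(x, f)
    settled = integrate_settle(
        x, g, k, src, tgt, lam, nh, x0e, t_max - t_coarse, _SETTLE_FINE, 1e-6, 1e-10
    )
    if settled and newton_polish(x, g, k, src, tgt, lam, nh, x0e, _NEWTON_TOL, 50):
        rhs(x, g, k, src, tgt, lam, nh, x0e, f)
        return True, _rel_residual(x, f)
    rhs(x, g, k, src, tgt, lam, nh, x0e, f)
    return settled, _rel_residual(x, f)


@njit(cache=True)
def enumerate_ensemble_kernel(
    g2, k2, lam2, nh2, x02, src, tgt, ics, dedup_tol, t_coarse, t_max, max_states
):
    """Distinct steady states per parameter set from many initial conditions.

    ``ics`` has shape (n_sets, n_init, n_nodes). States are deduplicated on
    Euclidean distance in log2 concentration space. Returns (states, counts,
    residuals, n_nonconverged).
    """
    n_sets, n_init, n = ics.shape
    states = np.zeros((n_sets, max_states, n))
    resid = np.zeros((n_sets, max_states))
    counts = np.zeros(n_sets, np.int64)
    nonconv = np.zeros(n_sets, np.int64)
    tol2 = dedup_tol * dedup_tol
    for s in range(n_sets):
        g = g2[s]
        kk = k2[s]
        lam = lam2[s]
        nh = nh2[s]
        x0e = x02[s]
        for ii in range(n_init):
            x = ics[s, ii].copy()
            ok, res = find_steady_state(x, g, kk, src, tgt, lam, nh, x0e, t_coarse, t_max)
            if not ok:
                nonconv[s] += 1
                continue
            found = False
            for q in range(counts[s]):
                d2 = 0.0
                for i in range(n):
                    a = np.log2(x[i] if x[i] > 1e-12 else 1e-12)
                    b = np.log2(states[s, q, i] if states[s, q, i] > 1e-12 else 1e-12)
                    d2 += (a - b) * (a - b)
                if d2 < tol2:
                    found = True
                    break
            if not found and counts[s] < max_states:
                states[s, counts[s]] = x
                resid[s, counts[s]] = res
                counts[s] += 1
    return states, counts, resid, nonconv


@njit(cache=True)
def euler_maruyama_kernel(
    xinit, g, k, src, tgt, lam, nh, x0e, dt, n_steps, eta, seed, record_every
):
    """Euler-Maruyama trajectory with per-node additive noise amplitude eta.

    X(t+dt) = X + f(X) dt + eta * sqrt(dt) * N(0,1), clipped at 0. Records
    every ``record_every`` steps (including t=0). Returns (records, n_recorded,
    ok); ok is False on numerical blow-up (|X| > 1e9).
    """
    np.random.seed(seed)
    n = xinit.shape[0]
    n_rec = n_steps // record_every + 1
    out = np.empty((n_rec, n))
    x = xinit.copy()
    f = np.empty(n)
    for i in range(n):
        out[0, i] = x[i]
    r = 1
    sq = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        rhs(x, g, k, src, tgt, lam, nh, x0e, f)
        for i in range(n):
            x[i] += f[i] * dt + eta[i] * sq * np.random.normal()
            if x[i] < 0.0:
                x[i] = 0.0
            elif x[i] > 1e9:
                return out, r, False
        if step % record_every == 0:
            for i in range(n):
                out[r, i] = x[i]
            r += 1
    return out, r, True
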