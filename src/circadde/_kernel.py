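"""Compiled fixed-step integrator for constant-delay gene-network DDEs.

The kernel integrates systems of the form

    dx_i/dt = scale_i * prod_k F_k(x_{r_k}(t - tau_k)) * s_i(t) - d_i x_i

where each modulation factor F_k is a bounded rational function of one
delayed regulator concentration and s_i(t) is an optional smoothed
square-wave forcing multiplier on one variable.  States and derivatives
are stored on a uniform grid; delayed values are obtained by cubic
Hermite interpolation, which keeps the dense-output error at the order
of the RK4 step.

Constraint: the step size must not exceed the smallest positive delay,
otherwise stage lookups would need extrapolation beyond the grid.
"""

import numpy as np
from numba import njit

__all__ = ["rk4_delay_integrate"]


@njit(cache=True, inline="always")
def _hermite(tq, t0, h, X, D, Dh, n_pre, i_last):
    """Cubic Hermite interpolation of the state grid at time tq.

    Intervals lying entirely in the history segment (t <= 0) use the
    history derivative Dh: the solution's right-derivative at t = 0
    must not leak across the initial discontinuity."""
    s = (tq - t0) / h
    i = int(np.floor(s))
    if i < 0:
        i = 0
    if i > i_last - 1:
        i = i_last - 1
    u = s - i
    h00 = (1.0 + 2.0 * u) * (1.0 - u) * (1.0 - u)
    h10 = u * (1.0 - u) * (1.0 - u)
    h01 = u * u * (3.0 - 2.0 * u)
    h11 = u * u * (u - 1.0)
    n = X.shape[1]
    out = np.empty(n)
    in_hist = i + 1 <= n_pre
    for j in range(n):
        d0 = Dh[i, j] if in_hist else D[i, j]
        d1 = Dh[i + 1, j] if in_hist else D[i + 1, j]
        out[j] = (
            h00 * X[i, j]
            + h10 * h * d0
            + h01 * X[i + 1, j]
            + h11 * h * d1
        )
    return out


@njit(cache=True, inline="always")
def _forcing(t, gene, f_gene, f_str, f_period, f_on, f_t0, f_smooth):
    if gene != f_gene or f_str == 0.0:
        return 1.0
    p = (t - f_t0) % f_period
    if f_smooth <= 0.0:
        g = 1.0 if p < f_on else 0.0
    else:
        g = 0.0
        for k in range(-1, 2):
            q = p - k * f_period
            up = 1.0 / (1.0 + np.exp(-q / f_smooth))
            dn = 1.0 / (1.0 + np.exp((q - f_on) / f_smooth))
            g += up * dn
    return 1.0 + f_str * g


@njit(cache=True)
def _rhs(t, y, t0, h, X, D, Dh, n_pre, i_last,
         deg, scale,
         fg, fr, frole, ftau, fexp, fbas, ffold, fsat, fkd,
         force_gene, force_str, force_period, force_on, force_t0,
         force_smooth, has_factors):
    n = y.shape[0]
    dx = np.empty(n)
    nf = fg.shape[0]
    for g in range(n):
        if has_factors[g]:
            p = scale[g]
        else:
            p = 0.0
        dx[g] = p
    # delayed lookups cached per distinct delay would help, but nf is
    # small (<= ~16) and the Hermite evaluation is cheap
    for k in range(nf):
        g = fg[k]
        tau = ftau[k]
        if tau > 0.0:
            xl = _hermite(t - tau, t0, h, X, D, Dh, n_pre, i_last)
            xr = xl[fr[k]]
        else:
            xr = y[fr[k]]
        xr = xr * fkd[k]
        if xr < 0.0:
            xr = 0.0
        u = (xr / fsat[k]) ** fexp[k]
        if frole[k] > 0:
            F = fbas[k] * (1.0 + ffold[k] * u) / (1.0 + u)
        else:
            F = fbas[k] / (1.0 + u)
        dx[g] *= F
    for g in range(n):
        dx[g] *= _forcing(t, g, force_gene, force_str, force_period,
                          force_on, force_t0, force_smooth)
        dx[g] = dx[g] - deg[g] * y[g]
    return dx


@njit(cache=True)
def rk4_delay_integrate(h, n_pre, n_steps, X, D, Dh,
                        deg, scale,
                        fg, fr, frole, ftau, fexp, fbas, ffold, fsat, fkd,
                        force_gene, force_str, force_period, force_on,
                        force_t0, force_smooth, has_factors):
    """Integrate in place.

    X, D are (n_pre + n_steps + 1, n) arrays whose first n_pre + 1 rows
    (times t0 .. 0) hold the history and its time derivative.  Returns 0
    on success or the row index of the first non-finite state.
    """
    t0 = -n_pre * h
    for i in range(n_pre, n_pre + n_steps):
        t = t0 + i * h
        y = X[i]
        k1 = _rhs(t, y, t0, h, X, D, Dh, n_pre, i,
                  deg, scale, fg, fr, frole, ftau, fexp, fbas, ffold,
                  fsat, fkd, force_gene, force_str, force_period,
                  force_on, force_t0, force_smooth, has_factors)
        D[i] = k1
        y2 = y + 0.5 * h * k1
        k2 = _rhs(t + 0.5 * h, y2, t0, h, X, D, Dh, n_pre, i,
                  deg, scale, fg, fr, frole, ftau, fexp, fbas, ffold,
                  fsat, fkd, force_gene, force_str, force_period,
                  force_on, force_t0, force_smooth, has_factors)
        y3 = y + 0.5 * h * k2
        k3 = _rhs(t + 0.5 * h, y3, t0, h, X, D, Dh, n_pre, i,
                  deg, scale, fg, fr, frole, ftau, fexp, fbas, ffold,
                  fsat, fkd, force_gene, force_str, force_period,
                  force_on, force_t0, force_smooth, has_factors)
        y4 = y + h * k3
        k4 = _rhs(t + h, y4, t0, h, X, D, Dh, n_pre, i,
                  deg, scale, fg, fr, frole, ftau, fexp, fbas, ffold,
                  fsat, fkd, force_gene, force_str, force_period,
                  force_on, force_t0, force_smooth, has_factors)
        xn = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        ok = True
        for j in range(xn.shape[0]):
            if not np.isfinite(xn[j]):
                ok = False
        if not ok:
            return i + 1
        X[i + 1] = xn
    i = n_pre + n_steps
    D[i] = _rhs(t0 + i * h, X[i], t0, h, X, D, Dh, n_pre, i,
                deg, scale, fg, fr, frole, ftau, fexp, fbas, ffold,
                fsat, fkd, force_gene, force_str, force_period,
                force_on, force_t0, force_smooth, has_factors)
    return 0
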