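"""Numba-compiled inner loops for the neural and hemodynamic integrators.

Kept free of Python objects: plain float64 arrays and scalars in, arrays
out, so the surrounding modules own all validation and bookkeeping.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(inline="always")
def _transfer(x, d):
    # x/(1 - exp(-d*x)) with the removable singularity at x = 0 handled by
    # the series 1/d + x/2 + d*x^2/12.
    u = d * x
    if abs(u) < 1e-6:
        return 1.0 / d + x / 2.0 + d * x * x / 12.0
    return x / (1.0 - np.exp(-u))


@njit
def dmf_euler(C, J, G, a_E, b_E, d_E, a_I, b_I, d_I, gamma, tau_E, tau_I,
              I0, W_E, W_I, w_plus, J_NMDA, sigma, dt, n_steps, rec_every,
              seed, S0_E, S0_I):
    """Euler-Maruyama integration of the coupled E-I gating equations.

    Records window-averaged rates, currents and gating variables every
    ``rec_every`` steps.  Returns (status, bad_region, bad_step, rE, rI,
    IE, II, SE_rec, SI_rec, SE, SI); status 0 = ok, 1 = non-finite state.
    """
    N = C.shape[0]
    n_rec = n_steps // rec_every
    rE = np.empty((N, n_rec))
    rI = np.empty((N, n_rec))
    IEr = np.empty((N, n_rec))
    IIr = np.empty((N, n_rec))
    SEr = np.empty((N, n_rec))
    SIr = np.empty((N, n_rec))
    accrE = np.zeros(N)
    accrI = np.zeros(N)
    accIE = np.zeros(N)
    accII = np.zeros(N)
    accSE = np.zeros(N)
    accSI = np.zeros(N)

    np.random.seed(seed)
    SE = S0_E.copy()
    SI = S0_I.copy()
    sqdt = np.sqrt(dt)
    inv_rec = 1.0 / rec_every

    for step in range(n_steps):
        coupling = C @ SE
        for i in range(N):
            IE = W_E * I0 + w_plus * J_NMDA * SE[i] \
                + G * J_NMDA * coupling[i] - J[i] * SI[i]
            II = W_I * I0 + J_NMDA * SE[i] - SI[i]
            re = _transfer(a_E * IE - b_E, d_E)
            ri = _transfer(a_I * II - b_I, d_I)
            SE[i] = SE[i] + dt * (-SE[i] / tau_E
                                  + (1.0 - SE[i]) * gamma * re) \
                + sqdt * sigma * np.random.standard_normal()
            SI[i] = SI[i] + dt * (-SI[i] / tau_I + ri / 1000.0) \
                + sqdt * sigma * np.random.standard_normal()
            if SE[i] < 0.0:
                SE[i] = 0.0
            elif SE[i] > 1.0:
                SE[i] = 1.0
            if SI[i] < 0.0:
                SI[i] = 0.0
            elif SI[i] > 1.0:
                SI[i] = 1.0
            if not (np.isfinite(SE[i]) and np.isfinite(SI[i])):
                return 1, i, step, rE, rI, IEr, IIr, SEr, SIr, SE, SI
            accrE[i] += re
            accrI[i] += ri
            accIE[i] += IE
            accII[i] += II
            accSE[i] += SE[i]
            accSI[i] += SI[i]
        if (step + 1) % rec_every == 0:
            k = (step + 1) // rec_every - 1
            for i in range(N):
                rE[i, k] = accrE[i] * inv_rec
                rI[i, k] = accrI[i] * inv_rec
                IEr[i, k] = accIE[i] * inv_rec
                IIr[i, k] = accII[i] * inv_rec
                SEr[i, k] = accSE[i] * inv_rec
                SIr[i, k] = accSI[i] * inv_rec
                accrE[i] = 0.0
                accrI[i] = 0.0
                accIE[i] = 0.0
                accII[i] = 0.0
                accSE[i] = 0.0
                accSI[i] = 0.0
    return 0, -1, -1, rE, rI, IEr, IIr, SEr, SIr, SE, SI


@njit
def balloon_euler(drive, dt_s, kappa, gamma_h, tau_h, alpha, rho,
                  V0, k1, k2, k3):
    """Explicit Euler on the hemodynamic state, log-transformed f, v, q.

    ``drive`` is the N x T vasodilatory drive (already c1*rate + c0).
    Returns (status, bad_region, bad_step, B) where B is the N x T BOLD
    signal sampled on the input grid; status 1 flags a non-finite state.
    """
    N, T = drive.shape
    s = np.zeros(N)
    lf = np.zeros(N)   # log f, rest f = 1
    lv = np.zeros(N)
    lq = np.zeros(N)
    B = np.empty((N, T))
    ia = 1.0 / alpha
    log1mrho = np.log(1.0 - rho)
    for t in range(T):
        for i in range(N):
            f = np.exp(lf[i])
            v = np.exp(lv[i])
            q = np.exp(lq[i])
            ds = drive[i, t] - kappa * s[i] - gamma_h * (f - 1.0)
            dlf = s[i] / f
            dlv = (f - v ** ia) / (tau_h * v)
            E = 1.0 - np.exp(log1mrho / f)  # oxygen extraction E(f, rho)
            dlq = (f * E / rho - q * v ** (ia - 1.0)) / (tau_h * q)
            s[i] += dt_s * ds
            lf[i] += dt_s * dlf
            lv[i] += dt_s * dlv
            lq[i] += dt_s * dlq
            v = np.exp(lv[i])
            q = np.exp(lq[i])
            if not (np.isfinite(s[i]) and np.isfinite(v) and np.isfinite(q)):
                return 1, i, t, B
            B[i, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v)
                            + k3 * (1.0 - v))
    return 0, -1, -1, B
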