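"""Compiled inner loops for network integration.

The ODE right-hand side and the fixed-step RK4 loop live here as numba
kernels so that a full 6-source, 300-ms simulation costs ~1 ms, which is
what makes finite-difference Jacobians and multi-start model fitting
tractable on one CPU.  Everything is written against plain float64 arrays;
the object-level API in :mod:`cmcdcm.network` prepares those arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# state columns: 0..3 = V(SS,SP,II,DP), 4..7 = I(SS,SP,II,DP)


@njit(cache=True)
def _rhs(y, af, ab, c, kap, gam, r, u, gdsp, gdii, bnorm, dyn, out):
    n = y.shape[0]
    sig = np.empty((n, 4))
    for i in range(n):
        for p in range(4):
            sig[i, p] = 1.0 / (1.0 + np.exp(-r[i] * y[i, p])) - 0.5
    for i in range(n):
        fdr = 0.0
        bdr = 0.0
        for j in range(n):
            fdr += af[i, j] * sig[j, 1]  # SP output of lower sources
            bdr += ab[i, j] * sig[j, 3]  # DP output of higher sources
        g_spsp = gam[i, 7]
        g_iiii = gam[i, 5]
        if dyn:
            m = 0.0
            for j in range(n):
                m += bnorm[i, j] * sig[j, 3]
            if gdsp[i] != 0.0:
                g_spsp = g_spsp * np.exp(-gdsp[i] * (1.0 + m))
            if gdii[i] != 0.0:
                g_iiii = g_iiii * np.exp(-gdii[i] * (1.0 + m))
        s_ss = sig[i, 0]
        s_sp = sig[i, 1]
        s_ii = sig[i, 2]
        s_dp = sig[i, 3]
        # voltage derivatives
        out[i, 0] = y[i, 4]
        out[i, 1] = y[i, 5]
        out[i, 2] = y[i, 6]
        out[i, 3] = y[i, 7]
        # current derivatives (critically damped synaptic kernels)
        k = kap[i, 0]
        out[i, 4] = (
            k * (fdr - gam[i, 0] * s_ss - gam[i, 1] * s_sp - gam[i, 2] * s_ii + c[i] * u)
            - 2.0 * k * y[i, 4]
            - k * k * y[i, 0]
        )
        k = kap[i, 1]
        out[i, 5] = (
            k * (-bdr + gam[i, 6] * s_ss - g_spsp * s_sp) - 2.0 * k * y[i, 5] - k * k * y[i, 1]
        )
        k = kap[i, 2]
        out[i, 6] = (
            k * (-bdr + gam[i, 3] * s_ss + gam[i, 4] * s_dp - g_iiii * s_ii)
            - 2.0 * k * y[i, 6]
            - k * k * y[i, 2]
        )
        k = kap[i, 3]
        out[i, 7] = (
            k * (fdr - gam[i, 8] * s_dp - gam[i, 9] * s_ii) - 2.0 * k * y[i, 7] - k * k * y[i, 3]
        )


@njit(cache=True)
def _gauss_input(t, latency, dispersion, amplitude):
    z = (t - latency) / dispersion
    return amplitude * np.exp(-0.5 * z * z)


@njit(cache=True)
def integrate_rk4(
    y0,
    t0,
    n_steps,
    dt,
    af,
    ab,
    c,
    kap,
    gam,
    r,
    latency,
    dispersion,
    amplitude,
    gdsp,
    gdii,
    bnorm,
    dyn,
):
    """Fixed-step classical RK4 from state ``y0`` at ``t0``.

    Returns the trajectory array (n_steps + 1, n_sources, 8); row k is the
    state at t = t0 + k * dt.
    """
    n = af.shape[0]
    traj = np.zeros((n_steps + 1, n, 8))
    y = y0.copy()
    traj[0] = y
    k1 = np.empty((n, 8))
    k2 = np.empty((n, 8))
    k3 = np.empty((n, 8))
    k4 = np.empty((n, 8))
    ytmp = np.empty((n, 8))
    for step in range(n_steps):
        t = t0 + step * dt
        u0 = _gauss_input(t, latency, dispersion, amplitude)
        um = _gauss_input(t + 0.5 * dt, latency, dispersion, amplitude)
        u1 = _gauss_input(t + dt, latency, dispersion, amplitude)
        _rhs(y, af, ab, c, kap, gam, r, u0, gdsp, gdii, bnorm, dyn, k1)
        for i in range(n):
            for s in range(8):
                ytmp[i, s] = y[i, s] + 0.5 * dt * k1[i, s]
        _rhs(ytmp, af, ab, c, kap, gam, r, um, gdsp, gdii, bnorm, dyn, k2)
        for i in range(n):
            for s in range(8):
                ytmp[i, s] = y[i, s] + 0.5 * dt * k2[i, s]
        _rhs(ytmp, af, ab, c, kap, gam, r, um, gdsp, gdii, bnorm, dyn, k3)
        for i in range(n):
            for s in range(8):
                ytmp[i, s] = y[i, s] + dt * k3[i, s]
        _rhs(ytmp, af, ab, c, kap, gam, r, u1, gdsp, gdii, bnorm, dyn, k4)
        for i in range(n):
            for s in range(8):
                y[i, s] = y[i, s] + (dt / 6.0) * (
                    k1[i, s] + 2.0 * k2[i, s] + 2.0 * k3[i, s] + k4[i, s]
                )
                traj[step + 1, i, s] = y[i, s]
    return traj


def rhs_numpy(y, af, ab, c, kap, gam, r, u, gdsp=None, gdii=None, bnorm=None, dyn=False):
    """Pure-numpy reference of the compiled right-hand side (for testing)."""
    n = y.shape[0]
    out = np.empty_like(y)
    if gdsp is None:
        gdsp = np.zeros(n)
    if gdii is None:
        gdii = np.zeros(n)
    if bnorm is None:
        bnorm = np.zeros((n, n))
    _rhs.py_func(
        np.asarray(y, float),
        np.asarray(af, float),
        np.asarray(ab, float),
        np.asarray(c, float),
        np.asarray(kap, float),
        np.asarray(gam, float),
        np.asarray(r, float),
        float(u),
        np.asarray(gdsp, float),
        np.asarray(gdii, float),
        np.asarray(bnorm, float),
        bool(dyn),
        out,
    )
    return out
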