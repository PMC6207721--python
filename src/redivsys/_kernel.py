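"""Compiled inner loop of the hybrid lineage simulator.

One jitted routine advances a single cell: ODE species integrate the
deterministic rates (RK4 on the extensive counts), low-copy species fire
discrete reactions through the modified next-reaction method with
propensities ``M * f_r(X)`` frozen over short refresh windows, replication
initiates when the origin concentration reaches its threshold, and
scheduled divisions partition the molecules binomially.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# rate-law kind codes mirror redivsys.core
_CONST, _LIN, _MA, _HILL, _HILLR, _MM, _TL = 0, 1, 2, 3, 4, 5, 6

STATUS_OK = 0
STATUS_ODD_ORIGIN = 1
STATUS_BUFFER_FULL = 2


@njit(cache=False)
def _rates(kind, par, sidx, X, f):
    for r in range(kind.shape[0]):
        k = kind[r]
        if k == _CONST:
            f[r] = par[r, 0]
        elif k == _LIN:
            f[r] = par[r, 0] * X[sidx[r, 0]]
        elif k == _MA:
            f[r] = par[r, 0] * X[sidx[r, 0]] * X[sidx[r, 1]]
        elif k == _HILL:
            a = X[sidx[r, 0]]
            f[r] = par[r, 0] * a / (a + par[r, 1])
        elif k == _HILLR:
            a = X[sidx[r, 0]]
            p = X[sidx[r, 1]]
            f[r] = (par[r, 0] * a / (a + par[r, 1])) / (1.0 + (p / par[r, 2]) ** par[r, 3])
        elif k == _MM:
            s = X[sidx[r, 1]]
            f[r] = par[r, 0] * X[sidx[r, 0]] * s / (par[r, 1] + s)
        else:
            a = X[sidx[r, 1]]
            f[r] = (X[sidx[r, 0]] / par[r, 1]) * par[r, 0] * a / (a + par[r, 2])


@njit(cache=False)
def _deriv(kind, par, sidx, nu, mass, det_rxn, x, f, dx):
    """dx/dt for ODE-integrated reactions: M * nu_det f(X)."""
    M = 0.0
    for i in range(x.shape[0]):
        M += mass[i] * x[i]
    for i in range(x.shape[0]):
        dx[i] = 0.0
    Xl = x / M
    _rates(kind, par, sidx, Xl, f)
    for j in range(det_rxn.shape[0]):
        r = det_rxn[j]
        w = M * f[r]
        for i in range(x.shape[0]):
            if nu[i, r] != 0.0:
                dx[i] += w * nu[i, r]
    return M


@njit(cache=False)
def _growth(kind, par, sidx, nu, mass, x, f):
    M = 0.0
    for i in range(x.shape[0]):
        M += mass[i] * x[i]
    Xl = x / M
    _rates(kind, par, sidx, Xl, f)
    lam = 0.0
    for r in range(kind.shape[0]):
        mn = 0.0
        for i in range(x.shape[0]):
            mn += mass[i] * nu[i, r]
        lam += mn * f[r]
    return lam


@njit(cache=False)
def _rk4(kind, par, sidx, nu, mass, det_rxn, x, f, k1, k2, k3, k4, xtmp, dt):
    N = x.shape[0]
    _deriv(kind, par, sidx, nu, mass, det_rxn, x, f, k1)
    for i in range(N):
        xtmp[i] = x[i] + 0.5 * dt * k1[i]
    _deriv(kind, par, sidx, nu, mass, det_rxn, xtmp, f, k2)
    for i in range(N):
        xtmp[i] = x[i] + 0.5 * dt * k2[i]
    _deriv(kind, par, sidx, nu, mass, det_rxn, xtmp, f, k3)
    for i in range(N):
        xtmp[i] = x[i] + dt * k3[i]
    _deriv(kind, par, sidx, nu, mass, det_rxn, xtmp, f, k4)
    for i in range(N):
        x[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=False)
def _trunc_normal(mean, sd, lo, hi):
    if sd <= 0.0:
        return mean
    for _ in range(1000):
        v = np.random.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return mean


@njit(cache=False)
def run_lineage(
    kind, par, sidx, nu, mass,
    stoch_rxn, det_rxn, stoch_sp,
    x_init, O_init,
    Oc, tauCD,
    refresh, dt_max, sample_dt,
    t_end, max_divisions,
    rho_mean, rho_sd, rho_lo, rho_hi,
    deterministic_partition, track_complement,
    low_copy_bound, seed,
):
    """Simulate one lineage; returns sampled series, event logs and status."""
    np.random.seed(seed)
    N = x_init.shape[0]
    R = kind.shape[0]
    Rs = stoch_rxn.shape[0]

    x = x_init.copy()
    # integer-round the stochastic species (stochastic rounding)
    for i in range(N):
        if stoch_sp[i]:
            base = np.floor(x[i])
            if np.random.random() < x[i] - base:
                base += 1.0
            x[i] = base
    f = np.empty(R)
    dx = np.empty(N)
    k1 = np.empty(N)
    k2 = np.empty(N)
    k3 = np.empty(N)
    k4 = np.empty(N)
    xtmp = np.empty(N)
    xprev = np.empty(N)

    M = 0.0
    for i in range(N):
        M += mass[i] * x[i]
    O = O_init
    t = 0.0
    D = 0

    pend = np.empty(64)
    n_pend = 0

    T = np.zeros(Rs)
    P = np.empty(Rs)
    a_frozen = np.empty(Rs)
    for j in range(Rs):
        P[j] = -np.log(np.random.random())

    max_samp = int(t_end / sample_dt) + 4
    s_t = np.empty(max_samp)
    s_X = np.empty((max_samp, N))
    s_M = np.empty(max_samp)
    s_lam = np.empty(max_samp)
    s_O = np.empty(max_samp, dtype=np.int64)
    s_D = np.empty(max_samp, dtype=np.int64)
    i_samp = 0
    next_sample = 0.0

    max_ev = max_divisions + int(t_end * 0.5) + 64
    div_t = np.empty(max_ev)
    div_rho = np.empty(max_ev)
    div_Mb = np.empty(max_ev)
    div_Ma = np.empty(max_ev)
    i_div = 0
    ini_t = np.empty(max_ev)
    ini_M = np.empty(max_ev)
    ini_O = np.empty(max_ev, dtype=np.int64)
    i_ini = 0

    low_copy_hits = 0
    neg_clamps = 0
    status = STATUS_OK

    while t < t_end and D < max_divisions:
        # window end: refresh boundary, simulation end or next scheduled division
        t_div = pend[0] if n_pend > 0 else 1e300
        t_win = min(t + refresh, t_end)
        if t_div < t_win:
            t_win = t_div

        # frozen propensities of the stochastic reactions
        Xl = x / M
        _rates(kind, par, sidx, Xl, f)
        tau_best = 1e300
        j_best = -1
        for j in range(Rs):
            a_frozen[j] = M * f[stoch_rxn[j]]
            if a_frozen[j] > 0.0:
                tau = (P[j] - T[j]) / a_frozen[j]
                if tau < tau_best:
                    tau_best = tau
                    j_best = j
        t_event = t + tau_best
        fire = t_event <= t_win
        if not fire:
            t_event = t_win
        t_start = t

        # advance ODE species to t_event, watching initiation crossings
        n_det = det_rxn.shape[0]
        t_cur = t
        while t_cur < t_event - 1e-12:
            dt = t_event - t_cur
            if n_det > 0 and dt > dt_max:
                dt = dt_max
            M_prev = M
            for i in range(N):
                xprev[i] = x[i]
            if n_det > 0:
                # RK4 on the deterministic part
                _rk4(kind, par, sidx, nu, mass, det_rxn, x, f, k1, k2, k3, k4, xtmp, dt)
                M = 0.0
                for i in range(N):
                    if x[i] < 0.0:
                        x[i] = 0.0
                        neg_clamps += 1
                    M += mass[i] * x[i]

            # replication initiation: origin concentration reached Oc.
            # Land the step on the crossing (linear interpolation of the
            # crossing time, re-integration up to it), then fire.
            crossed = M * Oc >= O
            if crossed:
                denom = M - M_prev
                frac = 1.0 if denom <= 0.0 else (O / Oc - M_prev) / denom
                if frac < 0.0:
                    frac = 0.0
                if frac > 1.0:
                    frac = 1.0
                if 1e-9 < frac < 0.999999:
                    for i in range(N):
                        x[i] = xprev[i]
                    dt = frac * dt
                    _rk4(kind, par, sidx, nu, mass, det_rxn, x, f, k1, k2, k3, k4, xtmp, dt)
                    M = 0.0
                    for i in range(N):
                        if x[i] < 0.0:
                            x[i] = 0.0
                            neg_clamps += 1
                        M += mass[i] * x[i]
            t_cur += dt

            n_fire = 0
            if crossed:
                n_fire = 1
                while M * Oc >= O * (1 << n_fire):  # overlapping rounds
                    n_fire += 1
            for _ in range(n_fire):
                O *= 2
                if i_ini < max_ev:
                    ini_t[i_ini] = t_cur
                    ini_M[i_ini] = M
                    ini_O[i_ini] = O
                    i_ini += 1
                # insert scheduled division, keeping the queue sorted
                if n_pend >= 64:
                    status = STATUS_BUFFER_FULL
                    break
                td = t_cur + tauCD
                k = n_pend
                while k > 0 and pend[k - 1] > td:
                    pend[k] = pend[k - 1]
                    k -= 1
                pend[k] = td
                n_pend += 1
            if status != STATUS_OK:
                break
            # a division scheduled inside this window truncates it
            if n_pend > 0 and pend[0] < t_event:
                t_event = pend[0]
                fire = False

            # sampling grid
            while next_sample <= t_cur and i_samp < max_samp:
                s_t[i_samp] = t_cur
                for i in range(N):
                    s_X[i_samp, i] = x[i] / M
                s_M[i_samp] = M
                s_lam[i_samp] = _growth(kind, par, sidx, nu, mass, x, f)
                s_O[i_samp] = O
                s_D[i_samp] = D
                i_samp += 1
                next_sample += sample_dt
        if status != STATUS_OK:
            break

        # integrate the unit-exponential hazard clocks with the frozen propensities
        for j in range(Rs):
            T[j] += a_frozen[j] * (t_event - t_start)
        t = t_event

        if fire and j_best >= 0:
            r = stoch_rxn[j_best]
            for i in range(N):
                if nu[i, r] != 0.0:
                    x[i] += nu[i, r]
                    if x[i] < 0.0:
                        x[i] = 0.0
            M = 0.0
            for i in range(N):
                M += mass[i] * x[i]
            P[j_best] += -np.log(np.random.random())
            for i in range(N):
                if stoch_sp[i] and x[i] > low_copy_bound:
                    low_copy_hits += 1
        elif n_pend > 0 and t >= pend[0] - 1e-12:
            # division: partition molecules, halve origins
            if O % 2 != 0:
                status = STATUS_ODD_ORIGIN
                break
            rho = 0.5 if deterministic_partition else _trunc_normal(rho_mean, rho_sd, rho_lo, rho_hi)
            if track_complement:
                rho = 1.0 - rho
            M_before = M
            for i in range(N):
                if deterministic_partition:
                    x[i] *= rho
                elif stoch_sp[i]:
                    n_i = int(x[i] + 0.5)
                    x[i] = float(np.random.binomial(n_i, rho))
                else:
                    mu = rho * x[i]
                    sd = np.sqrt(rho * (1.0 - rho) * x[i]) if x[i] > 0 else 0.0
                    v = mu + sd * np.random.normal() if sd > 0 else mu
                    if v < 0.0:
                        v = 0.0
                    if v > x[i]:
                        v = x[i]
                    x[i] = v
            O //= 2
            D += 1
            M = 0.0
            for i in range(N):
                M += mass[i] * x[i]
            if i_div < max_ev:
                div_t[i_div] = t
                div_rho[i_div] = rho
                div_Mb[i_div] = M_before
                div_Ma[i_div] = M
                i_div += 1
            # drop the fired division
            for k in range(1, n_pend):
                pend[k - 1] = pend[k]
            n_pend -= 1

    return (status, t, D, low_copy_hits, neg_clamps,
            s_t[:i_samp], s_X[:i_samp], s_M[:i_samp], s_lam[:i_samp],
            s_O[:i_samp], s_D[:i_samp],
            div_t[:i_div], div_rho[:i_div], div_Mb[:i_div], div_Ma[:i_div],
            ini_t[:i_ini], ini_M[:i_ini], ini_O[:i_ini])
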