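"""Numba kernels: QSS root, ODE right-hand side, Rosenbrock integrator.

The structural system is four ODEs in (CT, RTC, CPT, RTP) — total drug and
total target in the central and peripheral compartments, all in nM — with the
unbound concentrations recovered algebraically from the quasi-steady-state
(QSS) quadratic at every evaluation.  The target turnover rate constant
``kout`` (default 20/day) makes the system stiff relative to horizons of
months, so the integrator is a 2(3) Rosenbrock pair (the ode23s scheme of
Shampine & Reichelt) with an analytic Jacobian; it takes day-scale steps in
smooth regions while remaining stable across the fast target mode.

Parameter array layout (length 11)::

    0 V1   1 V2   2 CL   3 Q
    4 R0C  5 KSSC 6 kintC
    7 R0P  8 KSSP 9 kintP
    10 kout

TMDD arms are switched off by setting the corresponding R0 to zero; the QSS
root then reduces exactly to C = CT and the compartment is linear.
"""

import math

import numpy as np
from numba import njit

# index constants for readability inside kernels
IV1, IV2, ICL, IQ = 0, 1, 2, 3
IR0C, IKSSC, IKINTC = 4, 5, 6
IR0P, IKSSP, IKINTP = 7, 8, 9
IKOUT = 10
NPARAM = 11

_D = 1.0 / (2.0 + math.sqrt(2.0))
_E32 = 6.0 + math.sqrt(2.0)


@njit(cache=True, fastmath=False)
def qss_root(ct, rt, kss):
    """Non-negative root of C^2 + (RT + KSS - CT) C - KSS CT = 0, clamped to [0, CT]."""
    b = ct - rt - kss
    s = math.sqrt(b * b + 4.0 * kss * ct)
    c = 0.5 * (b + s)
    if c < 0.0:
        c = 0.0
    elif c > ct:
        c = ct
    return c


@njit(cache=True)
def _qss_partials(ct, rt, kss):
    """(C, dC/dCT, dC/dRT) for the QSS root."""
    b = ct - rt - kss
    s = math.sqrt(b * b + 4.0 * kss * ct)
    if s < 1e-300:
        return 0.0, 0.5, -0.5
    c = 0.5 * (b + s)
    if c < 0.0:
        c = 0.0
    elif c > ct:
        c = ct
    dct = 0.5 * (1.0 + (b + 2.0 * kss) / s)
    drt = -0.5 * (1.0 + b / s)
    return c, dct, drt


@njit(cache=True)
def rhs(y, p, inrate, out):
    """Derivative of (CT, RTC, CPT, RTP); ``inrate`` is the drug input in nM/day."""
    ct, rtc, cpt, rtp = y[0], y[1], y[2], y[3]
    c = qss_root(ct, rtc, p[IKSSC])
    cp = qss_root(cpt, rtp, p[IKSSP])
    cmc = ct - c
    cmp_ = cpt - cp
    kout = p[IKOUT]
    k10 = p[ICL] / p[IV1]
    k12 = p[IQ] / p[IV1]
    k21 = p[IQ] / p[IV2]
    out[0] = inrate - k10 * c - k12 * c + k21 * cp - p[IKINTC] * cmc
    out[1] = p[IR0C] * kout - kout * (rtc - cmc) - p[IKINTC] * cmc
    out[2] = k12 * c - k21 * cp - p[IKINTP] * cmp_
    out[3] = p[IR0P] * kout - kout * (rtp - cmp_) - p[IKINTP] * cmp_


@njit(cache=True)
def _jac(y, p, J):
    ct, rtc, cpt, rtp = y[0], y[1], y[2], y[3]
    _, a1, a2 = _qss_partials(ct, rtc, p[IKSSC])
    _, b1, b2 = _qss_partials(cpt, rtp, p[IKSSP])
    kout = p[IKOUT]
    kintC = p[IKINTC]
    kintP = p[IKINTP]
    k10 = p[ICL] / p[IV1]
    k12 = p[IQ] / p[IV1]
    k21 = p[IQ] / p[IV2]
    ke = k10 + k12
    J[0, 0] = -ke * a1 - kintC * (1.0 - a1)
    J[0, 1] = -ke * a2 + kintC * a2
    J[0, 2] = k21 * b1
    J[0, 3] = k21 * b2
    J[1, 0] = (kout - kintC) * (1.0 - a1)
    J[1, 1] = -kout * (1.0 + a2) + kintC * a2
    J[1, 2] = 0.0
    J[1, 3] = 0.0
    J[2, 0] = k12 * a1
    J[2, 1] = k12 * a2
    J[2, 2] = -k21 * b1 - kintP * (1.0 - b1)
    J[2, 3] = -k21 * b2 + kintP * b2
    J[3, 0] = 0.0
    J[3, 1] = 0.0
    J[3, 2] = (kout - kintP) * (1.0 - b1)
    J[3, 3] = -kout * (1.0 + b2) + kintP * b2


@njit(cache=True)
def _lu4(A):
    """In-place LU with partial pivoting; returns pivot index array."""
    piv = np.empty(4, dtype=np.int64)
    for k in range(4):
        pk = k
        amax = abs(A[k, k])
        for i in range(k + 1, 4):
            if abs(A[i, k]) > amax:
                amax = abs(A[i, k])
                pk = i
        piv[k] = pk
        if pk != k:
            for j in range(4):
                tmp = A[k, j]
                A[k, j] = A[pk, j]
                A[pk, j] = tmp
        akk = A[k, k]
        if akk == 0.0:
            akk = 1e-300
            A[k, k] = akk
        for i in range(k + 1, 4):
            A[i, k] /= akk
            lik = A[i, k]
            for j in range(k + 1, 4):
                A[i, j] -= lik * A[k, j]
    return piv


@njit(cache=True)
def _lu_solve4(A, piv, b, x):
    for i in range(4):
        x[i] = b[i]
    for k in range(4):
        pk = piv[k]
        if pk != k:
            tmp = x[k]
            x[k] = x[pk]
            x[pk] = tmp
        for i in range(k + 1, 4):
            x[i] -= A[i, k] * x[k]
    for i in range(3, -1, -1):
        s = x[i]
        for j in range(i + 1, 4):
            s -= A[i, j] * x[j]
        x[i] = s / A[i, i]


@njit(cache=True)
def _integrate_interval(y, p, inrate, ta, tb, h0, rtol, atol):
    """Advance ``y`` in place from ta to tb under constant input. Returns (ok, h_next)."""
    t = ta
    h = h0
    span = tb - ta
    if h > span:
        h = span
    if h <= 0.0:
        h = span
    J = np.empty((4, 4))
    W = np.empty((4, 4))
    f0 = np.empty(4)
    f1 = np.empty(4)
    f2 = np.empty(4)
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    tmp = np.empty(4)
    ynew = np.empty(4)
    nfail = 0
    while t < tb - 1e-12 * max(1.0, abs(tb)):
        if h > tb - t:
            h = tb - t
        _jac(y, p, J)
        for i in range(4):
            for j in range(4):
                W[i, j] = -h * _D * J[i, j]
            W[i, i] += 1.0
        piv = _lu4(W)
        rhs(y, p, inrate, f0)
        _lu_solve4(W, piv, f0, k1)
        for i in range(4):
            tmp[i] = y[i] + 0.5 * h * k1[i]
        rhs(tmp, p, inrate, f1)
        for i in range(4):
            tmp[i] = f1[i] - k1[i]
        _lu_solve4(W, piv, tmp, k2)
        for i in range(4):
            k2[i] += k1[i]
        for i in range(4):
            ynew[i] = y[i] + h * k2[i]
        rhs(ynew, p, inrate, f2)
        for i in range(4):
            tmp[i] = f2[i] - _E32 * (k2[i] - f1[i]) - 2.0 * (k1[i] - f0[i])
        _lu_solve4(W, piv, tmp, k3)
        errnorm = 0.0
        for i in range(4):
            err = (h / 6.0) * (k1[i] - 2.0 * k2[i] + k3[i])
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            e = abs(err) / sc
            if e > errnorm:
                errnorm = e
        if errnorm <= 1.0:
            t += h
            for i in range(4):
                y[i] = ynew[i] if ynew[i] > 0.0 else 0.0
            fac = 0.9 * errnorm ** (-1.0 / 3.0) if errnorm > 1e-12 else 5.0
            if fac > 5.0:
                fac = 5.0
            h *= fac
            nfail = 0
        else:
            fac = 0.9 * errnorm ** (-1.0 / 3.0)
            if fac < 0.2:
                fac = 0.2
            h *= fac
            nfail += 1
            if h < 1e-12 or nfail > 60:
                return False, t
    return True, h


@njit(cache=True)
def _step_rosenbrock2(y, p, inrate, h, J, W, f0, f1, k1, k2, tmp):
    """One 2nd-order Rosenbrock step (no error control); y updated in place."""
    _jac(y, p, J)
    for i in range(4):
        for j in range(4):
            W[i, j] = -h * _D * J[i, j]
        W[i, i] += 1.0
    piv = _lu4(W)
    rhs(y, p, inrate, f0)
    _lu_solve4(W, piv, f0, k1)
    for i in range(4):
        tmp[i] = y[i] + 0.5 * h * k1[i]
    rhs(tmp, p, inrate, f1)
    for i in range(4):
        tmp[i] = f1[i] - k1[i]
    _lu_solve4(W, piv, tmp, k2)
    for i in range(4):
        yn = y[i] + h * (k2[i] + k1[i])
        y[i] = yn if yn > 0.0 else 0.0


_RAMP_SLOPE = 0.2    # step-size growth per day since the last dose boundary


@njit(cache=True)
def integrate_profile_fixed(p, y0, dose_t, dose_rate, dose_dur, out_times,
                            h0, hmax):
    """Deterministic fixed-schedule Rosenbrock integration.

    The step size ramps linearly from ``h0`` just after every infusion
    start/stop to ``hmax``, independent of the solution, so the integration
    error is a smooth function of the parameters — which keeps
    finite-difference gradients of the likelihood clean.  Accuracy is set by
    (h0, hmax); used by the estimation layer, not the reporting simulator.
    """
    nout = out_times.shape[0]
    nd = dose_t.shape[0]
    nodes = np.empty(2 * nd + nout + 1)
    m = 0
    nodes[m] = 0.0
    m += 1
    for k in range(nd):
        nodes[m] = dose_t[k]
        m += 1
        nodes[m] = dose_t[k] + dose_dur[k]
        m += 1
    for k in range(nout):
        nodes[m] = out_times[k]
        m += 1
    nodes = np.sort(nodes[:m])
    out = np.empty((nout, 4))
    y = y0.copy()
    t = 0.0
    iout = 0
    J = np.empty((4, 4))
    W = np.empty((4, 4))
    f0 = np.empty(4)
    f1 = np.empty(4)
    k1 = np.empty(4)
    k2 = np.empty(4)
    tmp = np.empty(4)
    last_bound = 0.0
    while iout < nout and out_times[iout] <= 1e-12:
        for i in range(4):
            out[iout, i] = y[i]
        iout += 1
    for inode in range(m):
        tb = nodes[inode]
        if tb <= t + 1e-12:
            continue
        if iout >= nout and tb > out_times[nout - 1]:
            break
        tmid = 0.5 * (t + tb)
        inrate = 0.0
        for k in range(nd):
            if dose_t[k] <= tmid < dose_t[k] + dose_dur[k]:
                inrate += dose_rate[k]
        tt = t
        while tt < tb - 1e-12 * max(1.0, abs(tb)):
            tau = tt - last_bound
            h = h0 + _RAMP_SLOPE * tau
            if h > hmax:
                h = hmax
            if h > tb - tt:
                h = tb - tt
            _step_rosenbrock2(y, p, inrate, h, J, W, f0, f1, k1, k2, tmp)
            tt += h
        t = tb
        # dose boundaries reset the ramp
        for k in range(nd):
            if (abs(dose_t[k] - t) <= 1e-9) or (abs(dose_t[k] + dose_dur[k] - t) <= 1e-9):
                last_bound = t
                break
        while iout < nout and abs(out_times[iout] - t) <= 1e-9 * max(1.0, t):
            for i in range(4):
                out[iout, i] = y[i]
            iout += 1
    return out, True, t


@njit(cache=True)
def integrate_profile(p, y0, dose_t, dose_rate, dose_dur, out_times, rtol, atol):
    """Integrate from t=0 through ``out_times`` with zero-order infusion inputs.

    dose_rate is in nM/day (already amount/duration/V1 in molar units).
    Returns (states (nout, 4), ok flag, time reached).
    """
    nout = out_times.shape[0]
    nd = dose_t.shape[0]
    # build merged node grid: 0, dose starts/stops, output times
    nodes = np.empty(2 * nd + nout + 1)
    m = 0
    nodes[m] = 0.0
    m += 1
    for k in range(nd):
        nodes[m] = dose_t[k]
        m += 1
        nodes[m] = dose_t[k] + dose_dur[k]
        m += 1
    for k in range(nout):
        nodes[m] = out_times[k]
        m += 1
    nodes = np.sort(nodes[:m])
    out = np.empty((nout, 4))
    y = y0.copy()
    t = 0.0
    h = 0.01
    iout = 0
    # record any output times at (or before) t=0
    while iout < nout and out_times[iout] <= 1e-12:
        for i in range(4):
            out[iout, i] = y[i]
        iout += 1
    for inode in range(m):
        tb = nodes[inode]
        if tb <= t + 1e-12:
            continue
        if iout >= nout and tb > out_times[nout - 1]:
            break
        # constant infusion rate on (t, tb): evaluate at midpoint
        tmid = 0.5 * (t + tb)
        inrate = 0.0
        for k in range(nd):
            if dose_t[k] <= tmid < dose_t[k] + dose_dur[k]:
                inrate += dose_rate[k]
        ok, h = _integrate_interval(y, p, inrate, t, tb, h, rtol, atol)
        if not ok:
            return out, False, t
        t = tb
        while iout < nout and abs(out_times[iout] - t) <= 1e-9 * max(1.0, t):
            for i in range(4):
                out[iout, i] = y[i]
            iout += 1
    return out, True, t


@njit(cache=True)
def linear2cpt_conc(V1, V2, CL, Q, dose_t, dose_rate, dose_dur, times, out):
    """Closed-form central concentration (nM) of the linear two-compartment
    model under superposed zero-order infusions.  dose_rate in nmol/day."""
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    ssum = k10 + k12 + k21
    disc = ssum * ssum - 4.0 * k10 * k21
    if disc < 0.0:
        disc = 0.0
    rt = math.sqrt(disc)
    alpha = 0.5 * (ssum + rt)
    beta = 0.5 * (ssum - rt)
    if beta < 1e-14:
        beta = 1e-14
    denom = alpha - beta
    if abs(denom) < 1e-14:
        denom = 1e-14
    ca = (alpha - k21) / denom
    cb = (k21 - beta) / denom
    nd = dose_t.shape[0]
    for it in range(times.shape[0]):
        t = times[it]
        conc = 0.0
        for k in range(nd):
            ts = t - dose_t[k]
            if ts <= 0.0:
                continue
            r = dose_rate[k] / V1
            # unit-step infusion response started at dose_t[k]
            u1 = r * (ca / alpha * (1.0 - math.exp(-alpha * ts))
                      + cb / beta * (1.0 - math.exp(-beta * ts)))
            conc += u1
            te = ts - dose_dur[k]
            if te > 0.0:
                u2 = r * (ca / alpha * (1.0 - math.exp(-alpha * te))
                          + cb / beta * (1.0 - math.exp(-beta * te)))
                conc -= u2
        out[it] = conc if conc > 0.0 else 0.0
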