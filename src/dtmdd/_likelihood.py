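"""Jitted marginal-likelihood kernels (Laplace approximation, FOCE-style).

For each subject the joint negative log density of data and random effects,

    U(eta) = sum_j [0.5 log 2pi + log sd_j + 0.5 ((y_j - f_j)/sd_j)^2]
           + sum_k [0.5 log 2pi + log omega_k + 0.5 (eta_k/omega_k)^2],

is minimised over the active random effects by damped Gauss-Newton with a
finite-difference residual Jacobian, and the marginal likelihood is
approximated by Laplace's method with the Gauss-Newton Hessian
H = G' W G + Omega^-1 (the standard FOCE approximation):

    -2 log l_i  ~=  2 U(eta_hat) - q log 2pi + log det H.

With all omegas zero this reduces exactly to the Gaussian residual sum.
Random effects are active only when their omega is positive *and* the
parameter is present in the subject's structural model (AS reference
subjects have no target, hence no R0 effects).
"""

import math

import numpy as np
from numba import njit

from . import _ode

LOG2PI = math.log(2.0 * math.pi)

#: p-array index for each eta slot (order V1, CL, V2, R0C, R0P)
ETA_PIDX = np.array([_ode.IV1, _ode.ICL, _ode.IV2, _ode.IR0C, _ode.IR0P],
                    dtype=np.int64)

_FD_H = 1e-4       # fd step on eta for the residual Jacobian
_DTOL = 1e-10      # inner-mode Newton-decrement tolerance (in units of U)
_BIG = 1e90


@njit(cache=True)
def _apply_eta(p_typ, eta5, eta_pidx, out_p):
    for i in range(p_typ.shape[0]):
        out_p[i] = p_typ[i]
    for k in range(5):
        if eta5[k] != 0.0:
            out_p[eta_pidx[k]] = p_typ[eta_pidx[k]] * math.exp(eta5[k])


@njit(cache=True)
def subject_conc(p, dose_t, dose_rate, dose_dur, times, h0, hmax, mgl, out):
    """Serum concentration (mg/L) at ``times``; closed form when linear.

    Nonlinear subjects use the deterministic fixed-schedule integrator
    (step ramp h0 -> hmax after each dose boundary), whose error is a smooth
    function of the parameters — a requirement for clean finite-difference
    gradients in the outer optimisation.
    """
    if p[_ode.IR0C] == 0.0 and p[_ode.IR0P] == 0.0:
        _ode.linear2cpt_conc(p[_ode.IV1], p[_ode.IV2], p[_ode.ICL], p[_ode.IQ],
                             dose_t, dose_rate, dose_dur, times, out)
        for i in range(times.shape[0]):
            out[i] *= mgl
        return True
    y0 = np.zeros(4)
    y0[1] = p[_ode.IR0C]
    y0[3] = p[_ode.IR0P]
    rates = dose_rate / p[_ode.IV1]
    states, ok, _ = _ode.integrate_profile_fixed(p, y0, dose_t, rates, dose_dur,
                                                 times, h0, hmax)
    if not ok:
        return False
    for i in range(times.shape[0]):
        c = _ode.qss_root(states[i, 0], states[i, 1], p[_ode.IKSSC])
        out[i] = c * mgl
    return True


@njit(cache=True)
def _data_nll(f, y, sig_a, sig_p, errform):
    U = 0.0
    for j in range(f.shape[0]):
        fj = f[j]
        if errform == 0:
            sd = sig_a + sig_p * fj
        else:
            sd = math.sqrt(sig_a * sig_a + (sig_p * fj) ** 2)
        if sd < 1e-10:
            sd = 1e-10
        r = y[j] - fj
        U += 0.5 * LOG2PI + math.log(sd) + 0.5 * (r / sd) ** 2
    return U


@njit(cache=True)
def _prior_nll(eta5, act, q, omegas5):
    U = 0.0
    for a in range(q):
        k = act[a]
        w = omegas5[k]
        U += 0.5 * LOG2PI + math.log(w) + 0.5 * (eta5[k] / w) ** 2
    return U


@njit(cache=True)
def _chol(A, q):
    """In-place lower Cholesky; returns False if not positive definite."""
    for i in range(q):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= A[i, k] * A[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                A[i, i] = math.sqrt(s)
            else:
                A[i, j] = s / A[j, j]
    return True


@njit(cache=True)
def _chol_solve(L, q, b, x):
    for i in range(q):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(q - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, q):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]


@njit(cache=True)
def _gn_matrices(G, f, y, eta5, act, q, omegas5, sig_a, sig_p, errform, A, g):
    for a in range(q):
        g[a] = 0.0
        for b in range(q):
            A[a, b] = 0.0
    n = f.shape[0]
    for j in range(n):
        fj = f[j]
        if errform == 0:
            sd = sig_a + sig_p * fj
        else:
            sd = math.sqrt(sig_a * sig_a + (sig_p * fj) ** 2)
        if sd < 1e-10:
            sd = 1e-10
        w = 1.0 / (sd * sd)
        r = y[j] - fj
        for a in range(q):
            g[a] -= G[j, a] * r * w
            for b in range(a, q):
                A[a, b] += G[j, a] * G[j, b] * w
    for a in range(q):
        k = act[a]
        w2 = omegas5[k] * omegas5[k]
        A[a, a] += 1.0 / w2
        g[a] += eta5[k] / w2
        for b in range(a + 1, q):
            A[b, a] = A[a, b]


@njit(cache=True)
def subject_neg2ll(p_typ, eta_pidx, dose_t, dose_rate, dose_dur, times, y,
                   omegas5, sig_a, sig_p, errform, h0, hmax, mgl, eta5,
                   max_inner):
    """Laplace -2 log marginal likelihood of one subject; eta5 updated in place
    to the conditional mode (empirical-Bayes estimate).

    ``max_inner = 0`` evaluates the Laplace approximation at the supplied
    eta5 without re-optimising (used for gradient perturbations around an
    already-converged mode, where the envelope theorem makes the first-order
    mode-shift contribution vanish)."""
    n = times.shape[0]
    act = np.empty(5, dtype=np.int64)
    q = 0
    for k in range(5):
        if omegas5[k] > 0.0 and p_typ[eta_pidx[k]] > 0.0:
            act[q] = k
            q += 1
        else:
            eta5[k] = 0.0
    p = np.empty(p_typ.shape[0])
    f = np.empty(n)
    ftmp = np.empty(n)
    _apply_eta(p_typ, eta5, eta_pidx, p)
    if not subject_conc(p, dose_t, dose_rate, dose_dur, times, h0, hmax, mgl, f):
        return _BIG
    U = _data_nll(f, y, sig_a, sig_p, errform) + _prior_nll(eta5, act, q, omegas5)
    if q == 0:
        return 2.0 * U
    G = np.empty((n, q))
    A = np.empty((q, q))
    g = np.empty(q)
    delta = np.empty(q)
    x = np.empty(q)
    etn = np.empty(5)
    fresh = False        # A/g correspond to the current eta
    for it in range(max_inner):
        # fd residual Jacobian wrt active etas at the current mode iterate
        for a in range(q):
            k = act[a]
            for kk in range(5):
                etn[kk] = eta5[kk]
            etn[k] += _FD_H
            _apply_eta(p_typ, etn, eta_pidx, p)
            if not subject_conc(p, dose_t, dose_rate, dose_dur, times, h0, hmax,
                                mgl, ftmp):
                return _BIG
            for j in range(n):
                G[j, a] = (ftmp[j] - f[j]) / _FD_H
        _gn_matrices(G, f, y, eta5, act, q, omegas5, sig_a, sig_p, errform, A, g)
        fresh = True
        Lc = A.copy()
        if not _chol(Lc, q):
            return _BIG
        for a in range(q):
            delta[a] = -g[a]
        _chol_solve(Lc, q, delta, x)
        # Newton decrement: expected improvement of U along the GN step
        dec = 0.0
        for a in range(q):
            dec -= 0.5 * g[a] * x[a]
        if dec < _DTOL * (1.0 + abs(U)):
            break
        # damped line search on U
        step = 1.0
        improved = False
        for _ls in range(7):
            for kk in range(5):
                etn[kk] = eta5[kk]
            for a in range(q):
                etn[act[a]] += step * x[a]
            _apply_eta(p_typ, etn, eta_pidx, p)
            if subject_conc(p, dose_t, dose_rate, dose_dur, times, h0, hmax,
                            mgl, ftmp):
                Un = (_data_nll(ftmp, y, sig_a, sig_p, errform)
                      + _prior_nll(etn, act, q, omegas5))
                if Un < U - 1e-13:
                    for kk in range(5):
                        eta5[kk] = etn[kk]
                    for j in range(n):
                        f[j] = ftmp[j]
                    U = Un
                    improved = True
                    fresh = False
                    break
            step *= 0.5
        if not improved:
            break
    if not fresh:
        # the mode moved after the last Jacobian: rebuild the GN Hessian there
        for a in range(q):
            k = act[a]
            for kk in range(5):
                etn[kk] = eta5[kk]
            etn[k] += _FD_H
            _apply_eta(p_typ, etn, eta_pidx, p)
            if not subject_conc(p, dose_t, dose_rate, dose_dur, times, h0, hmax,
                                mgl, ftmp):
                return _BIG
            for j in range(n):
                G[j, a] = (ftmp[j] - f[j]) / _FD_H
        _gn_matrices(G, f, y, eta5, act, q, omegas5, sig_a, sig_p, errform, A, g)
    # Laplace with the Gauss-Newton Hessian at the mode
    if not _chol(A, q):
        return _BIG
    logdet = 0.0
    for a in range(q):
        logdet += 2.0 * math.log(A[a, a])
    return 2.0 * U - q * LOG2PI + logdet


@njit(cache=True)
def total_neg2ll(P_typ, eta_pidx, obs_ptr, obs_t, obs_y,
                 dose_ptr, dose_t, dose_rate, dose_dur,
                 omegas5, sig_a, sig_p, errform, h0, hmax, mgl, etas,
                 max_inner, dual):
    """Per-subject Laplace -2LL contributions; ``etas`` (n,5) warm-started in place.

    The inner problem can be multimodal for large omegas; with ``dual`` set,
    warm starts far from zero are re-searched from eta = 0 and the better
    mode kept, removing warm-start hysteresis from reported values."""
    nsub = obs_ptr.shape[0] - 1
    out = np.empty(nsub)
    for i in range(nsub):
        o0, o1 = obs_ptr[i], obs_ptr[i + 1]
        d0, d1 = dose_ptr[i], dose_ptr[i + 1]
        far = False
        for k in range(5):
            if abs(etas[i, k]) > 0.3:
                far = True
        v1 = subject_neg2ll(
            P_typ[i], eta_pidx, dose_t[d0:d1], dose_rate[d0:d1], dose_dur[d0:d1],
            obs_t[o0:o1], obs_y[o0:o1], omegas5, sig_a, sig_p, errform,
            h0, hmax, mgl, etas[i], max_inner,
        )
        if far and max_inner > 0 and dual == 1:
            e2 = np.zeros(5)
            v2 = subject_neg2ll(
                P_typ[i], eta_pidx, dose_t[d0:d1], dose_rate[d0:d1],
                dose_dur[d0:d1], obs_t[o0:o1], obs_y[o0:o1], omegas5,
                sig_a, sig_p, errform, h0, hmax, mgl, e2, max_inner,
            )
            if v2 < v1:
                v1 = v2
                for k in range(5):
                    etas[i, k] = e2[k]
        out[i] = v1
    return out


@njit(cache=True)
def subject_joint_nll(p_typ, eta_pidx, dose_t, dose_rate, dose_dur, times, y,
                      omegas5, sig_a, sig_p, errform, h0, hmax, mgl, eta5):
    """U(eta): joint negative log density, used by the importance sampler."""
    act = np.empty(5, dtype=np.int64)
    q = 0
    for k in range(5):
        if omegas5[k] > 0.0 and p_typ[eta_pidx[k]] > 0.0:
            act[q] = k
            q += 1
    p = np.empty(p_typ.shape[0])
    f = np.empty(times.shape[0])
    _apply_eta(p_typ, eta5, eta_pidx, p)
    if not subject_conc(p, dose_t, dose_rate, dose_dur, times, h0, hmax, mgl, f):
        return _BIG
    return _data_nll(f, y, sig_a, sig_p, errform) + _prior_nll(eta5, act, q, omegas5)


@njit(cache=True)
def simulate_dv(P_typ, eta_pidx, obs_ptr, obs_t, dose_ptr, dose_t, dose_rate,
                dose_dur, omegas5, sig_a, sig_p, errform, h0, hmax, mgl,
                z_eta, z_eps, out):
    """One replicate of the design: new etas (z_eta standard normal, (n,5)) and
    residuals (z_eps, flat).  Fills ``out`` with simulated DV (mg/L, >= 0)."""
    nsub = obs_ptr.shape[0] - 1
    for i in range(nsub):
        o0, o1 = obs_ptr[i], obs_ptr[i + 1]
        d0, d1 = dose_ptr[i], dose_ptr[i + 1]
        eta5 = np.empty(5)
        for k in range(5):
            if omegas5[k] > 0.0 and P_typ[i, eta_pidx[k]] > 0.0:
                eta5[k] = omegas5[k] * z_eta[i, k]
            else:
                eta5[k] = 0.0
        p = np.empty(P_typ.shape[1])
        _apply_eta(P_typ[i], eta5, eta_pidx, p)
        f = np.empty(o1 - o0)
        ok = subject_conc(p, dose_t[d0:d1], dose_rate[d0:d1], dose_dur[d0:d1],
                          obs_t[o0:o1], h0, hmax, mgl, f)
        for j in range(o1 - o0):
            if not ok:
                out[o0 + j] = np.nan
                continue
            fj = f[j]
            if errform == 0:
                sd = sig_a + sig_p * fj
            else:
                sd = math.sqrt(sig_a * sig_a + (sig_p * fj) ** 2)
            v = fj + sd * z_eps[o0 + j]
            out[o0 + j] = v if v > 0.0 else 0.0
    return True


@njit(cache=True)
def subject_eb_moments(p_typ, eta_pidx, dose_t, dose_rate, dose_dur, times, y,
                       omegas5, sig_a, sig_p, errform, h0, hmax, mgl, eta5,
                       var5):
    """Conditional (empirical-Bayes) variance of each active eta at the mode.

    Fills var5 with the diagonal of the Gauss-Newton posterior covariance
    (zero for inactive slots).  Used by the EM-style recentering update of
    the outer optimiser."""
    n = times.shape[0]
    act = np.empty(5, dtype=np.int64)
    q = 0
    for k in range(5):
        var5[k] = 0.0
        if omegas5[k] > 0.0 and p_typ[eta_pidx[k]] > 0.0:
            act[q] = k
            q += 1
    if q == 0:
        return True
    p = np.empty(p_typ.shape[0])
    f = np.empty(n)
    ftmp = np.empty(n)
    _apply_eta(p_typ, eta5, eta_pidx, p)
    if not subject_conc(p, dose_t, dose_rate, dose_dur, times, h0, hmax, mgl, f):
        return False
    G = np.empty((n, q))
    etn = np.empty(5)
    for a in range(q):
        k = act[a]
        for kk in range(5):
            etn[kk] = eta5[kk]
        etn[k] += _FD_H
        _apply_eta(p_typ, etn, eta_pidx, p)
        if not subject_conc(p, dose_t, dose_rate, dose_dur, times, h0, hmax,
                            mgl, ftmp):
            return False
        for j in range(n):
            G[j, a] = (ftmp[j] - f[j]) / _FD_H
    A = np.empty((q, q))
    g = np.empty(q)
    _gn_matrices(G, f, y, eta5, act, q, omegas5, sig_a, sig_p, errform, A, g)
    if not _chol(A, q):
        return False
    e = np.empty(q)
    col = np.empty(q)
    for a in range(q):
        for b in range(q):
            e[b] = 1.0 if b == a else 0.0
        _chol_solve(A, q, e, col)
        var5[act[a]] = col[a]
    return True


@njit(cache=True)
def eb_moments(P_typ, eta_pidx, obs_ptr, obs_t, obs_y,
               dose_ptr, dose_t, dose_rate, dose_dur,
               omegas5, sig_a, sig_p, errform, h0, hmax, mgl, etas, vars_):
    """Per-subject EB conditional variances for all subjects (etas given)."""
    nsub = obs_ptr.shape[0] - 1
    for i in range(nsub):
        o0, o1 = obs_ptr[i], obs_ptr[i + 1]
        d0, d1 = dose_ptr[i], dose_ptr[i + 1]
        subject_eb_moments(
            P_typ[i], eta_pidx, dose_t[d0:d1], dose_rate[d0:d1], dose_dur[d0:d1],
            obs_t[o0:o1], obs_y[o0:o1], omegas5, sig_a, sig_p, errform,
            h0, hmax, mgl, etas[i], vars_[i],
        )


@njit(cache=True)
def sym_outer(S):
    """Deterministic S'S (single-threaded, fixed summation order)."""
    n, p = S.shape
    H = np.zeros((p, p))
    for i in range(n):
        for a in range(p):
            sa = S[i, a]
            for b in range(a, p):
                H[a, b] += sa * S[i, b]
    for a in range(p):
        for b in range(a + 1, p):
            H[b, a] = H[a, b]
    return H
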