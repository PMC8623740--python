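"""Structural double central-peripheral TMDD model with QSS approximation.

Two-compartment disposition of an antibody whose elimination is partly
target-mediated in both the central and the peripheral compartment.  In each
compartment the free drug C, free target R and drug-target complex are
collapsed under the quasi-steady-state approximation: only the totals
(CT = C + complex, RT = R + complex) are integrated, and the unbound
concentration is the non-negative root of

    C^2 + (RT + KSS - CT) * C - KSS * CT = 0.

The four ODEs (all concentrations in nM, time in days)::

    dCT/dt  = In(t) - (CL/V1) C - (Q/V1) C + (Q/V2) CP - kintC (CT - C)
    dRTC/dt = kinC - kout (RTC - (CT - C)) - kintC (CT - C)
    dCPT/dt = (Q/V1) C - (Q/V2) CP - kintP (CPT - CP)
    dRTP/dt = kinP - kout (RTP - (CPT - CP)) - kintP (CPT - CP)

with kin = R0 * kout in each compartment, so the undosed state
(0, R0C, 0, R0P) is an exact equilibrium.  The peripheral transfer terms use
the micro-constant (k12/k21) concentration convention: the sum of the two
*concentration* states is conserved by transfer, so CPT is an apparent
concentration; no volume scaling is applied.  Setting a compartment's R0 to
zero switches its TMDD arm off and recovers linear kinetics exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _ode
from .units import UnitSystem

__all__ = [
    "StructuralParams",
    "DoseEvent",
    "SecondaryParams",
    "IntegrationError",
    "qss_unbound",
    "rhs",
    "simulate_profile",
    "terminal_half_life",
]

#: default infusion duration: 2 h, matching peri-infusion sampling schedules
DEFAULT_INFUSION_DUR = 2.0 / 24.0


@dataclass
class StructuralParams:
    """Fixed-effect structural parameters for one (typical or individual) subject.

    Volumes in L, clearances in L/day, target levels and dissociation
    constants in nM, rate constants in /day.  ``tmdd_central`` /
    ``tmdd_peripheral`` select the structural variant; a disabled arm is
    equivalent to R0 = 0 in that compartment.
    """

    V1: float
    V2: float
    CL: float
    Q: float
    R0C: float = 0.0
    KSSC: float = 1.0
    kintC: float = 0.0
    R0P: float = 0.0
    KSSP: float = 1.0
    kintP: float = 0.0
    kout: float = 20.0
    tmdd_central: bool = False
    tmdd_peripheral: bool = False

    def __post_init__(self) -> None:
        for name in ("V1", "V2", "CL", "Q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.V1 <= 0 or self.V2 <= 0:
            raise ValueError("volumes must be strictly positive")
        if self.tmdd_central and not (
            self.R0C > 0 and self.KSSC > 0 and self.kintC > 0 and self.kout > 0
        ):
            raise ValueError("active central TMDD arm requires positive R0C, KSSC, kintC, kout")
        if self.tmdd_peripheral and not (
            self.R0P > 0 and self.KSSP > 0 and self.kintP > 0 and self.kout > 0
        ):
            raise ValueError("active peripheral TMDD arm requires positive R0P, KSSP, kintP, kout")

    # effective (variant-aware) quantities -------------------------------
    @property
    def R0C_eff(self) -> float:
        return self.R0C if self.tmdd_central else 0.0

    @property
    def R0P_eff(self) -> float:
        return self.R0P if self.tmdd_peripheral else 0.0

    @property
    def kinC(self) -> float:
        """Zero-order central target production (nM/day), derived as R0C*kout."""
        return self.R0C_eff * self.kout

    @property
    def kinP(self) -> float:
        return self.R0P_eff * self.kout

    @property
    def is_linear(self) -> bool:
        return not (self.tmdd_central or self.tmdd_peripheral)

    def to_array(self) -> np.ndarray:
        """Pack into the kernel parameter layout (disabled arms -> R0 = 0)."""
        p = np.empty(_ode.NPARAM)
        p[_ode.IV1] = self.V1
        p[_ode.IV2] = self.V2
        p[_ode.ICL] = self.CL
        p[_ode.IQ] = self.Q
        p[_ode.IR0C] = self.R0C_eff
        p[_ode.IKSSC] = max(self.KSSC, 1e-12)
        p[_ode.IKINTC] = self.kintC if self.tmdd_central else 0.0
        p[_ode.IR0P] = self.R0P_eff
        p[_ode.IKSSP] = max(self.KSSP, 1e-12)
        p[_ode.IKINTP] = self.kintP if self.tmdd_peripheral else 0.0
        p[_ode.IKOUT] = self.kout
        return p

    def replace(self, **kw) -> "StructuralParams":
        return replace(self, **kw)

    def initial_state(self) -> np.ndarray:
        return np.array([0.0, self.R0C_eff, 0.0, self.R0P_eff])


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order infusion: ``amount_mg`` delivered over ``duration`` days."""

    time: float
    amount_mg: float
    duration: float = DEFAULT_INFUSION_DUR

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("infusion duration must be positive")
        if self.amount_mg < 0:
            raise ValueError("dose amount must be non-negative")
        if self.time < 0:
            raise ValueError("dose time must be non-negative")

    @property
    def rate_mg_day(self) -> float:
        return self.amount_mg / self.duration


@dataclass(frozen=True)
class SecondaryParams:
    """Linear-phase secondary parameters of the two-compartment backbone."""

    t_half_alpha: float
    t_half_beta: float
    k10: float
    k12: float
    k21: float


class IntegrationError(RuntimeError):
    """ODE integration failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last successful time {last_time:.6g} day)")
        self.last_time = last_time


def qss_unbound(total_drug, total_target, kss):
    """Unbound drug concentration from totals under the QSS approximation.

    Vectorised over ``total_drug`` / ``total_target``.  All inputs nM.
    """
    ct = np.asarray(total_drug, dtype=float)
    rt = np.asarray(total_target, dtype=float)
    if np.any(ct < 0) or np.any(rt < 0):
        raise ValueError("total concentrations must be non-negative")
    if not np.all(np.asarray(kss) > 0):
        raise ValueError("KSS must be strictly positive")
    b = ct - rt - kss
    c = 0.5 * (b + np.sqrt(b * b + 4.0 * kss * ct))
    c = np.clip(c, 0.0, ct)
    if c.ndim == 0:
        return float(c)
    return c


def rhs(state, params: StructuralParams, infusion_rate: float = 0.0) -> np.ndarray:
    """Time derivative of (CT, RTC, CPT, RTP); ``infusion_rate`` in nM/day."""
    y = np.asarray(state, dtype=float)
    out = np.empty(4)
    _ode.rhs(y, params.to_array(), float(infusion_rate), out)
    return out


def _regimen_arrays(regimen, V1: float, units: UnitSystem):
    events = sorted(regimen, key=lambda d: d.time)
    dose_t = np.array([d.time for d in events], dtype=float)
    dose_dur = np.array([d.duration for d in events], dtype=float)
    # nM/day input into the central compartment: (mg/day -> nmol/day) / V1
    dose_rate = np.array(
        [units.to_nM(d.rate_mg_day) / V1 for d in events], dtype=float
    )
    return dose_t, dose_rate, dose_dur


def simulate_profile(
    params: StructuralParams,
    regimen,
    times,
    units: UnitSystem | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Simulate a full trajectory and post-process unbound/occupancy columns.

    Parameters
    ----------
    params : StructuralParams
    regimen : sequence of DoseEvent
    times : array of output times (days), sorted, starting at >= 0
    units : UnitSystem for the serum-concentration column (default MW 149 kDa)

    Returns
    -------
    pandas.DataFrame with columns time_day, conc_mgL, C_nM, CT_nM, CP_nM,
    CPT_nM, RTC_nM, RTP_nM, ratio_C, ratio_P.  ratio_* is the unbound/total
    target ratio, identically KSS/(KSS + C) under QSS.
    """
    import pandas as pd

    units = units or UnitSystem()
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0) or (times.size and times[0] < 0):
        raise ValueError("output times must be a sorted non-negative 1-d array")
    dose_t, dose_rate, dose_dur = _regimen_arrays(regimen, params.V1, units)
    p = params.to_array()
    y0 = params.initial_state()
    states, ok, t_last = _ode.integrate_profile(
        p, y0, dose_t, dose_rate, dose_dur, times, rtol, atol
    )
    if not ok:
        raise IntegrationError("stiff integration failed", t_last)
    ct, rtc, cpt, rtp = states.T
    c = qss_unbound(ct, rtc, p[_ode.IKSSC])
    cp = qss_unbound(cpt, rtp, p[_ode.IKSSP])
    c = np.atleast_1d(c)
    cp = np.atleast_1d(cp)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_c = np.where(rtc > 0, (rtc - (ct - c)) / rtc, 1.0)
        ratio_p = np.where(rtp > 0, (rtp - (cpt - cp)) / rtp, 1.0)
    return pd.DataFrame(
        {
            "time_day": times,
            "conc_mgL": units.to_mgL(c),
            "C_nM": c,
            "CT_nM": ct,
            "CP_nM": cp,
            "CPT_nM": cpt,
            "RTC_nM": rtc,
            "RTP_nM": rtp,
            "ratio_C": ratio_c,
            "ratio_P": ratio_p,
        }
    )


def terminal_half_life(V1: float, V2: float, CL: float, Q: float) -> SecondaryParams:
    """Distribution/terminal half-lives of the linear two-compartment backbone.

    alpha, beta are the eigen-rates of the 2x2 linear disposition matrix:
    alpha + beta = k10 + k12 + k21, alpha * beta = k10 * k21.
    """
    if min(V1, V2, CL) <= 0 or Q < 0:
        raise ValueError("V1, V2, CL must be positive and Q non-negative")
    k10 = CL / V1
    if Q == 0.0:
        # peripheral compartment unreachable: observable kinetics are one-compartment
        th = math.log(2.0) / k10
        return SecondaryParams(th, th, k10, 0.0, 0.0)
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    disc = max(s * s - 4.0 * k10 * k21, 0.0)
    root = math.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    return SecondaryParams(
        t_half_alpha=math.log(2.0) / alpha,
        t_half_beta=math.log(2.0) / beta,
        k10=k10,
        k12=k12,
        k21=k21,
    )


def linear_profile_conc(params: StructuralParams, regimen, times, units: UnitSystem | None = None):
    """Closed-form serum concentration (mg/L) for the linear two-compartment model.

    Exact superposition of bi-exponential infusion responses; used both as the
    fast path for linear subjects and as the analytic reference for the ODE
    integrator.
    """
    units = units or UnitSystem()
    times = np.asarray(times, dtype=float)
    dose_t, dose_rate, dose_dur = _regimen_arrays(regimen, 1.0, units)
    # dose_rate above is nmol/day when V1=1 passed; kernel divides by V1 itself
    out = np.empty(times.shape[0])
    _ode.linear2cpt_conc(
        params.V1, params.V2, params.CL, params.Q, dose_t, dose_rate, dose_dur, times, out
    )
    return units.to_mgL(out)


def load_regimen(path, bw: float | None = None):
    """Read a dose regimen from a JSON config file.

    The file holds either a list of events
    ``[{"time": 0, "amount_mg": 330, "duration": 0.0833}, ...]`` or a
    compact weight-based form
    ``{"mg_per_kg": 5, "times_weeks": [0, 2, 6, 14, 22], "duration": 0.0833}``
    (requires ``bw``; the dose is vial-rounded).  Times may be given in days
    ("times_days") instead of weeks.  Returns a list of DoseEvent.
    """
    import json

    with open(path) as fh:
        cfg = json.load(fh)
    if isinstance(cfg, list):
        return [DoseEvent(time=float(e["time"]), amount_mg=float(e["amount_mg"]),
                          duration=float(e.get("duration", DEFAULT_INFUSION_DUR)))
                for e in cfg]
    dur = float(cfg.get("duration", DEFAULT_INFUSION_DUR))
    if "times_weeks" in cfg:
        times = [7.0 * float(w) for w in cfg["times_weeks"]]
    else:
        times = [float(t) for t in cfg["times_days"]]
    if "mg_per_kg" in cfg:
        if bw is None:
            raise ValueError("weight-based regimen requires a body weight")
        from .datagen import dose_from_weight

        amount = dose_from_weight(bw, float(cfg["mg_per_kg"]))
    else:
        amount = float(cfg["amount_mg"])
    return [DoseEvent(time=t, amount_mg=amount, duration=dur) for t in times]
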