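"""Population NLME model objects: TMDDModel / TMDDResults.

``TMDDModel`` binds a study dataset to one of the four structural variants
(two-compartment, central TMDD, peripheral TMDD, double TMDD), a fixed target
turnover rate ``kout``, a covariate model and an error model.  ``fit()``
maximises the Laplace-approximate marginal likelihood over typical values,
covariate coefficients, interindividual variability SDs and residual error
parameters (all simultaneously, ``kout`` fixed) and returns a ``TMDDResults``
carrying estimates, -2LL, AIC, optional RSE%, empirical-Bayes random effects
and a ``summary()`` table.

Below-quantitation-limit records are excluded from the likelihood.  AS
reference subjects contribute through the linear model (closed-form
bi-exponential predictions); the TMDD parameters are informed by the IBD
subjects only, while the two-compartment backbone and the variability/error
parameters are shared across cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _likelihood, _ode
from .datagen import StudyDataset
from .population import ETA_PARAMS, PopulationParams
from .structural import StructuralParams
from .units import UnitSystem

__all__ = ["ModelVariant", "TMDDModel", "TMDDResults", "marginal_neg2ll"]

_PIDX = {"V1": _ode.IV1, "V2": _ode.IV2, "CL": _ode.ICL, "Q": _ode.IQ,
         "R0C": _ode.IR0C, "KSSC": _ode.IKSSC, "kintC": _ode.IKINTC,
         "R0P": _ode.IR0P, "KSSP": _ode.IKSSP, "kintP": _ode.IKINTP,
         "kout": _ode.IKOUT}


class ModelVariant(str, Enum):
    two_compartment = "two_compartment"
    central_tmdd = "central_tmdd"
    peripheral_tmdd = "peripheral_tmdd"
    double_tmdd = "double_tmdd"

    @property
    def structural_names(self):
        base = ("V1", "V2", "CL", "Q")
        if self is ModelVariant.two_compartment:
            return base
        if self is ModelVariant.central_tmdd:
            return base + ("KSSC", "R0C", "kintC")
        if self is ModelVariant.peripheral_tmdd:
            return base + ("KSSP", "R0P", "kintP")
        return base + ("KSSC", "R0C", "kintC", "KSSP", "R0P", "kintP")

    @property
    def has_central(self):
        return self in (ModelVariant.central_tmdd, ModelVariant.double_tmdd)

    @property
    def has_peripheral(self):
        return self in (ModelVariant.peripheral_tmdd, ModelVariant.double_tmdd)

    @property
    def omega_names(self):
        names = ["V1", "CL", "V2"]
        if self.has_central:
            names.append("R0C")
        if self.has_peripheral:
            names.append("R0P")
        return tuple(names)


#: standard covariate model of the final published analysis
FINAL_COVARIATE_EFFECTS = (("BW", "V1"), ("SX", "V1"), ("SX", "CL"), ("DIS", "R0C"))

_BETA_FIELD = {("BW", "V1"): "beta_BW_V1", ("SX", "V1"): "beta_SX_V1",
               ("SX", "CL"): "beta_SX_CL", ("DIS", "R0C"): "beta_UC_R0C"}


def _sym_outer(S: np.ndarray) -> np.ndarray:
    from . import _likelihood

    return _likelihood.sym_outer(np.ascontiguousarray(S))


def _variant_of(params: StructuralParams) -> ModelVariant:
    if params.tmdd_central and params.tmdd_peripheral:
        return ModelVariant.double_tmdd
    if params.tmdd_central:
        return ModelVariant.central_tmdd
    if params.tmdd_peripheral:
        return ModelVariant.peripheral_tmdd
    return ModelVariant.two_compartment


@dataclass
class _CompiledData:
    obs_ptr: np.ndarray
    obs_t: np.ndarray
    obs_y: np.ndarray
    dose_ptr: np.ndarray
    dose_t: np.ndarray
    dose_rate: np.ndarray       # nmol/day
    dose_dur: np.ndarray
    bw: np.ndarray
    male: np.ndarray
    uc: np.ndarray
    as_flag: np.ndarray
    ids: np.ndarray
    obs_all_ptr: np.ndarray = None
    obs_all_t: np.ndarray = None
    obs_all_y: np.ndarray = None
    obs_all_cens: np.ndarray = None


class TMDDModel:
    """Nonlinear mixed-effects double-TMDD model bound to a dataset.

    Parameters
    ----------
    dataset : StudyDataset or NONMEM-style DataFrame
    variant : ModelVariant or str
    kout : float
        Fixed target turnover rate constant (/day); never estimated.
    covariate_effects : sequence of (covariate, parameter) pairs
        covariate in {"BW", "SX", "DIS"}; BW enters as a centred power
        function, SX/DIS as log-scale shifts (references: female, CD).
    bw_ref : float
        Centring weight (kg) for the BW power term.
    """

    def __init__(self, dataset, variant=ModelVariant.double_tmdd, kout: float = 20.0,
                 covariate_effects=(), error_form: str = "combined1",
                 units: UnitSystem | None = None, bw_ref: float = 66.0,
                 fit_step_init: float = 0.01, fit_step_max: float = 0.5):
        if isinstance(dataset, pd.DataFrame):
            dataset = StudyDataset(df=dataset, subjects=[], provenance={})
        self.dataset = dataset
        self.variant = ModelVariant(variant)
        self.kout = float(kout)
        self.covariate_effects = tuple((c, p) for c, p in covariate_effects)
        for c, p in self.covariate_effects:
            if c not in ("BW", "SX", "DIS") or p not in _PIDX:
                raise ValueError(f"unsupported covariate effect {(c, p)}")
        self.error_form = error_form
        self.units = units or UnitSystem()
        self.bw_ref = float(bw_ref)
        # fixed-schedule integrator steps for likelihood predictions
        self.fit_step_init = float(fit_step_init)
        self.fit_step_max = float(fit_step_max)
        self._data = self._compile(dataset.df)
        self._etas = np.zeros((len(self._data.ids), 5))

    @classmethod
    def from_csv(cls, path, **kw) -> "TMDDModel":
        return cls(StudyDataset.from_csv(path), **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "TMDDModel":
        return cls(df, **kw)

    # ------------------------------------------------------------------
    def _compile(self, df: pd.DataFrame) -> _CompiledData:
        obs_ptr, obs_t, obs_y = [0], [], []
        all_ptr, all_t, all_y, all_c = [0], [], [], []
        dose_ptr, dose_t, dose_rate, dose_dur = [0], [], [], []
        bw, male, uc, as_flag, ids = [], [], [], [], []
        for sid, g in df.groupby("ID", sort=True):
            first = g.iloc[0]
            obs = g[g["EVID"] == 0]
            used = obs[obs["CENS"] == 0]
            obs_t.extend(used["TIME"].tolist())
            obs_y.extend(used["DV"].tolist())
            obs_ptr.append(len(obs_t))
            all_t.extend(obs["TIME"].tolist())
            all_y.extend(obs["DV"].tolist())
            all_c.extend(obs["CENS"].astype(int).tolist())
            all_ptr.append(len(all_t))
            dose = g[g["EVID"] == 1]
            for _, row in dose.iterrows():
                amt, rate = float(row["AMT"]), float(row["RATE"])
                dose_t.append(float(row["TIME"]))
                dose_rate.append(self.units.to_nM(rate))     # mg/day -> nmol/day
                dose_dur.append(amt / rate if rate > 0 else 2.0 / 24.0)
            dose_ptr.append(len(dose_t))
            bw.append(float(first["BW"]))
            male.append(float(int(first["SEX"])))
            uc.append(1.0 if int(first["DIS"]) == 1 else 0.0)
            as_flag.append(1.0 if int(first["DIS"]) == 2 else 0.0)
            ids.append(int(sid))
        return _CompiledData(
            obs_ptr=np.array(obs_ptr, dtype=np.int64), obs_t=np.array(obs_t),
            obs_y=np.array(obs_y), dose_ptr=np.array(dose_ptr, dtype=np.int64),
            dose_t=np.array(dose_t), dose_rate=np.array(dose_rate),
            dose_dur=np.array(dose_dur), bw=np.array(bw), male=np.array(male),
            uc=np.array(uc), as_flag=np.array(as_flag),
            ids=np.array(ids, dtype=np.int64),
            obs_all_ptr=np.array(all_ptr, dtype=np.int64),
            obs_all_t=np.array(all_t), obs_all_y=np.array(all_y),
            obs_all_cens=np.array(all_c, dtype=np.int64),
        )

    @property
    def n_subjects(self) -> int:
        return len(self._data.ids)

    @property
    def n_obs(self) -> int:
        """Number of observations entering the likelihood (non-censored)."""
        return int(self._data.obs_t.shape[0])

    # --- outer parameter vector ---------------------------------------
    @property
    def param_names(self):
        names = [f"theta_{n}" for n in self.variant.structural_names]
        names += [f"beta_{c}_{p}" for c, p in self.covariate_effects]
        names += [f"omega_{n}" for n in self.variant.omega_names]
        names += ["sigma_add", "sigma_prop"]
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def _pack(self, pop: PopulationParams, betas: dict | None = None) -> np.ndarray:
        th = pop.theta
        x = []
        for n in self.variant.structural_names:
            x.append(math.log(max(getattr(th, n), 1e-12)))
        for eff in self.covariate_effects:
            if betas is not None and eff in betas:
                x.append(betas[eff])
            else:
                x.append(getattr(pop, _BETA_FIELD.get(eff, "beta_BW_V1"))
                         if eff in _BETA_FIELD else 0.0)
        for n in self.variant.omega_names:
            w = getattr(pop, f"omega_{n}")
            # exact zeros survive the log transform via an underflow sentinel
            x.append(math.log(w) if w > 0 else -750.0)
        x.append(math.log(pop.sigma_add) if pop.sigma_add > 0 else -750.0)
        x.append(math.log(pop.sigma_prop) if pop.sigma_prop > 0 else -750.0)
        return np.array(x)

    def _unpack(self, x: np.ndarray):
        ns = len(self.variant.structural_names)
        nb = len(self.covariate_effects)
        nw = len(self.variant.omega_names)
        theta = {n: math.exp(x[i]) for i, n in enumerate(self.variant.structural_names)}
        betas = {eff: x[ns + i] for i, eff in enumerate(self.covariate_effects)}
        omegas = {n: math.exp(x[ns + nb + i]) for i, n in enumerate(self.variant.omega_names)}
        sig_a = math.exp(x[ns + nb + nw])
        sig_p = math.exp(x[ns + nb + nw + 1])
        return theta, betas, omegas, sig_a, sig_p

    def _pop_from_x(self, x: np.ndarray) -> tuple[PopulationParams, dict]:
        theta, betas, omegas, sig_a, sig_p = self._unpack(x)
        sp = StructuralParams(
            V1=theta["V1"], V2=theta["V2"], CL=theta["CL"], Q=theta["Q"],
            R0C=theta.get("R0C", 0.0), KSSC=theta.get("KSSC", 1.0),
            kintC=theta.get("kintC", 0.0), R0P=theta.get("R0P", 0.0),
            KSSP=theta.get("KSSP", 1.0), kintP=theta.get("kintP", 0.0),
            kout=self.kout,
            tmdd_central=self.variant.has_central,
            tmdd_peripheral=self.variant.has_peripheral,
        )
        kw = {}
        for eff, fieldname in _BETA_FIELD.items():
            if eff in betas:
                kw[fieldname] = betas[eff]
        pop = PopulationParams(
            theta=sp, bw_ref=self.bw_ref,
            omega_V1=omegas.get("V1", 0.0), omega_CL=omegas.get("CL", 0.0),
            omega_V2=omegas.get("V2", 0.0), omega_R0C=omegas.get("R0C", 0.0),
            omega_R0P=omegas.get("R0P", 0.0),
            sigma_add=sig_a, sigma_prop=sig_p, error_form=self.error_form,
            **kw,
        )
        return pop, betas

    # --- typical parameter matrix --------------------------------------
    def _typical_matrix(self, theta: dict, betas: dict) -> np.ndarray:
        n = self.n_subjects
        d = self._data
        base = np.zeros(_ode.NPARAM)
        base[_ode.IKSSC] = 1.0
        base[_ode.IKSSP] = 1.0
        base[_ode.IKOUT] = self.kout
        for name, v in theta.items():
            base[_PIDX[name]] = v
        P = np.tile(base, (n, 1))
        for (cov, par), beta in betas.items():
            col = _PIDX[par]
            if cov == "BW":
                P[:, col] *= (d.bw / self.bw_ref) ** beta
            elif cov == "SX":
                P[:, col] *= np.exp(beta * d.male)
            else:  # DIS: UC vs CD reference; AS handled below
                P[:, col] *= np.exp(beta * d.uc)
        ref = d.as_flag > 0.5
        P[ref, _ode.IR0C] = 0.0
        P[ref, _ode.IR0P] = 0.0
        P[ref, _ode.IKINTC] = 0.0
        P[ref, _ode.IKINTP] = 0.0
        return P

    def _omega5(self, omegas: dict) -> np.ndarray:
        return np.array([omegas.get("V1", 0.0), omegas.get("CL", 0.0),
                         omegas.get("V2", 0.0), omegas.get("R0C", 0.0),
                         omegas.get("R0P", 0.0)])

    # --- likelihood -----------------------------------------------------
    def _neg2ll_vector(self, x: np.ndarray, etas: np.ndarray,
                       max_inner: int = 50, dual: bool = False) -> np.ndarray:
        theta, betas, omegas, sig_a, sig_p = self._unpack(x)
        P = self._typical_matrix(theta, betas)
        d = self._data
        return _likelihood.total_neg2ll(
            P, _likelihood.ETA_PIDX, d.obs_ptr, d.obs_t, d.obs_y,
            d.dose_ptr, d.dose_t, d.dose_rate, d.dose_dur,
            self._omega5(omegas), sig_a, sig_p,
            0 if self.error_form == "combined1" else 1,
            self.fit_step_init, self.fit_step_max, self.units.to_mgL(1.0), etas,
            max_inner, 1 if dual else 0,
        )

    def neg2ll(self, pop: PopulationParams, etas: np.ndarray | None = None) -> float:
        """Laplace -2 log marginal likelihood at the given population parameters."""
        x = self._pack(pop)
        etas = etas if etas is not None else np.zeros((self.n_subjects, 5))
        return float(np.sum(self._neg2ll_vector(x, etas, dual=True)))

    # --- initial values --------------------------------------------------
    def initial_values(self) -> PopulationParams:
        """Heuristic start: backbone from naive pooled moments, TMDD arm from
        generic antibody-scale values; variability/error at field-typical
        magnitudes."""
        d = self._data
        obs = self.dataset.df[(self.dataset.df["EVID"] == 0)
                              & (self.dataset.df["CENS"] == 0)]
        doses = self.dataset.df[self.dataset.df["EVID"] == 1]
        peak = obs.groupby("ID")["DV"].max()
        amt = doses.groupby("ID")["AMT"].sum() / doses.groupby("ID")["AMT"].count()
        v1 = float(np.median((amt / peak).dropna())) if len(peak) else 3.0
        v1 = min(max(v1, 1.0), 8.0)
        sp = StructuralParams(
            V1=v1, V2=0.7 * v1, CL=0.25, Q=1.0,
            R0C=2.6, KSSC=13.7, kintC=0.13,
            R0P=0.30, KSSP=0.45, kintP=0.005,
            kout=self.kout,
            tmdd_central=self.variant.has_central,
            tmdd_peripheral=self.variant.has_peripheral,
        )
        return PopulationParams(
            theta=sp, bw_ref=self.bw_ref,
            omega_V1=0.3, omega_CL=0.4, omega_V2=0.4,
            omega_R0C=1.0 if self.variant.has_central else 0.0,
            omega_R0P=1.0 if self.variant.has_peripheral else 0.0,
            sigma_add=1.5, sigma_prop=0.2, error_form=self.error_form,
        )

    # --- fitting ----------------------------------------------------------
    def fit(self, start: PopulationParams | None = None, maxiter: int = 60,
            compute_rse: bool = False, fd_eps: float = 1e-4,
            gain_tol: float = 0.01,
            start_etas: np.ndarray | None = None) -> "TMDDResults":
        """Maximise the Laplace marginal likelihood.

        The outer optimiser is a damped (Levenberg-Marquardt) Newton method
        whose Hessian is the BHHH outer product of per-subject score vectors
        — the standard choice for marginal-likelihood surfaces, whose long
        correlated valleys (CL-Q-KSS trade-offs) defeat diagonally scaled
        quasi-Newton methods.  Scores come from central differences around a
        common empirical-Bayes mode snapshot; the modes are frozen during the
        perturbed evaluations (their first-order shift does not move the
        marginal likelihood at the mode).  Iteration stops when two
        consecutive accepted steps gain less than ``gain_tol`` points of
        -2LL, or at ``maxiter``.
        """
        start = start or self.initial_values()
        x0 = self._pack(start)
        npar = len(x0)
        etas = np.zeros((self.n_subjects, 5))
        if start_etas is not None:
            etas[:] = start_etas
        work = np.empty_like(etas)
        nev = [0]

        def vec(x, e, max_inner=50):
            nev[0] += 1
            return self._neg2ll_vector(x, e, max_inner=max_inner)

        def value(x, e, max_inner=50):
            tot = float(np.sum(vec(x, e, max_inner)))
            return tot if np.isfinite(tot) and tot < 1e80 else 1e12

        def value_grad_scores(x):
            """(f, gradient, per-subject score matrix) by central differences."""
            v0 = vec(x, etas)
            f0 = float(np.sum(v0))
            if not np.isfinite(f0) or f0 > 1e80:
                return 1e12, None, None
            snap = etas.copy()
            S = np.empty((self.n_subjects, npar))
            for j in range(npar):
                xp = x.copy()
                xp[j] += fd_eps
                work[:] = snap
                vp = vec(xp, work, max_inner=0)
                xp[j] = x[j] - fd_eps
                work[:] = snap
                vm = vec(xp, work, max_inner=0)
                S[:, j] = (vp - vm) / (2.0 * fd_eps)
            return f0, S.sum(axis=0), S

        bounds = []
        ns = len(self.variant.structural_names)
        nb = len(self.covariate_effects)
        nw = len(self.variant.omega_names)
        for i in range(npar):
            if ns <= i < ns + nb:
                bounds.append((-3.0, 3.0))
            elif ns + nb <= i < ns + nb + nw:
                bounds.append((math.log(1e-3), math.log(2.5)))
            else:
                # generous but finite box around the start keeps Newton steps
                # out of degenerate ridges (e.g. huge V1 absorbed by omega)
                bounds.append((x0[i] - 3.0, x0[i] + 3.0))
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        x = np.clip(x0, lo, hi)
        f, g, S = value_grad_scores(x)
        if g is None:
            raise RuntimeError("likelihood not finite at the starting values")
        lam = 1e-2
        n_iter = 0
        stall = 0
        converged = False
        for _ in range(maxiter):
            # BHHH: Hessian of -2LL ~= 0.5 * sum_i q_i q_i' (q = subject score)
            # (accumulated in float64 with a deterministic single-threaded
            # reduction: threaded BLAS summation order varies run to run and
            # the optimizer path amplifies the last-bit differences)
            H = 0.5 * _sym_outer(S)
            dH = np.clip(np.diag(H), 1e-8, None)
            accepted = False
            for _try in range(10):
                try:
                    step = np.linalg.solve(H + lam * np.diag(dH), -g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                x_new = np.clip(x + step, lo, hi)
                work[:] = etas
                f_new = value(x_new, work)
                if f_new < f:
                    accepted = True
                    lam = max(lam / 3.0, 1e-8)
                    break
                lam *= 8.0
            if not accepted:
                converged = True
                break
            # far from the optimum BHHH overestimates curvature (the scores
            # share the misfit direction), so extend the accepted step
            # geometrically while the objective keeps improving; the total
            # move per iteration is capped (trust region) so a descending
            # ridge cannot fling the iterate into a degenerate basin
            t = 2.0
            smax = float(np.max(np.abs(step)))
            while t * smax <= 1.5:
                x_ext = np.clip(x + t * step, lo, hi)
                work2 = etas.copy()
                f_ext = value(x_ext, work2)
                if f_ext < f_new:
                    x_new, f_new = x_ext, f_ext
                    work[:] = work2
                    t *= 2.0
                else:
                    break
            # EM-style recentering: the profile likelihood is flat along
            # ridges where a shift of a typical value is absorbed by a common
            # displacement of that parameter's random effects (with an
            # inflated omega).  Absorbing the mean EB eta into the typical
            # value and refreshing omega from the EB first/second moments
            # jumps straight along such a ridge; the move is kept only when
            # it improves the objective.
            x_em = self._em_candidate(x_new, work)
            if x_em is not None:
                work2 = work.copy()
                f_em = value(np.clip(x_em, lo, hi), work2)
                if f_em < f_new - 1e-9:
                    x_new = np.clip(x_em, lo, hi)
                    f_new = f_em
                    work[:] = work2
            gain = f - f_new
            x = x_new
            etas[:] = work
            f, g, S = value_grad_scores(x)
            n_iter += 1
            if g is None:
                break
            if gain < gain_tol:
                stall += 1
                if stall >= 3:
                    converged = True
                    break
            else:
                stall = 0
        xhat = x
        # final dual-start mode refresh removes warm-start hysteresis from
        # the reported likelihood (fits, refits and evaluations then agree)
        v = self._neg2ll_vector(xhat, etas, dual=True)
        neg2ll = float(np.sum(v))
        pop, betas = self._pop_from_x(xhat)
        rse = None
        if compute_rse:
            rse = self._rse_bhhh(xhat, etas)
        return TMDDResults(
            model=self, params=pop, betas=betas, x=xhat, neg2ll=neg2ll,
            n_params=npar, converged=converged,
            n_iter=n_iter, n_fev=nev[0], etas=etas.copy(),
            per_subject_neg2ll=v, rse=rse,
            message="converged" if converged else "maxiter",
            fixed={"kout": self.kout},
        )

    def _em_candidate(self, x: np.ndarray, etas: np.ndarray):
        """Recentred parameter vector from the EB moments at (x, etas).

        For each random-effect-bearing parameter: shift the typical value by
        the mean conditional mode and set omega^2 to the mean of
        (eta - mean)^2 + conditional variance.  Returns None when no slot is
        active."""
        theta, betas, omegas, sig_a, sig_p = self._unpack(x)
        P = self._typical_matrix(theta, betas)
        om5 = self._omega5(omegas)
        d = self._data
        vars_ = np.zeros_like(etas)
        _likelihood.eb_moments(
            P, _likelihood.ETA_PIDX, d.obs_ptr, d.obs_t, d.obs_y,
            d.dose_ptr, d.dose_t, d.dose_rate, d.dose_dur,
            om5, sig_a, sig_p, 0 if self.error_form == "combined1" else 1,
            self.fit_step_init, self.fit_step_max, self.units.to_mgL(1.0),
            etas, vars_)
        snames = list(self.variant.structural_names)
        onames = list(self.variant.omega_names)
        nsd = len(snames)
        nb = len(self.covariate_effects)
        x_em = x.copy()
        changed = False
        for k, pname in enumerate(ETA_PARAMS):
            if pname not in onames or om5[k] <= 0.0:
                continue
            active = P[:, _likelihood.ETA_PIDX[k]] > 0.0
            if not active.any():
                continue
            e = etas[active, k]
            v = vars_[active, k]
            mean = float(np.mean(e))
            var_new = float(np.mean((e - mean) ** 2 + v))
            x_em[snames.index(pname)] += mean
            x_em[nsd + nb + onames.index(pname)] = 0.5 * math.log(max(var_new, 1e-8))
            changed = True
        return x_em if changed else None

    def results_from_params(self, pop: PopulationParams) -> "TMDDResults":
        """Results object at known parameters (no optimisation); EB modes are
        still computed, so diagnostics and simulation work as after a fit."""
        x = self._pack(pop)
        etas = np.zeros((self.n_subjects, 5))
        v = self._neg2ll_vector(x, etas, dual=True)
        pop2, betas = self._pop_from_x(x)
        return TMDDResults(model=self, params=pop2, betas=betas, x=x,
                           neg2ll=float(np.sum(v)), n_params=len(x),
                           converged=True, n_iter=0, n_fev=1, etas=etas.copy(),
                           per_subject_neg2ll=v, rse=None, message="evaluated",
                           fixed={"kout": self.kout})

    def _rse_bhhh(self, x: np.ndarray, etas: np.ndarray) -> dict:
        """RSE% from the BHHH (outer-product-of-scores) information estimate."""
        h = 1e-4
        n = self.n_subjects
        npar = len(x)
        scores = np.zeros((n, npar))
        for j in range(npar):
            xp = x.copy(); xp[j] += h
            xm = x.copy(); xm[j] -= h
            vp = self._neg2ll_vector(xp, etas.copy())
            vm = self._neg2ll_vector(xm, etas.copy())
            scores[:, j] = -(vp - vm) / (4.0 * h)  # d(loglik_i)/dx_j
        info = scores.T @ scores
        try:
            cov = np.linalg.inv(info + 1e-10 * np.eye(npar))
        except np.linalg.LinAlgError:
            return {}
        se_x = np.sqrt(np.maximum(np.diag(cov), 0.0))
        out = {}
        ns = len(self.variant.structural_names)
        nb = len(self.covariate_effects)
        for i, name in enumerate(self.param_names):
            if ns <= i < ns + nb:
                # identity-scale coefficient: RSE relative to its value
                val = abs(x[i])
                out[name] = 100.0 * se_x[i] / val if val > 1e-12 else np.inf
            else:
                # log-scale parameter: SE of log is already a relative error
                out[name] = 100.0 * se_x[i]
        return out

    # --- simulation on the observed design -------------------------------
    def simulate_dv_matrix(self, pop: PopulationParams, n_reps: int, seed: int,
                           include_censored_times: bool = False) -> np.ndarray:
        """Simulate ``n_reps`` replicates of the dataset's DV vector (mg/L).

        Row r is one full replicate over the likelihood observations (or all
        observation records when ``include_censored_times``)."""
        x = self._pack(pop)
        theta, betas, omegas, sig_a, sig_p = self._unpack(x)
        P = self._typical_matrix(theta, betas)
        d = self._data
        if include_censored_times:
            optr, ot = d.obs_all_ptr, d.obs_all_t
        else:
            optr, ot = d.obs_ptr, d.obs_t
        ntot = ot.shape[0]
        rng = np.random.default_rng(seed)
        out = np.empty((n_reps, ntot))
        buf = np.empty(ntot)
        om5 = self._omega5(omegas)
        errform = 0 if self.error_form == "combined1" else 1
        for r in range(n_reps):
            z_eta = rng.standard_normal((self.n_subjects, 5))
            z_eps = rng.standard_normal(ntot)
            _likelihood.simulate_dv(P, _likelihood.ETA_PIDX, optr, ot,
                                    d.dose_ptr, d.dose_t, d.dose_rate, d.dose_dur,
                                    om5, sig_a, sig_p, errform,
                                    self.fit_step_init, self.fit_step_max,
                                    self.units.to_mgL(1.0), z_eta, z_eps, buf)
            out[r] = buf
        return out

    def predict_conc(self, pop: PopulationParams, etas: np.ndarray | None = None,
                     include_censored_times: bool = False) -> np.ndarray:
        """Noise-free predicted concentrations at the observation times.

        etas None -> population prediction at eta = 0; otherwise individual
        predictions at the supplied (n_subjects, 5) random effects."""
        x = self._pack(pop)
        theta, betas, omegas, sig_a, sig_p = self._unpack(x)
        P = self._typical_matrix(theta, betas)
        d = self._data
        if include_censored_times:
            optr, ot = d.obs_all_ptr, d.obs_all_t
        else:
            optr, ot = d.obs_ptr, d.obs_t
        out = np.empty(ot.shape[0])
        if etas is None:
            etas = np.zeros((self.n_subjects, 5))
        p = np.empty(_ode.NPARAM)
        for i in range(self.n_subjects):
            o0, o1 = optr[i], optr[i + 1]
            d0, d1 = d.dose_ptr[i], d.dose_ptr[i + 1]
            _likelihood._apply_eta(P[i], etas[i], _likelihood.ETA_PIDX, p)
            ok = _likelihood.subject_conc(
                p, d.dose_t[d0:d1], d.dose_rate[d0:d1], d.dose_dur[d0:d1],
                ot[o0:o1], self.fit_step_init, self.fit_step_max,
                self.units.to_mgL(1.0), out[o0:o1])
            if not ok:
                out[o0:o1] = np.nan
        return out


@dataclass
class TMDDResults:
    """Estimation results: estimates, uncertainty, fit statistics, EB modes."""

    model: TMDDModel
    params: PopulationParams
    betas: dict
    x: np.ndarray
    neg2ll: float
    n_params: int
    converged: bool
    n_iter: int
    n_fev: int
    etas: np.ndarray
    per_subject_neg2ll: np.ndarray
    rse: dict | None = None
    message: str = ""
    fixed: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return self.neg2ll + 2.0 * self.n_params

    @property
    def param_values(self) -> dict:
        theta, betas, omegas, sig_a, sig_p = self.model._unpack(self.x)
        out = {f"theta_{k}": v for k, v in theta.items()}
        out.update({f"beta_{c}_{p}": b for (c, p), b in betas.items()})
        out.update({f"omega_{k}": v for k, v in omegas.items()})
        out["sigma_add"] = sig_a
        out["sigma_prop"] = sig_p
        return out

    def summary(self) -> str:
        lines = [
            f"Double-TMDD population model ({self.model.variant.value})",
            f"subjects: {self.model.n_subjects}   observations: {self.model.n_obs}",
            f"fixed: " + ", ".join(f"{k}={v:g}" for k, v in self.fixed.items()),
            f"-2LL: {self.neg2ll:.2f}   AIC: {self.aic:.2f}   "
            f"params: {self.n_params}   converged: {self.converged}",
            "-" * 56,
            f"{'parameter':<18}{'estimate':>12}{'RSE%':>10}",
        ]
        rse = self.rse or {}
        for name, val in self.param_values.items():
            r = rse.get(name)
            lines.append(f"{name:<18}{val:>12.4g}{(f'{r:.0f}' if r is not None else '-'):>10}")
        return "\n".join(lines)

    # diagnostics delegate to the diagnostics module
    def gof_table(self, n_reps: int = 1000, seed: int = 0):
        from .diagnostics import gof_table
        return gof_table(self, n_reps=n_reps, seed=seed)

    def vpc(self, n_reps: int = 1000, percentiles=(10, 50, 90), seed: int = 0, bins=None):
        from .diagnostics import vpc
        return vpc(self, n_reps=n_reps, percentiles=percentiles, seed=seed, bins=bins)

    def npde(self, n_reps: int = 1000, seed: int = 0):
        from .diagnostics import npde
        return npde(self, n_reps=n_reps, seed=seed)


def marginal_neg2ll(dataset, pop: PopulationParams, variant=None, kout: float | None = None,
                    covariate_effects=(), method: str = "laplace",
                    n_importance: int = 500, seed: int = 0,
                    units: UnitSystem | None = None, bw_ref: float = 66.0):
    """Approximate -2 log marginal likelihood of a dataset at given parameters.

    method "laplace" (default; deterministic, MC-SE 0) or "importance"
    (importance sampling around the conditional modes with a Gaussian
    proposal from the Gauss-Newton Hessian).  Returns (value, mc_se).
    """
    variant = ModelVariant(variant) if variant is not None else _variant_of(pop.theta)
    model = TMDDModel(dataset, variant=variant,
                      kout=kout if kout is not None else pop.theta.kout,
                      covariate_effects=covariate_effects, units=units,
                      bw_ref=bw_ref, error_form=pop.error_form)
    x = model._pack(pop)
    etas = np.zeros((model.n_subjects, 5))
    v = model._neg2ll_vector(x, etas)    # also sets EB modes
    if method == "laplace":
        return float(np.sum(v)), 0.0
    if method != "importance":
        raise ValueError("method must be 'laplace' or 'importance'")
    theta, betas, omegas, sig_a, sig_p = model._unpack(x)
    P = model._typical_matrix(theta, betas)
    om5 = model._omega5(omegas)
    d = model._data
    errform = 0 if model.error_form == "combined1" else 1
    mgl = model.units.to_mgL(1.0)
    rng = np.random.default_rng(seed)
    total = 0.0
    var_total = 0.0
    for i in range(model.n_subjects):
        o0, o1 = d.obs_ptr[i], d.obs_ptr[i + 1]
        d0, d1 = d.dose_ptr[i], d.dose_ptr[i + 1]
        args = (P[i], _likelihood.ETA_PIDX, d.dose_t[d0:d1], d.dose_rate[d0:d1],
                d.dose_dur[d0:d1], d.obs_t[o0:o1], d.obs_y[o0:o1], om5,
                sig_a, sig_p, errform, model.fit_step_init, model.fit_step_max, mgl)
        act = [k for k in range(5) if om5[k] > 0 and P[i, _likelihood.ETA_PIDX[k]] > 0]
        q = len(act)
        if q == 0:
            total += float(v[i])
            continue
        mode = etas[i].copy()
        # proposal covariance: numeric GN Hessian via fd of U around the mode
        H = _numeric_hessian(args, mode, act)
        try:
            Hc = np.linalg.cholesky(np.linalg.inv(H))
        except np.linalg.LinAlgError:
            H = H + 1e-6 * np.eye(q)
            Hc = np.linalg.cholesky(np.linalg.inv(H))
        z = rng.standard_normal((n_importance, q))
        logw = np.empty(n_importance)
        sgn, logdet_prop = np.linalg.slogdet(H)
        for s in range(n_importance):
            eta = mode.copy()
            step = Hc @ z[s]
            for a, k in enumerate(act):
                eta[k] = mode[k] + step[a]
            U = _likelihood.subject_joint_nll(*args, eta)
            log_q = (-0.5 * q * _likelihood.LOG2PI + 0.5 * logdet_prop
                     - 0.5 * float(z[s] @ z[s]))
            logw[s] = -U - log_q
        m = np.max(logw)
        w = np.exp(logw - m)
        lhat = m + np.log(np.mean(w))
        total += -2.0 * lhat
        # delta-method MC SE of -2 log(mean w)
        se_i = 2.0 * np.std(w) / (np.mean(w) * math.sqrt(n_importance))
        var_total += se_i**2
    return float(total), float(math.sqrt(var_total))


def _numeric_hessian(args, mode, act, h: float = 1e-3) -> np.ndarray:
    q = len(act)

    def U(eta):
        return _likelihood.subject_joint_nll(*args, eta)

    H = np.zeros((q, q))
    u0 = U(mode.copy())
    for a in range(q):
        for b in range(a, q):
            ep = mode.copy(); ep[act[a]] += h; ep[act[b]] += h
            em = mode.copy(); em[act[a]] -= h; em[act[b]] -= h
            e1 = mode.copy(); e1[act[a]] += h; e1[act[b]] -= h
            e2 = mode.copy(); e2[act[a]] -= h; e2[act[b]] += h
            H[a, b] = H[b, a] = (U(ep) + U(em) - U(e1) - U(e2)) / (4 * h * h)
    # symmetrise tiny asymmetries; ensure positive diagonal
    for a in range(q):
        if H[a, a] <= 0:
            H[a, a] = abs(H[a, a]) + 1e-6
    _ = u0
    return H
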