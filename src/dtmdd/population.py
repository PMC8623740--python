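"""Population layer: covariate model, interindividual variability, residual error.

Typical values are mapped to individual structural parameters in two steps:

1. covariates — body weight enters as a power function centred on a reference
   weight; sex and disease are coded on the log scale
   (ln theta_TV = ln theta_ref + beta for the non-reference category, with
   females and Crohn's disease as references);
2. random effects — log-normal ("exponential") interindividual variability on
   V1, CL, V2, R0C, R0P: theta_i = theta_TV * exp(eta_i), eta ~ N(0, omega^2).

The residual error model is mixed additive-proportional in the combined-1
form y = f + (sigma_add + sigma_prop * f) * eps, the default of common NLME
software; the alternative sqrt(sigma_add^2 + sigma_prop^2 f^2) form is
selectable but non-default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .structural import StructuralParams

__all__ = [
    "PopulationParams",
    "SubjectCovariates",
    "ETA_PARAMS",
    "typical_params",
    "individual_params",
    "residual_error",
    "residual_sd",
    "final_model_params",
    "base_model_params",
]

#: parameters carrying random effects, in eta-vector order
ETA_PARAMS = ("V1", "CL", "V2", "R0C", "R0P")

#: reference body weight (kg) used to centre the BW power term
DEFAULT_BWREF = 66.0


@dataclass(frozen=True)
class SubjectCovariates:
    """Covariates of one subject.

    ``disease`` is one of "CD" (reference), "UC", "AS".  AS subjects are the
    linear-kinetics reference population: both TMDD arms are forced off.
    """

    BW: float
    male: bool = False
    disease: str = "CD"
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.BW <= 0:
            raise ValueError("body weight must be positive")
        if self.disease not in ("CD", "UC", "AS"):
            raise ValueError(f"unknown disease code {self.disease!r}")


@dataclass
class PopulationParams:
    """Typical structural parameters + covariate, variability and error model.

    Covariate coefficients apply on the log scale; omegas are standard
    deviations of the log-normal random effects; sigma_add (mg/L) and
    sigma_prop (fraction) parameterise the combined residual error.
    """

    theta: StructuralParams
    beta_BW_V1: float = 0.0
    beta_SX_V1: float = 0.0
    beta_SX_CL: float = 0.0
    beta_UC_R0C: float = 0.0
    bw_ref: float = DEFAULT_BWREF
    omega_V1: float = 0.0
    omega_CL: float = 0.0
    omega_V2: float = 0.0
    omega_R0C: float = 0.0
    omega_R0P: float = 0.0
    sigma_add: float = 0.0
    sigma_prop: float = 0.0
    error_form: str = "combined1"

    def __post_init__(self) -> None:
        for name in ("omega_V1", "omega_CL", "omega_V2", "omega_R0C", "omega_R0P",
                     "sigma_add", "sigma_prop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.error_form not in ("combined1", "combined2"):
            raise ValueError("error_form must be 'combined1' or 'combined2'")

    @property
    def omegas(self) -> np.ndarray:
        return np.array([self.omega_V1, self.omega_CL, self.omega_V2,
                         self.omega_R0C, self.omega_R0P])

    def replace(self, **kw) -> "PopulationParams":
        return replace(self, **kw)

    # flat key-value serialisation ---------------------------------------
    _FLAT_MAP = {
        "V1": ("theta", "V1"), "V2": ("theta", "V2"), "CL": ("theta", "CL"),
        "Q": ("theta", "Q"), "R0_C": ("theta", "R0C"), "KSS_C": ("theta", "KSSC"),
        "kint_C": ("theta", "kintC"), "R0_P": ("theta", "R0P"),
        "KSS_P": ("theta", "KSSP"), "kint_P": ("theta", "kintP"),
        "kout": ("theta", "kout"),
    }

    def to_dict(self) -> dict:
        d = {k: getattr(self.theta, attr) for k, (_, attr) in self._FLAT_MAP.items()}
        d["tmdd_central"] = int(self.theta.tmdd_central)
        d["tmdd_peripheral"] = int(self.theta.tmdd_peripheral)
        d["BW_V1"] = self.beta_BW_V1
        d["SX_V1"] = self.beta_SX_V1
        d["SX_CL"] = self.beta_SX_CL
        d["UC_R0C"] = self.beta_UC_R0C
        d["bw_ref"] = self.bw_ref
        for k in ("omega_V1", "omega_CL", "omega_V2", "omega_R0C", "omega_R0P",
                  "sigma_add", "sigma_prop"):
            d[k] = getattr(self, k)
        return d

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PopulationParams":
        import json

        with open(path) as fh:
            d = json.load(fh)
        theta = StructuralParams(
            V1=d["V1"], V2=d["V2"], CL=d["CL"], Q=d["Q"],
            R0C=d.get("R0_C", 0.0), KSSC=d.get("KSS_C", 1.0), kintC=d.get("kint_C", 0.0),
            R0P=d.get("R0_P", 0.0), KSSP=d.get("KSS_P", 1.0), kintP=d.get("kint_P", 0.0),
            kout=d.get("kout", 20.0),
            tmdd_central=bool(d.get("tmdd_central", d.get("R0_C", 0.0) > 0)),
            tmdd_peripheral=bool(d.get("tmdd_peripheral", d.get("R0_P", 0.0) > 0)),
        )
        return cls(
            theta=theta,
            beta_BW_V1=d.get("BW_V1", 0.0), beta_SX_V1=d.get("SX_V1", 0.0),
            beta_SX_CL=d.get("SX_CL", 0.0), beta_UC_R0C=d.get("UC_R0C", 0.0),
            bw_ref=d.get("bw_ref", DEFAULT_BWREF),
            omega_V1=d.get("omega_V1", 0.0), omega_CL=d.get("omega_CL", 0.0),
            omega_V2=d.get("omega_V2", 0.0), omega_R0C=d.get("omega_R0C", 0.0),
            omega_R0P=d.get("omega_R0P", 0.0),
            sigma_add=d.get("sigma_add", 0.0), sigma_prop=d.get("sigma_prop", 0.0),
        )


def typical_params(pop: PopulationParams, cov: SubjectCovariates) -> StructuralParams:
    """Covariate-adjusted typical structural parameters for one subject.

    V1 scales with (BW/BWref)^beta_BW_V1 and exp(beta_SX_V1) in males; CL with
    exp(beta_SX_CL) in males; R0C with exp(beta_UC_R0C) in UC.  AS subjects get
    both TMDD arms switched off (linear reference kinetics).
    """
    th = pop.theta
    male = 1.0 if cov.male else 0.0
    v1 = th.V1 * (cov.BW / pop.bw_ref) ** pop.beta_BW_V1 * np.exp(pop.beta_SX_V1 * male)
    cl = th.CL * np.exp(pop.beta_SX_CL * male)
    r0c = th.R0C * (np.exp(pop.beta_UC_R0C) if cov.disease == "UC" else 1.0)
    kw = dict(V1=v1, CL=cl, R0C=r0c)
    if cov.disease == "AS":
        kw.update(tmdd_central=False, tmdd_peripheral=False, R0C=0.0, R0P=0.0,
                  kintC=0.0, kintP=0.0)
    return th.replace(**kw)


def individual_params(typical: StructuralParams, eta) -> StructuralParams:
    """Apply exponential random effects; ``eta`` indexed as ETA_PARAMS."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (5,):
        raise ValueError("eta must have length 5 (V1, CL, V2, R0C, R0P)")
    return typical.replace(
        V1=typical.V1 * np.exp(eta[0]),
        CL=typical.CL * np.exp(eta[1]),
        V2=typical.V2 * np.exp(eta[2]),
        R0C=typical.R0C * np.exp(eta[3]),
        R0P=typical.R0P * np.exp(eta[4]),
    )


def residual_sd(pred_conc, sigma_add, sigma_prop, form: str = "combined1"):
    """Per-observation residual SD (mg/L) of the mixed error model."""
    f = np.asarray(pred_conc, dtype=float)
    if form == "combined1":
        return sigma_add + sigma_prop * f
    if form == "combined2":
        return np.sqrt(sigma_add**2 + (sigma_prop * f) ** 2)
    raise ValueError(f"unknown error form {form!r}")


def residual_error(pred_conc, sigma_add, sigma_prop, epsilon, form: str = "combined1"):
    """Observed concentration y = f + sd(f) * eps (mg/L)."""
    f = np.asarray(pred_conc, dtype=float)
    return f + residual_sd(f, sigma_add, sigma_prop, form) * np.asarray(epsilon)


# ---------------------------------------------------------------------------
# Published parameter sets (double-TMDD model of infliximab in IBD, with the
# AS cohort as the linear reference).  These define the default study
# conditions of the synthetic-data generator and simulation study.
# ---------------------------------------------------------------------------

def final_model_params() -> PopulationParams:
    """Final covariate model estimates (double central+peripheral TMDD)."""
    theta = StructuralParams(
        V1=2.6, V2=1.9, CL=0.16, Q=1.8,
        R0C=3.3, KSSC=15.4, kintC=0.17,
        R0P=0.46, KSSP=0.49, kintP=0.0079,
        kout=20.0, tmdd_central=True, tmdd_peripheral=True,
    )
    return PopulationParams(
        theta=theta,
        beta_BW_V1=0.33, beta_SX_V1=0.13, beta_SX_CL=0.36, beta_UC_R0C=0.57,
        bw_ref=DEFAULT_BWREF,
        omega_V1=0.27, omega_CL=0.35, omega_V2=0.39, omega_R0C=1.0, omega_R0P=1.1,
        sigma_add=1.8, sigma_prop=0.20,
    )


def base_model_params() -> PopulationParams:
    """Base (covariate-free) double-TMDD estimates."""
    theta = StructuralParams(
        V1=2.8, V2=1.9, CL=0.20, Q=1.5,
        R0C=2.6, KSSC=13.7, kintC=0.13,
        R0P=0.30, KSSP=0.45, kintP=0.0050,
        kout=20.0, tmdd_central=True, tmdd_peripheral=True,
    )
    return PopulationParams(
        theta=theta,
        omega_V1=0.29, omega_CL=0.38, omega_V2=0.36, omega_R0C=1.0, omega_R0P=1.2,
        sigma_add=1.8, sigma_prop=0.20,
    )
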