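"""Synthetic study dataset generator.

Emulates the two study designs (rich AS reference cohort, sparse routine IBD
cohort) without any external data: covariates are drawn from the cohort
distributions, weight-based doses are rounded to the vial size, latent
concentration profiles are simulated with the structural + population model,
residual assay error is added, and records below the lower limit of
quantitation (0.103 mg/L) are flagged as censored.  All subjects are
ADA-free by construction.  Values above the 15 mg/L upper limit are retained
as-is (dilution-corrected reporting assumed).

Datasets are carried in a NONMEM-style table with columns
ID, TIME, AMT, RATE, DV, EVID, MDV, CENS, BW, SEX, DIS, COHORT
(SEX 0=F/1=M; DIS 0=CD/1=UC/2=AS) and round-trip bit-identically through CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import designs as _designs
from .designs import LLOQ, StudyDesign, CovariateSpec, DESIGNS
from .population import (ETA_PARAMS, PopulationParams, SubjectCovariates,
                         individual_params, residual_error, typical_params)
from .structural import DoseEvent, StructuralParams, linear_profile_conc, simulate_profile
from .units import UnitSystem

__all__ = [
    "StudyDataset", "SubjectRecord", "sample_covariates", "dose_from_weight",
    "generate_dataset", "generate_joint_dataset",
]

GENERATOR_VERSION = "1.0"
_DIS_CODE = {"CD": 0, "UC": 1, "AS": 2}
_DIS_NAME = {v: k for k, v in _DIS_CODE.items()}

NONMEM_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV", "CENS",
                  "BW", "SEX", "DIS", "COHORT"]


@dataclass
class SubjectRecord:
    """One subject: covariates, dosing events and (when simulated) true etas."""

    id: int
    covariates: SubjectCovariates
    doses: list
    age: float | None = None
    eta: np.ndarray | None = None


@dataclass
class StudyDataset:
    """A study dataset: NONMEM-style table + per-subject structure + provenance."""

    df: pd.DataFrame
    subjects: list
    provenance: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    @property
    def n_obs(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, provenance: dict | None = None) -> "StudyDataset":
        df = pd.read_csv(path)
        missing = [c for c in NONMEM_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        subjects = []
        for sid, g in df.groupby("ID", sort=True):
            first = g.iloc[0]
            cov = SubjectCovariates(
                BW=float(first["BW"]), male=bool(int(first["SEX"])),
                disease=_DIS_NAME[int(first["DIS"])], cohort=str(first["COHORT"]),
            )
            doses = []
            for _, row in g[g["EVID"] == 1].iterrows():
                amt = float(row["AMT"])
                rate = float(row["RATE"])
                doses.append(DoseEvent(time=float(row["TIME"]), amount_mg=amt,
                                       duration=amt / rate if rate > 0 else _designs.INFUSION_DUR))
            subjects.append(SubjectRecord(id=int(sid), covariates=cov, doses=doses))
        return cls(df=df, subjects=subjects, provenance=provenance or {})


def dose_from_weight(bw_kg: float, dose_per_kg: float = 5.0, vial_mg: float = 100.0) -> float:
    """Weight-based dose rounded half-up to the nearest vial (100 mg)."""
    if bw_kg <= 0:
        raise ValueError("body weight must be positive")
    return math.floor(bw_kg * dose_per_kg / vial_mg + 0.5) * vial_mg


def _trunc_normal(rng, mean, sd, lo, hi, n):
    """Truncated Gaussian by rejection (fast for mild truncation)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def sample_covariates(cohort, n: int, seed=None, rng=None):
    """Draw ``n`` subjects' covariates from a cohort spec.

    ``cohort`` is a CovariateSpec or one of the names "as", "ibd",
    "scenario".  Returns (list of SubjectCovariates, ages array).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    spec = _resolve_cov_spec(cohort)
    label = cohort if isinstance(cohort, str) else ""
    if rng is None:
        rng = np.random.default_rng(seed)
    bw = _trunc_normal(rng, spec.bw_mean, spec.bw_sd, spec.bw_lo, spec.bw_hi, n)
    male = rng.random(n) < spec.p_male
    if spec.disease_pool == ("AS",):
        disease = np.array(["AS"] * n)
    else:
        disease = np.where(rng.random(n) < spec.p_uc, "UC", "CD")
    ages = rng.normal(spec.age_mean, spec.age_sd, size=n)
    covs = [SubjectCovariates(BW=float(bw[i]), male=bool(male[i]),
                              disease=str(disease[i]), cohort=label)
            for i in range(n)]
    return covs, ages


def _resolve_cov_spec(cohort) -> CovariateSpec:
    if isinstance(cohort, CovariateSpec):
        return cohort
    table = {"as": _designs.AS_COVARIATES, "ibd": _designs.IBD_COVARIATES,
             "scenario": _designs.SCENARIO_COVARIATES}
    try:
        return table[cohort]
    except KeyError:
        raise ValueError(f"unknown cohort {cohort!r}; expected one of {sorted(table)}")


def _predict_conc(params: StructuralParams, doses, times, units: UnitSystem):
    """Latent serum concentration (mg/L) at the sampling times."""
    if params.is_linear:
        return linear_profile_conc(params, doses, times, units)
    traj = simulate_profile(params, doses, times, units=units, rtol=1e-8, atol=1e-10)
    return traj["conc_mgL"].to_numpy()


def generate_dataset(
    design: StudyDesign,
    pop: PopulationParams,
    n: int,
    seed: int,
    missingness: float = 0.10,
    units: UnitSystem | None = None,
    id_offset: int = 0,
) -> StudyDataset:
    """Simulate one cohort under a design and population model.

    Per-sample independent dropout (default 10%) emulates real-world missing
    visits.  Residual error is drawn per observation; negative simulated
    concentrations are truncated at zero and anything below the LLOQ is
    flagged censored with the LLOQ recorded as the bound.
    """
    units = units or UnitSystem()
    rng = np.random.default_rng(seed)
    covs, ages = sample_covariates(design.covariates, n, rng=rng)
    covs = [SubjectCovariates(BW=c.BW, male=c.male,
                              disease="AS" if design.linear_kinetics else c.disease,
                              cohort=design.name)
            for c in covs]
    omegas = pop.omegas
    rows = []
    subjects = []
    for i in range(n):
        sid = id_offset + i + 1
        cov = covs[i]
        eta = rng.normal(0.0, 1.0, size=5) * omegas
        typ = typical_params(pop, cov)
        ind = individual_params(typ, eta)
        amt = dose_from_weight(cov.BW, design.dose_mg_per_kg)
        doses = [DoseEvent(time=t, amount_mg=amt, duration=design.infusion_duration)
                 for t in design.dose_days]
        t_samp = np.array([t for t, _ in design.sample_times])
        labels = [lab for _, lab in design.sample_times]
        keep = rng.random(t_samp.size) >= missingness
        try:
            f = _predict_conc(ind, doses, t_samp, units)
        except Exception as exc:  # noqa: BLE001 - annotate subject then re-raise
            raise RuntimeError(f"simulation failed for subject {sid}") from exc
        eps = rng.normal(0.0, 1.0, size=t_samp.size)
        y = residual_error(f, pop.sigma_add, pop.sigma_prop, eps, pop.error_form)
        y = np.maximum(y, 0.0)
        sex = int(cov.male)
        dis = _DIS_CODE[cov.disease]
        for d in doses:
            rows.append((sid, d.time, d.amount_mg, d.rate_mg_day, 0.0, 1, 1, 0,
                         cov.BW, sex, dis, design.name))
        for j in range(t_samp.size):
            if not keep[j]:
                continue
            cens = int(y[j] < LLOQ)
            dv = LLOQ if cens else y[j]
            rows.append((sid, t_samp[j], 0.0, 0.0, dv, 0, 0, cens,
                         cov.BW, sex, dis, design.name))
        subjects.append(SubjectRecord(id=sid, covariates=cov, doses=doses,
                                      age=float(ages[i]), eta=eta))
    df = pd.DataFrame(rows, columns=NONMEM_COLUMNS)
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    prov = {
        "generator_version": GENERATOR_VERSION,
        "design": design.name,
        "n": n,
        "seed": int(seed),
        "missingness": missingness,
        "true_params": pop.to_dict(),
        "note": "synthetic cohort; sampling template is an emulation of the design",
    }
    return StudyDataset(df=df, subjects=subjects, provenance=prov)


def generate_joint_dataset(pop: PopulationParams, n_as: int, n_ibd: int, seed: int,
                           ibd_design: StudyDesign | None = None,
                           missingness: float = 0.10) -> StudyDataset:
    """AS reference cohort + IBD cohort in one dataset (IDs 1..n_as, then IBD)."""
    ss = np.random.SeedSequence(seed)
    s_as, s_ibd = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
    das = generate_dataset(_designs.AS_RICH, pop, n_as, s_as, missingness=missingness)
    dibd = generate_dataset(ibd_design or _designs.IBD_SPARSE, pop, n_ibd, s_ibd,
                            missingness=missingness, id_offset=n_as)
    df = pd.concat([das.df, dibd.df], ignore_index=True)
    prov = {"generator_version": GENERATOR_VERSION, "seed": int(seed),
            "components": [das.provenance, dibd.provenance]}
    return StudyDataset(df=df, subjects=das.subjects + dibd.subjects, provenance=prov)
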