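"""Study designs: dosing schedules, sampling templates, covariate distributions.

Three designs are bundled:

* ``as_rich`` — ankylosing-spondylitis-like reference cohort: 5 mg/kg at weeks
  0, 2, 6, 12, 18 with dense sampling (pre-dose, 2 h and 4 h after each
  infusion, plus intermediate visits at weeks 1, 3, 4, 5, 8, 10, 14);
  linear reference kinetics (no TMDD).
* ``ibd_sparse`` — routine IBD cohort: 5 mg/kg at weeks 0, 2, 6, then every 8
  weeks (induction + first maintenance cycles retained here, i.e. weeks 0, 2,
  6, 14, 22), with trough and peak samples per cycle.
* ``ibd_rich`` — the IBD regimen with dense sampling, used for simulation
  studies of estimator recovery.

Dose amounts are weight-based and rounded to the nearest 100 mg vial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: lower/upper limits of quantitation of the assay (mg/L)
LLOQ = 0.103
ULOQ = 15.0

#: 2-h infusion, peak drawn 1 h after the end of the infusion
INFUSION_DUR = 2.0 / 24.0
PEAK_OFFSET = INFUSION_DUR + 1.0 / 24.0


@dataclass(frozen=True)
class CovariateSpec:
    """Truncated-Gaussian body weight plus categorical frequencies."""

    bw_mean: float
    bw_sd: float
    bw_lo: float = 41.0
    bw_hi: float = 110.0
    p_male: float = 0.5
    p_uc: float = 0.0          # P(UC) among IBD; ignored when disease == "AS"
    disease_pool: tuple = ("CD", "UC")
    age_mean: float = 40.0
    age_sd: float = 12.0


@dataclass(frozen=True)
class StudyDesign:
    """Dosing rule + sampling template + covariate distribution for one cohort."""

    name: str
    dose_days: tuple
    dose_mg_per_kg: float
    sample_times: tuple          # (time_day, label) pairs
    covariates: CovariateSpec
    linear_kinetics: bool = False   # AS reference cohort: TMDD off
    infusion_duration: float = INFUSION_DUR

    def __post_init__(self) -> None:
        times = [t for t, _ in self.sample_times]
        if any(t < 0 for t in times) or sorted(times) != list(times):
            raise ValueError("sampling times must be non-negative and sorted")


def _as_samples(dose_days):
    out = []
    for d in dose_days:
        out.append((d, "trough"))
        out.append((d + 2.0 / 24.0, "peak"))
        out.append((d + 4.0 / 24.0, "peak"))
    for w in (1, 3, 4, 5, 8, 10, 14):
        out.append((7.0 * w, "intermediate"))
    return tuple(sorted(out))


def _ibd_sparse_samples(dose_days):
    out = []
    for d in dose_days[:3]:
        out.append((d + PEAK_OFFSET, "peak"))
    for d in dose_days[1:]:
        out.append((d, "trough"))
    return tuple(sorted(out))


def _ibd_rich_samples(dose_days):
    out = []
    for d in dose_days:
        out.append((d, "trough"))
        out.append((d + PEAK_OFFSET, "peak"))
    # early-washout samples after doses 1, 3 and 5: trough/peak-only designs
    # leave the distribution phase (the V1/V2/Q split) unidentified
    for d in (1, 3, 43, 45, 155, 157):
        out.append((float(d), "intermediate"))
    for d in (7, 21, 28, 56, 70, 84, 112, 126, 140, 168, 182, 196):
        out.append((float(d), "intermediate"))
    return tuple(sorted(out))


_AS_DOSES = tuple(7.0 * w for w in (0, 2, 6, 12, 18))
_IBD_DOSES = tuple(7.0 * w for w in (0, 2, 6, 14, 22))

AS_COVARIATES = CovariateSpec(bw_mean=75.0, bw_sd=15.0, p_male=19 / 25,
                              disease_pool=("AS",), age_mean=43.0)
IBD_COVARIATES = CovariateSpec(bw_mean=64.0, bw_sd=12.0, p_male=80 / 133,
                               p_uc=25 / 133, age_mean=34.0)
#: covariate scenario of the occupancy simulation study
SCENARIO_COVARIATES = CovariateSpec(bw_mean=66.0, bw_sd=15.0, p_male=0.5, p_uc=1 / 6)

AS_RICH = StudyDesign(
    name="as_rich", dose_days=_AS_DOSES, dose_mg_per_kg=5.0,
    sample_times=_as_samples(_AS_DOSES), covariates=AS_COVARIATES,
    linear_kinetics=True,
)
IBD_SPARSE = StudyDesign(
    name="ibd_sparse", dose_days=_IBD_DOSES, dose_mg_per_kg=5.0,
    sample_times=_ibd_sparse_samples(_IBD_DOSES), covariates=IBD_COVARIATES,
)
IBD_RICH = StudyDesign(
    name="ibd_rich", dose_days=_IBD_DOSES, dose_mg_per_kg=5.0,
    sample_times=_ibd_rich_samples(_IBD_DOSES), covariates=IBD_COVARIATES,
)

DESIGNS = {d.name: d for d in (AS_RICH, IBD_SPARSE, IBD_RICH)}
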