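"""Model comparison and covariate selection.

Structural variants are compared by AIC (= -2LL + 2 * number of estimated
parameters); nested statistical models by the likelihood ratio test, the
-2LL difference referred to a chi-square distribution.  Covariate screening
follows the classical two-stage procedure: a univariate step admitting
covariates at alpha = 0.05 into a full model, then backward elimination
keeping only covariates whose removal raises -2LL significantly at
alpha = 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelVariant, TMDDModel, TMDDResults
from .population import PopulationParams

__all__ = ["lrt_pvalue", "kout_grid_select", "structural_ladder",
           "covariate_stepwise", "StepwiseTrail"]

#: kout candidates (per day) spanning reported target half-lives across species
DEFAULT_KOUT_GRID = (5.0, 10.0, 20.0, 40.0, 100.0, 150.0, 200.0)

#: default covariate-parameter candidates for the stepwise screen
DEFAULT_CANDIDATES = (("BW", "V1"), ("SX", "V1"), ("SX", "CL"), ("DIS", "R0C"))

_COV_ORDER = {"BW": 0, "SX": 1, "DIS": 2}


def lrt_pvalue(neg2ll_reduced: float, neg2ll_full: float, df: int) -> float:
    """Likelihood ratio test p-value for nested models.

    Negative -2LL differences (numerical noise) are clamped to zero.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = max(neg2ll_reduced - neg2ll_full, 0.0)
    return float(stats.chi2.sf(delta, df))


def _model_like(model: TMDDModel, **overrides) -> TMDDModel:
    kw = dict(variant=model.variant, kout=model.kout,
              covariate_effects=model.covariate_effects,
              error_form=model.error_form, units=model.units,
              bw_ref=model.bw_ref, fit_step_init=model.fit_step_init,
              fit_step_max=model.fit_step_max)
    kw.update(overrides)
    return TMDDModel(model.dataset, **kw)


def kout_grid_select(dataset, variant=ModelVariant.double_tmdd,
                     grid=DEFAULT_KOUT_GRID, start: PopulationParams | None = None,
                     maxiter: int = 60, warm_start: bool = True,
                     start_result: TMDDResults | None = None,
                     refine_steps: tuple | None = (0.002, 0.1), **model_kw):
    """Fit the model with ``kout`` fixed at each grid value; pick the AIC argmin.

    Ties break toward the smaller kout.  Returns (best_kout, table, results)
    where table is a DataFrame of kout / -2LL / AIC / converged and results
    maps kout -> TMDDResults.  Non-convergent grid points are kept in the
    table but excluded from the argmin with a warning column.

    With ``start_result`` every grid fit starts from the same incumbent
    (parameters and conditional modes), so convergence effort is symmetric.
    With ``refine_steps`` (an (h0, hmax) pair for the fixed-schedule
    integrator) each fitted optimum is re-evaluated at that finer schedule
    before the comparison: the production schedule's discretisation error is
    kout-dependent and of the same order as the grid's likelihood
    differences, so the final comparison uses the refined values.
    """
    grid = tuple(grid)
    if not grid:
        raise ValueError("kout grid must be non-empty")
    rows = []
    results = {}
    prev = start
    prev_etas = None
    if start_result is not None:
        prev = start_result.params
        prev_etas = start_result.etas
        warm_start = False
    for k in sorted(grid):
        model = TMDDModel(dataset, variant=variant, kout=k, **model_kw)
        res = model.fit(start=prev, maxiter=maxiter, start_etas=prev_etas)
        results[k] = res
        row = {"kout": k, "neg2ll": res.neg2ll, "aic": res.aic,
               "n_params": res.n_params, "converged": res.converged}
        if refine_steps is not None:
            fine = TMDDModel(dataset, variant=variant, kout=k,
                             fit_step_init=refine_steps[0],
                             fit_step_max=refine_steps[1], **model_kw)
            n2_fine = fine.neg2ll(res.params)
            row["neg2ll_fine"] = n2_fine
            row["aic_fine"] = n2_fine + 2.0 * res.n_params
        rows.append(row)
        if warm_start:
            prev = res.params
    table = pd.DataFrame(rows)
    crit = "aic_fine" if refine_steps is not None else "aic"
    ok = table[table["converged"]]
    pool = ok if len(ok) else table
    best = float(pool.sort_values([crit, "kout"]).iloc[0]["kout"])
    return best, table, results


def structural_ladder(dataset, kout: float = 20.0, starts: dict | None = None,
                      maxiter: int = 60, **model_kw) -> pd.DataFrame:
    """Fit the four structural variants and rank them by AIC.

    Returns a DataFrame sorted by AIC (ties by parameter count) with columns
    variant / -2LL / AIC / n_params / converged.  Per-variant failures are
    recorded and ranked over the remainder.
    """
    rows = []
    for variant in ModelVariant:
        model = TMDDModel(dataset, variant=variant, kout=kout, **model_kw)
        start = (starts or {}).get(variant)
        try:
            res = model.fit(start=start, maxiter=maxiter)
            rows.append({"variant": variant.value, "neg2ll": res.neg2ll,
                         "aic": res.aic, "n_params": res.n_params,
                         "converged": res.converged, "error": ""})
        except Exception as exc:  # noqa: BLE001 - keep ranking over the rest
            rows.append({"variant": variant.value, "neg2ll": np.nan,
                         "aic": np.inf, "n_params": np.nan,
                         "converged": False, "error": str(exc)})
    out = pd.DataFrame(rows).sort_values(["aic", "n_params"]).reset_index(drop=True)
    return out


@dataclass
class StepwiseTrail:
    """Audit trail of the two-stage covariate screen."""

    univariate: pd.DataFrame
    backward: list = field(default_factory=list)
    selected: tuple = ()
    base_neg2ll: float = np.nan
    final: TMDDResults | None = None

    def __str__(self) -> str:
        lines = ["Univariate step (alpha = %.3g):" % self.alpha_in,
                 self.univariate.to_string(index=False)]
        for step in self.backward:
            lines.append(str(step))
        lines.append(f"selected: {list(self.selected)}")
        return "\n".join(lines)

    alpha_in: float = 0.05
    alpha_out: float = 0.02


def covariate_stepwise(dataset, variant=ModelVariant.double_tmdd, kout: float = 20.0,
                       candidates=DEFAULT_CANDIDATES, alpha_in: float = 0.05,
                       alpha_out: float = 0.02, start: PopulationParams | None = None,
                       maxiter: int = 60, base_result: TMDDResults | None = None,
                       **model_kw) -> StepwiseTrail:
    """Two-stage covariate selection with a full decision log.

    Candidates are (covariate, parameter) pairs; only parameters carrying an
    estimated interindividual variance in the chosen variant are screened.
    At equal p-values covariates enter in the fixed order BW, SX, DIS for
    reproducibility.
    """
    base_model = TMDDModel(dataset, variant=variant, kout=kout,
                           covariate_effects=(), **model_kw)
    allowed = set(base_model.variant.omega_names)
    candidates = tuple((c, p) for c, p in candidates if p in allowed)
    base = base_result or base_model.fit(start=start, maxiter=maxiter)
    if not candidates:
        return StepwiseTrail(univariate=pd.DataFrame(), selected=(),
                             base_neg2ll=base.neg2ll, final=base,
                             alpha_in=alpha_in, alpha_out=alpha_out)

    uni_rows = []
    for cand in candidates:
        m = TMDDModel(dataset, variant=variant, kout=kout,
                      covariate_effects=(cand,), **model_kw)
        try:
            r = m.fit(start=base.params, maxiter=maxiter)
            # guard the LRT against base-fit under-convergence: the base
            # model evaluated at the candidate's non-covariate parameters is
            # a valid (if unoptimised) base likelihood, so use the better one
            base_at_cand = base_model.results_from_params(r.params).neg2ll
            base_neg2ll = min(base.neg2ll, base_at_cand)
            p = lrt_pvalue(base_neg2ll, r.neg2ll, df=1)
            uni_rows.append({"covariate": cand[0], "parameter": cand[1],
                             "neg2ll": r.neg2ll,
                             "delta": base_neg2ll - r.neg2ll, "p": p,
                             "significant": p < alpha_in, "converged": r.converged})
        except Exception as exc:  # noqa: BLE001
            uni_rows.append({"covariate": cand[0], "parameter": cand[1],
                             "neg2ll": np.nan, "delta": np.nan, "p": np.nan,
                             "significant": False, "converged": False,
                             "error": str(exc)})
    uni = pd.DataFrame(uni_rows)
    selected = [
        (row["covariate"], row["parameter"])
        for _, row in uni.iterrows() if bool(row["significant"])
    ]
    selected.sort(key=lambda cp: (_COV_ORDER.get(cp[0], 9), cp[1]))
    trail = StepwiseTrail(univariate=uni, base_neg2ll=base.neg2ll,
                          alpha_in=alpha_in, alpha_out=alpha_out)
    if not selected:
        trail.selected = ()
        trail.final = base
        return trail

    def fit_with(effects, init):
        m = TMDDModel(dataset, variant=variant, kout=kout,
                      covariate_effects=tuple(effects), **model_kw)
        return m.fit(start=init, maxiter=maxiter)

    full = fit_with(selected, base.params)
    # backward elimination at alpha_out
    current = list(selected)
    current_fit = full
    while len(current) > 1:
        drops = []
        for cand in current:
            reduced = [c for c in current if c != cand]
            r = fit_with(reduced, current_fit.params)
            p = lrt_pvalue(r.neg2ll, current_fit.neg2ll, df=1)
            drops.append((p, cand, r))
        # least significant covariate = largest removal p-value
        drops.sort(key=lambda t: (-t[0], _COV_ORDER.get(t[1][0], 9), t[1][1]))
        p, cand, r = drops[0]
        trail.backward.append(
            f"remove {cand}: p = {p:.4g} ({'drop' if p >= alpha_out else 'keep all'})")
        if p >= alpha_out:
            current.remove(cand)
            current_fit = r
        else:
            break
    if len(current) == 1:
        # test the last covariate against the covariate-free base
        p = lrt_pvalue(base.neg2ll, current_fit.neg2ll, df=1)
        trail.backward.append(
            f"remove {current[0]}: p = {p:.4g} ({'drop' if p >= alpha_out else 'keep'})")
        if p >= alpha_out:
            current = []
            current_fit = base
    trail.selected = tuple(current)
    trail.final = current_fit
    return trail
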