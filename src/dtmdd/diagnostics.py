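"""Simulation-based goodness-of-fit diagnostics: GOF table, VPC, NPDE.

All three are pure functions of (fitted results, seed): population residuals
(WRES) and prediction distribution errors are computed from the simulated
mean and covariance of each subject's observation vector rather than a
linearisation, and the normalized prediction distribution errors follow the
standard reference algorithm — decorrelation of observed and simulated
vectors with the lower-triangular (time-ordered Cholesky) square root of the
simulated covariance, rank-based probabilities and an inverse-normal map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .population import residual_sd

__all__ = ["gof_table", "vpc", "npde"]


def _sim_matrix(results, n_reps: int, seed: int) -> np.ndarray:
    return results.model.simulate_dv_matrix(results.params, n_reps, seed)


def gof_table(results, n_reps: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-observation diagnostics: PRED, IPRED, WRES, IWRES.

    IPRED comes from the empirical-Bayes modes; IWRES uses the residual-error
    SD at IPRED.  PRED and WRES come from the simulation-based mean and
    covariance of each subject's observation vector (``n_reps`` replicates of
    the observed design), so WRES accounts for the within-subject correlation
    induced by the random effects.
    """
    model = results.model
    d = model._data
    ipred = model.predict_conc(results.params, etas=results.etas)
    sims = _sim_matrix(results, n_reps, seed)
    pop = results.params
    rows = []
    for i in range(model.n_subjects):
        o0, o1 = d.obs_ptr[i], d.obs_ptr[i + 1]
        y = d.obs_y[o0:o1]
        if o1 == o0:
            continue
        S = sims[:, o0:o1]
        mu = S.mean(axis=0)
        cov = np.cov(S, rowvar=False)
        cov = np.atleast_2d(cov) + 1e-10 * np.eye(o1 - o0)
        try:
            L = np.linalg.cholesky(cov)
            wres = np.linalg.solve(L, y - mu)
        except np.linalg.LinAlgError:
            wres = (y - mu) / np.maximum(S.std(axis=0), 1e-10)
        sd_i = residual_sd(ipred[o0:o1], pop.sigma_add, pop.sigma_prop,
                           pop.error_form)
        iwres = (y - ipred[o0:o1]) / np.maximum(sd_i, 1e-10)
        for j in range(o1 - o0):
            rows.append({"ID": d.ids[i], "TIME": d.obs_t[o0 + j], "DV": y[j],
                         "PRED": mu[j], "IPRED": ipred[o0 + j],
                         "WRES": wres[j], "IWRES": iwres[j]})
    return pd.DataFrame(rows)


def vpc(results, n_reps: int = 1000, percentiles=(10, 50, 90), seed: int = 0,
        bins=None) -> pd.DataFrame:
    """Visual predictive check table: observed percentiles per time bin vs the
    simulated percentile bands (2.5/50/97.5% of each percentile across
    replicates).

    Bins default to the distinct nominal observation times of the design
    (scheduled studies); pass explicit bin edges for data-driven binning.
    Bins with fewer than 5 observations are flagged.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    model = results.model
    d = model._data
    t = d.obs_t
    y = d.obs_y
    sims = _sim_matrix(results, n_reps, seed)
    if bins is None:
        uniq = np.unique(np.round(t, 6))
        idx = np.searchsorted(uniq, np.round(t, 6))
        centers = uniq
    else:
        edges = np.asarray(bins)
        idx = np.clip(np.digitize(t, edges) - 1, 0, len(edges) - 2)
        centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for b in range(len(centers)):
        m = idx == b
        nb = int(m.sum())
        if nb == 0:
            continue
        row = {"bin_time": float(centers[b]), "n_obs": nb, "flagged": nb < 5}
        simsel = sims[:, m]
        for q in percentiles:
            row[f"obs_p{q}"] = float(np.percentile(y[m], q))
            rep_q = np.percentile(simsel, q, axis=1)
            row[f"sim_p{q}_lo"] = float(np.percentile(rep_q, 2.5))
            row[f"sim_p{q}_med"] = float(np.percentile(rep_q, 50))
            row[f"sim_p{q}_hi"] = float(np.percentile(rep_q, 97.5))
        rows.append(row)
    return pd.DataFrame(rows)


def npde(results, n_reps: int = 1000, seed: int = 0):
    """Normalized prediction distribution errors with a global normality check.

    Per subject the observed and simulated vectors are decorrelated with the
    simulated mean and the inverse lower-triangular Cholesky factor of the
    simulated covariance (observations time-ordered); prediction distribution
    errors are the ranks of the decorrelated observations among the
    decorrelated simulations, jittered to break ties, clipped to
    (1/(2 n_reps), 1 - 1/(2 n_reps)) and mapped through the standard normal
    quantile function.  Under a correct model NPDE ~ N(0, 1).

    Returns (DataFrame with per-observation NPDE, summary dict with mean,
    variance, and Shapiro/KS normality statistics).
    """
    model = results.model
    d = model._data
    sims = _sim_matrix(results, n_reps, seed)
    rng = np.random.default_rng(seed + 1)
    lo = 1.0 / (2.0 * n_reps)
    rows = []
    for i in range(model.n_subjects):
        o0, o1 = d.obs_ptr[i], d.obs_ptr[i + 1]
        ni = o1 - o0
        if ni == 0:
            continue
        S = sims[:, o0:o1]
        mu = S.mean(axis=0)
        cov = np.atleast_2d(np.cov(S, rowvar=False))
        ridge = 0.0
        for _ in range(6):
            try:
                L = np.linalg.cholesky(cov + ridge * np.eye(ni))
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10.0, 1e-8 * np.trace(cov) / ni)
        else:
            continue
        dec_obs = np.linalg.solve(L, d.obs_y[o0:o1] - mu)
        dec_sim = np.linalg.solve(L, (S - mu).T)  # (ni, n_reps)
        for j in range(ni):
            u = (np.sum(dec_sim[j] < dec_obs[j])
                 + rng.uniform(0.0, 1.0) * np.sum(dec_sim[j] == dec_obs[j])) / n_reps
            u = min(max(u, lo), 1.0 - lo)
            rows.append({"ID": d.ids[i], "TIME": d.obs_t[o0 + j],
                         "DV": d.obs_y[o0 + j], "pde": u,
                         "npde": stats.norm.ppf(u)})
    table = pd.DataFrame(rows)
    vals = table["npde"].to_numpy()
    ks = stats.kstest(vals, "norm")
    summary = {
        "n": int(vals.size),
        "mean": float(np.mean(vals)),
        "variance": float(np.var(vals, ddof=1)),
        "t_stat_mean_zero": float(stats.ttest_1samp(vals, 0.0).statistic),
        "ks_stat": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }
    return table, summary


def write_report(results, outdir, n_reps: int = 1000, seed: int = 0):
    """Write the diagnostics bundle: CSV tables plus a figure.

    Produces gof.csv, vpc.csv, npde.csv and diagnostics.png (observed vs
    PRED/IPRED, IWRES vs IPRED, NPDE histogram against the standard normal,
    and the VPC band plot) under ``outdir``.  Returns the output paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gof = gof_table(results, n_reps=n_reps, seed=seed)
    vpc_tab = vpc(results, n_reps=n_reps, seed=seed)
    npde_tab, npde_sum = npde(results, n_reps=n_reps, seed=seed)
    gof.to_csv(outdir / "gof.csv", index=False)
    vpc_tab.to_csv(outdir / "vpc.csv", index=False)
    npde_tab.to_csv(outdir / "npde.csv", index=False)

    fig, axes = plt.subplots(2, 3, figsize=(13, 8))
    lim = [0.0, float(max(gof["DV"].max(), gof["PRED"].max()) * 1.05)]
    for ax, col in zip(axes[0, :2], ("PRED", "IPRED")):
        ax.plot(gof[col], gof["DV"], "o", ms=3, alpha=0.4)
        ax.plot(lim, lim, "k-", lw=1)
        ax.set_xlabel(f"{col} (mg/L)")
        ax.set_ylabel("observed (mg/L)")
    axes[0, 2].plot(gof["IPRED"], gof["IWRES"], "o", ms=3, alpha=0.4)
    axes[0, 2].axhline(0.0, color="k", lw=1)
    axes[0, 2].set_xlabel("IPRED (mg/L)")
    axes[0, 2].set_ylabel("IWRES")
    axes[1, 0].plot(gof["PRED"], gof["WRES"], "o", ms=3, alpha=0.4)
    axes[1, 0].axhline(0.0, color="k", lw=1)
    axes[1, 0].set_xlabel("PRED (mg/L)")
    axes[1, 0].set_ylabel("WRES")
    x = np.linspace(-4, 4, 200)
    axes[1, 1].hist(npde_tab["npde"], bins=30, density=True, alpha=0.6)
    axes[1, 1].plot(x, np.exp(-x**2 / 2) / np.sqrt(2 * np.pi), "k--")
    axes[1, 1].set_xlabel("NPDE")
    ax = axes[1, 2]
    for q in (10, 50, 90):
        if f"obs_p{q}" in vpc_tab.columns:
            ax.fill_between(vpc_tab["bin_time"], vpc_tab[f"sim_p{q}_lo"],
                            vpc_tab[f"sim_p{q}_hi"], alpha=0.25)
            ax.plot(vpc_tab["bin_time"], vpc_tab[f"obs_p{q}"], "o-", ms=3)
    ax.set_xlabel("time (day)")
    ax.set_ylabel("concentration (mg/L)")
    fig.suptitle(f"NPDE mean {npde_sum['mean']:.3f}, "
                 f"variance {npde_sum['variance']:.3f}, "
                 f"KS p {npde_sum['ks_pvalue']:.3g}")
    fig.tight_layout()
    fig.savefig(outdir / "diagnostics.png", dpi=110)
    plt.close(fig)
    return {"gof": outdir / "gof.csv", "vpc": outdir / "vpc.csv",
            "npde": outdir / "npde.csv", "figure": outdir / "diagnostics.png"}
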