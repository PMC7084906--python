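"""Model qualification: nonparametric bootstrap, visual predictive check,
and goodness-of-fit residual diagnostics.

All results are plain tables (DataFrames); plotting is a thin optional layer
in :mod:`pkbridge.plots`.  Percentiles use linear interpolation between
order statistics (numpy's default, Hyndman-Fan type 7) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import METABOLITE, PARENT, PKDataset, StudyDesign
from .population import PopPKModel, PopPKResults, simulate_dataset

__all__ = ["BootstrapResult", "VPCResult", "bootstrap", "vpc", "gof"]


@dataclass
class BootstrapResult:
    """Replicate medians and nonparametric 95% CIs.

    ``table`` summarises converged replicates; ``table_all`` ignores the
    convergence filter (both are reported because the filtering policy is a
    judgement call); ``estimates`` holds the raw replicate estimates.
    """

    table: pd.DataFrame
    table_all: pd.DataFrame
    estimates: pd.DataFrame
    n_requested: int
    n_converged: int
    warning: str | None = None


@dataclass
class VPCResult:
    """Per-bin observed percentiles and simulated prediction bands."""

    table: pd.DataFrame
    n_replicates: int


def _summarise(est: pd.DataFrame, names) -> pd.DataFrame:
    rows = []
    for n in names:
        v = est[n].to_numpy(float)
        lo, hi = np.percentile(v, [2.5, 97.5])
        rows.append((n, float(np.median(v)), float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["parameter", "median", "ci_lo", "ci_hi"])


def bootstrap(result: PopPKResults, n: int = 1000, seed: int = 0, *,
              stratify: bool = True, identity: bool = False,
              fit_kwargs: dict | None = None) -> BootstrapResult:
    """Stratified nonparametric bootstrap of the fitted model.

    Subjects are resampled with replacement within PPL-dose strata (keeping
    the covariate design estimable in every replicate) and the model is
    refitted from the original estimates.  ``identity=True`` short-circuits
    resampling and refits the original subjects (a self-consistency check).
    """
    data = result.model.data
    pop = result.params
    rng = np.random.default_rng(seed)
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("compute_se", False)
    fit_kwargs.setdefault("maxfev", 2000)
    fit_kwargs.setdefault("fatol", 0.05)
    fit_kwargs.setdefault("xatol", 1e-3)
    fit_kwargs.setdefault("presolve", True)

    subj = data.subject_table()
    if stratify:
        strata = [g["ID"].tolist() for _, g in subj.groupby("DOSE_PPL", sort=True)]
    else:
        strata = [subj["ID"].tolist()]

    names = pop.estimated_names()
    rows = []
    n_conv = 0
    for b in range(n):
        if identity:
            ids = [i for s in strata for i in s]
        else:
            ids = [i for s in strata for i in rng.choice(s, size=len(s), replace=True)]
        dsb = data.resample_subjects(ids)
        try:
            res = PopPKModel(dsb, pop).fit(**fit_kwargs)
            # usable replicate: finite optimum (the optimizer's own success
            # flag is too strict under a capped evaluation budget)
            ok = bool(np.isfinite(res.ofv))
            rec = {nme: res.params.get_value(nme) for nme in names}
        except Exception:  # non-estimable replicate
            ok, rec = False, {nme: np.nan for nme in names}
        rec["replicate"] = b
        rec["converged"] = ok
        n_conv += ok
        rows.append(rec)
    est = pd.DataFrame(rows)
    est_ok = est[est["converged"]] if n_conv else est
    warning = None
    if n and n_conv < 0.8 * n:
        warning = f"only {n_conv}/{n} bootstrap replicates converged"
        warnings.warn(warning)
    return BootstrapResult(
        table=_summarise(est_ok.dropna(), names),
        table_all=_summarise(est.dropna(), names),
        estimates=est,
        n_requested=n,
        n_converged=n_conv,
        warning=warning,
    )


def _design_from_data(data: PKDataset, lloq=0.0, uloq=np.inf) -> StudyDesign:
    subj = data.subject_table()
    df = data.df
    if "GROUP" in df.columns:
        lab = df.groupby("ID", sort=False)["GROUP"].first()
        subj = subj.assign(GROUP=subj["ID"].map(lab))
    else:
        subj = subj.assign(GROUP=subj["DOSE_PPL"].map(lambda d: f"PPL{d:g}"))
    groups = tuple(
        (str(g), float(sub["DOSE_PPL"].iloc[0]), len(sub))
        for g, sub in subj.groupby("GROUP", sort=False)
    )
    times = tuple(sorted(df.loc[df["DV"].notna(), "TIME"].unique()))
    dose = float(subj["DOSE_DLX"].iloc[0])
    return StudyDesign(groups=groups, dlx_dose=dose, sample_times=times,
                       lloq=lloq, uloq=uloq)


def vpc(result: PopPKResults, data: PKDataset | None = None, n: int = 1000,
        seed: int = 0) -> VPCResult:
    """Visual predictive check at the original design.

    Simulates ``n`` replicate studies from the fitted model, then per
    (group, analyte, nominal time) bin reports the observed 5th/50th/95th
    percentiles, the simulated 95% CI of the median, and the simulated
    5th-95th prediction band.  Bins are the exact nominal timepoints (the
    design is balanced); no quantification-range censoring is applied to
    the simulations.
    """
    data = data if data is not None else result.model.data
    pop = result.params
    design = _design_from_data(data)

    obs = data.observations(drop_blq=False, drop_predose=True).copy()
    if "GROUP" not in obs.columns:
        obs["GROUP"] = obs["DOSE_PPL"].map(lambda d: f"PPL{d:g}")

    # simulated percentiles: collect per replicate, per bin
    rng = np.random.default_rng(seed)
    sim_median = {}
    sim_values = {}
    for r in range(n):
        rep = simulate_dataset(pop, design, seed=int(rng.integers(2**31)))
        rob = rep.observations(drop_blq=False, drop_predose=True)
        for (g, a, t), sub in rob.groupby(["GROUP", "ANALYTE", "TIME"], sort=False):
            v = sub["DV"].to_numpy(float)
            sim_median.setdefault((g, a, t), []).append(np.median(v))
            sim_values.setdefault((g, a, t), []).append(v)

    rows = []
    for (g, a, t), sub in obs.groupby(["GROUP", "ANALYTE", "TIME"], sort=True):
        v = sub["DV"].to_numpy(float)
        p5, p50, p95 = np.percentile(v, [5, 50, 95])
        med = np.asarray(sim_median[(g, a, t)])
        pool = np.concatenate(sim_values[(g, a, t)])
        mlo, mhi = np.percentile(med, [2.5, 97.5])
        blo, bhi = np.percentile(pool, [5, 95])
        rows.append((g, a, t, p50, p5, p95, mlo, mhi, blo, bhi))
    table = pd.DataFrame(
        rows,
        columns=["GROUP", "ANALYTE", "TIME", "obs_median", "obs_p5", "obs_p95",
                 "median_ci_lo", "median_ci_hi", "band_lo", "band_hi"],
    )
    return VPCResult(table=table, n_replicates=n)


def gof(result: PopPKResults, data: PKDataset | None = None) -> pd.DataFrame:
    """Goodness-of-fit table: PRED, IPRED and conditional weighted residuals.

    PRED is the typical prediction (eta = 0), IPRED the individual
    prediction at the empirical Bayes eta, and CWRES decorrelates the
    residual by the model-implied covariance of the conditional (FOCE-style)
    linearisation around the eta estimate.  A singular covariance falls back
    to plain proportional weighted residuals with a warning.
    """
    if data is not None and data is not result.model.data:
        model = PopPKModel(data, result.params,
                           metabolite_input=result.model.metabolite_input)
    else:
        model = result.model
    pop = result.params
    eng = model.engine
    comp, eta = eng.ofv_components(pop)
    p = pop.structural
    q = eng.q

    pred = eng.predict(p, np.zeros((eng.S, q)) if q else None)
    ipred = eng.predict(p, eta if q else None)
    sig2 = np.where(eng.metab, pop.sigma_m**2, pop.sigma_p**2)
    g = sig2 * ipred**2

    cwres = np.empty(len(eng.y))
    if q == 0:
        cwres = (eng.y - ipred) / np.sqrt(g)
    else:
        d = 1e-5
        J = np.empty((len(eng.y), q))
        for j in range(q):
            ep = eta.copy()
            ep[:, j] += d
            em = eta.copy()
            em[:, j] -= d
            J[:, j] = (eng.predict(p, ep) - eng.predict(p, em)) / (2 * d)
        omega = np.diag([pop.omega[nme] for nme in eng.eta_names])
        for i in range(eng.S):
            sel = eng.si == i
            Ji = J[sel]
            cov = Ji @ omega @ Ji.T + np.diag(g[sel])
            r = eng.y[sel] - (ipred[sel] - Ji @ eta[i])
            try:
                L = np.linalg.cholesky(cov)
                cwres[sel] = np.linalg.solve(L, r)
            except np.linalg.LinAlgError:
                warnings.warn(
                    "singular conditional covariance; falling back to "
                    "weighted residuals"
                )
                cwres[sel] = (eng.y[sel] - ipred[sel]) / np.sqrt(g[sel])

    obs = model.data.observations()
    return pd.DataFrame({
        "ID": obs["ID"].to_numpy(),
        "TIME": eng.t,
        "ANALYTE": np.where(eng.metab, METABOLITE, PARENT),
        "DV": eng.y,
        "PRED": pred,
        "IPRED": ipred,
        "CWRES": cwres,
    })
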