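"""Monte-Carlo simulation of human dosing scenarios with and without
propolis.

A scenario is a DLX regimen (40 or 60 mg, single dose / once daily / twice
daily) combined with a PPL daily dose (0, 5000 or 15,000 mg/day).  PPL is a
static covariate: its daily dose is converted to the covariate scale of the
inhibition model (mg/kg, dividing by body weight) and held constant — no
PPL kinetics are modelled.  Exposure metrics are model-predicted
concentrations (residual assay error is deliberately excluded), so the
replicate-to-replicate spread reflects inter-individual variability only.
Steady-state metrics come from the analytic superposition limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extrapolation import HUMAN, HumanParams
from .structural import DoseRegimen, InvalidParameterError, concentrations, derived_metrics

__all__ = [
    "Scenario",
    "ScenarioResult",
    "run_scenario",
    "percent_difference",
    "scenario_table",
    "profile_table",
]

_FREQ_TAU = {"single": None, "qd": 24.0, "bid": 12.0}

METRICS = ("cmax", "auc", "cmax_ss", "auc_ss", "half_life")


@dataclass(frozen=True)
class Scenario:
    """One human dosing scenario.

    ``dlx_dose`` is mg per administration; ``ppl_daily_dose`` mg/day;
    ``duration_days`` is checked against the time needed to reach steady
    state (>= 3 half-lives) but the steady-state metrics themselves are
    computed from the superposition limit.
    """

    dlx_dose: float = 40.0
    frequency: str = "qd"
    ppl_daily_dose: float = 0.0
    duration_days: int = 7
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.frequency not in _FREQ_TAU:
            raise InvalidParameterError(
                f"frequency must be one of {sorted(_FREQ_TAU)}"
            )
        if self.dlx_dose <= 0 or self.ppl_daily_dose < 0:
            raise InvalidParameterError("doses must be positive")

    @property
    def tau(self) -> float | None:
        return _FREQ_TAU[self.frequency]


@dataclass
class ScenarioResult:
    """Mean +/- SD exposure metrics over simulation replicates."""

    scenario: Scenario
    mean: dict
    sd: dict

    def percent_vs(self, reference: "ScenarioResult") -> dict:
        return {
            m: percent_difference(self.mean[m], reference.mean[m])
            for m in METRICS
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": list(METRICS),
             "mean": [self.mean[m] for m in METRICS],
             "sd": [self.sd[m] for m in METRICS]}
        )


def _replicate_metrics(h: HumanParams, sc: Scenario, omega: dict,
                       etas: np.ndarray | None, body_weight: float) -> ScenarioResult:
    ppl_cov = sc.ppl_daily_dose / body_weight
    tau = sc.tau
    p = h.structural
    half_life_typ = derived_metrics(p, DoseRegimen(sc.dlx_dose, ppl_dose=ppl_cov))["half_life"]
    if tau is not None and sc.duration_days * 24.0 < 3.0 * half_life_typ:
        warnings.warn(
            f"duration {sc.duration_days} d may not reach steady state "
            f"(t1/2 = {half_life_typ:.3g} h)"
        )
    names = list(omega)
    rows = {m: [] for m in METRICS}
    n = 1 if etas is None else len(etas)
    for r in range(n):
        kw = {}
        if etas is not None:
            for j, nme in enumerate(names):
                kw[nme] = getattr(p, nme) * math.exp(etas[r, j])
        pi = p.replace(**kw) if kw else p
        if tau is None:
            reg = DoseRegimen(sc.dlx_dose, ppl_dose=ppl_cov)
        else:
            reg = DoseRegimen(sc.dlx_dose, interval=tau,
                              n_doses=max(sc.duration_days * int(24 / tau), 2),
                              ppl_dose=ppl_cov)
        m = derived_metrics(pi, reg)
        rows["cmax"].append(m["cmax"])
        rows["auc"].append(m["auc_inf"])
        rows["cmax_ss"].append(m["cmax_ss"])
        rows["auc_ss"].append(m["auc_tau_ss"])
        rows["half_life"].append(m["half_life"])
    mean = {k: float(np.mean(v)) for k, v in rows.items()}
    sd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
          for k, v in rows.items()}
    return ScenarioResult(scenario=sc, mean=mean, sd=sd)


def run_scenario(h: HumanParams, omega: dict | None = None,
                 sigma=None, sc: Scenario = Scenario(), *,
                 body_weight: float = HUMAN.body_weight) -> ScenarioResult:
    """Simulate one scenario: per replicate, draw etas, apply the PPL
    inhibition, and compute exposure metrics analytically.

    ``omega`` defaults to the variability carried on ``h``; ``sigma`` is
    accepted for signature symmetry but residual error does not enter
    exposure metrics.
    """
    omega = omega if omega is not None else dict(h.omega)
    if omega and sc.n_replicates > 1:
        rng = np.random.default_rng(sc.seed)
        sds = np.sqrt(np.maximum([omega[k] for k in omega], 0.0))
        etas = rng.normal(0.0, sds, size=(sc.n_replicates, len(omega)))
    else:
        etas = None
    return _replicate_metrics(h, sc, omega, etas, body_weight)


def percent_difference(with_ppl: float, without_ppl: float) -> float:
    """``100 * (with - without) / without`` on replicate means."""
    if without_ppl == 0:
        raise InvalidParameterError("reference metric must be nonzero")
    return 100.0 * (with_ppl - without_ppl) / without_ppl


def scenario_table(h: HumanParams, omega: dict | None = None, *,
                   doses=(40.0, 60.0), frequencies=("single", "qd", "bid"),
                   ppl_daily=(0.0, 5000.0, 15000.0),
                   n_replicates: int = 1000, seed: int = 0,
                   typical: bool = False,
                   body_weight: float = HUMAN.body_weight) -> pd.DataFrame:
    """Exposure-metric grid over all scenarios, with percent differences.

    One row per (frequency, dose, metric); columns give mean +/- SD at each
    PPL level and the percent difference of each co-administration level
    versus PPL 0.  ``typical=True`` computes deterministic typical-value
    metrics (no replicates).  Replicate eta draws are shared across PPL
    levels within a row block (common random numbers) so percent
    differences are not blurred by simulation noise.
    """
    omega = omega if omega is not None else dict(h.omega)
    rng = np.random.default_rng(seed)
    rows = []
    for freq in frequencies:
        for dose in doses:
            if typical or not omega:
                etas = None
            else:
                sds = np.sqrt(np.maximum([omega[k] for k in omega], 0.0))
                etas = rng.normal(0.0, sds, size=(n_replicates, len(omega)))
            results = []
            for ppl in ppl_daily:
                sc = Scenario(dlx_dose=dose, frequency=freq,
                              ppl_daily_dose=ppl,
                              n_replicates=1 if etas is None else n_replicates,
                              seed=seed)
                results.append(
                    _replicate_metrics(h, sc, omega, etas, body_weight)
                )
            ref = results[0]
            for m in METRICS:
                row = {"frequency": freq, "dlx_dose": dose, "metric": m}
                for ppl, res in zip(ppl_daily, results):
                    tag = f"ppl{ppl:g}"
                    row[f"{tag}_mean"] = res.mean[m]
                    row[f"{tag}_sd"] = res.sd[m]
                    if ppl != ppl_daily[0]:
                        row[f"{tag}_pct_diff"] = percent_difference(
                            res.mean[m], ref.mean[m]
                        )
                rows.append(row)
    return pd.DataFrame(rows)


def profile_table(h: HumanParams, sc: Scenario, times=None,
                  omega: dict | None = None, *,
                  body_weight: float = HUMAN.body_weight) -> pd.DataFrame:
    """Mean +/- SD concentration-time profiles for one scenario.

    Covers the full simulated duration so first-interval and steady-state
    portions can both be plotted.
    """
    omega = omega if omega is not None else dict(h.omega)
    tau = sc.tau
    ppl_cov = sc.ppl_daily_dose / body_weight
    horizon = sc.duration_days * 24.0 if tau is not None else 48.0
    if times is None:
        times = np.linspace(0.0, horizon, 241)
    times = np.asarray(times, dtype=float)
    p = h.structural
    if tau is None:
        reg = DoseRegimen(sc.dlx_dose, ppl_dose=ppl_cov)
    else:
        reg = DoseRegimen(sc.dlx_dose, interval=tau,
                          n_doses=int(round(horizon / tau)), ppl_dose=ppl_cov)
    n = sc.n_replicates if omega else 1
    rng = np.random.default_rng(sc.seed)
    names = list(omega)
    cps, cms = [], []
    for r in range(n):
        kw = {
            nme: getattr(p, nme) * math.exp(rng.normal(0.0, math.sqrt(omega[nme])))
            for nme in names
        } if omega else {}
        pi = p.replace(**kw) if kw else p
        cp, cm = concentrations(pi, reg, times)
        cps.append(cp)
        cms.append(cm)
    cps, cms = np.asarray(cps), np.asarray(cms)
    out = []
    for analyte, arr in (("parent", cps), ("metabolite", cms)):
        out.append(pd.DataFrame({
            "time_h": times,
            "analyte": analyte,
            "mean": arr.mean(axis=0),
            "sd": arr.std(axis=0, ddof=1) if n > 1 else 0.0,
            "scenario": f"{sc.dlx_dose:g}mg-{sc.frequency}-PPL{sc.ppl_daily_dose:g}",
        }))
    return pd.concat(out, ignore_index=True)
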