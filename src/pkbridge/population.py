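"""Nonlinear mixed-effects layer for the parent-metabolite model.

The statistical model is the standard population-PK construction:

* individual parameters are lognormal around the typical values,
  ``P_i = P_tv * exp(eta_i)`` with ``eta_i ~ N(0, omega^2)`` on a declared
  subset of the structural parameters;
* observations carry proportional residual error per analyte,
  ``C_obs = C_pred * (1 + eps)`` with ``eps ~ N(0, sigma_analyte^2)``;
* the marginal likelihood is approximated by the conditional (Laplace)
  method: for each subject the joint density is maximised over ``eta``
  (inner Newton iteration) and corrected by the log-determinant of the
  conditional Hessian, with the residual variance evaluated at the
  conditional estimate (the "interaction" convention).  As ``omega -> 0``
  this reduces exactly to the naive-pooled -2 log-likelihood.

The public surface is statsmodels-like: :class:`PopPKModel` is built from a
:class:`~pkbridge.data.PKDataset` plus a :class:`PopulationModel` parameter
container; ``fit()`` returns a :class:`PopPKResults` carrying estimates,
standard errors, empirical Bayes etas, shrinkage and a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from ._kernel import HAVE_NUMBA, ofv_kernel
from .data import METABOLITE, PARENT, PKDataset, StudyDesign
from .structural import InvalidParameterError, StructuralParams, profile_arrays

__all__ = [
    "PopulationModel",
    "PopPKModel",
    "PopPKResults",
    "simulate_dataset",
    "ofv",
    "fit",
    "covariate_search",
]

_STRUCTURAL_NAMES = ("ka", "fpm", "clp", "clpm", "vp", "clm", "vm")
_LOGIT_NAMES = frozenset({"fpm", "emax_fpm", "emax_clpm", "emax_clp"})
_OMEGA_FLOOR = 1e-12
_PRED_FLOOR = 1e-10


@dataclass(frozen=True)
class PopulationModel:
    """Typical values + random-effect structure of the population model.

    ``omega`` maps structural parameter names to IIV variances (lognormal
    scale, so reported IIV% is ``100*sqrt(omega)``); ``sigma_p``/``sigma_m``
    are the proportional residual SDs of parent and metabolite; ``covariates``
    names the structural targets carrying an active PPL inhibition effect
    (their ``emax_*``/``ic50_*`` live on ``structural``); ``fixed`` lists
    parameter names held fixed during fitting.
    """

    structural: StructuralParams
    omega: dict = field(default_factory=dict)
    sigma_p: float = 0.2
    sigma_m: float = 0.2
    covariates: tuple = ()
    fixed: tuple = ()

    def __post_init__(self):
        for k, v in self.omega.items():
            if k not in _STRUCTURAL_NAMES:
                raise InvalidParameterError(f"omega target {k!r} unknown")
            if v < 0:
                raise InvalidParameterError("omega variances must be >= 0")
        if self.sigma_p < 0 or self.sigma_m < 0:
            raise InvalidParameterError("sigmas must be >= 0")
        for t in self.covariates:
            if t not in ("fpm", "clpm", "clp"):
                raise InvalidParameterError(f"covariate target {t!r} unknown")

    @property
    def eta_names(self) -> tuple:
        return tuple(self.omega)

    def iiv_percent(self) -> dict:
        """IIV reported as approximate CV%, ``100*sqrt(omega^2)``."""
        return {k: 100.0 * math.sqrt(v) for k, v in self.omega.items()}

    def replace(self, **kw) -> "PopulationModel":
        return replace(self, **kw)

    # --- flat parameter access used by the fitter ---------------------
    def get_value(self, name: str) -> float:
        if name.startswith("omega_"):
            return self.omega[name[6:]]
        if name == "sigma_p":
            return self.sigma_p
        if name == "sigma_m":
            return self.sigma_m
        return getattr(self.structural, name)

    def with_values(self, values: dict) -> "PopulationModel":
        struct_kw, omega = {}, dict(self.omega)
        sig = {}
        for name, v in values.items():
            if name.startswith("omega_"):
                omega[name[6:]] = v
            elif name in ("sigma_p", "sigma_m"):
                sig[name] = v
            else:
                struct_kw[name] = v
        return self.replace(
            structural=self.structural.replace(**struct_kw),
            omega=omega,
            **sig,
        )

    def estimated_names(self, extra_fixed=()) -> list:
        """Free parameter names in fitting order."""
        fixed = set(self.fixed) | set(extra_fixed)
        names = [n for n in _STRUCTURAL_NAMES if n not in fixed]
        for t in self.covariates:
            for pref in ("emax", "ic50"):
                nm = f"{pref}_{t}"
                if nm not in fixed:
                    names.append(nm)
        for k in self.omega:
            nm = f"omega_{k}"
            if nm not in fixed:
                names.append(nm)
        for nm in ("sigma_p", "sigma_m"):
            if nm not in fixed:
                names.append(nm)
        return names


def _transform(name: str, x: float) -> float:
    if name in _LOGIT_NAMES or name.startswith("emax"):
        x = min(max(x, 1e-10), 1 - 1e-10)
        return math.log(x / (1.0 - x))
    return math.log(max(x, 1e-300))


def _untransform(name: str, t: float) -> float:
    if name in _LOGIT_NAMES or name.startswith("emax"):
        return 1.0 / (1.0 + math.exp(-min(max(t, -700), 700)))
    return math.exp(min(t, 700))


class _LikelihoodEngine:
    """Vectorised per-subject likelihood with inner eta optimisation."""

    def __init__(self, data: PKDataset, eta_names, metabolite_input="depot"):
        obs = data.observations()
        subj = data.subject_table()
        ids = subj["ID"].tolist()
        if obs["ID"].nunique() != len(ids):
            missing = set(ids) - set(obs["ID"])
            raise InvalidParameterError(
                f"subjects without usable observations: {sorted(map(str, missing))}"
            )
        idx = {s: i for i, s in enumerate(ids)}
        self.ids = ids
        self.S = len(ids)
        self.t = obs["TIME"].to_numpy(float)
        self.y = obs["DV"].to_numpy(float)
        self.metab = (obs["ANALYTE"] == METABOLITE).to_numpy()
        self.si = obs["ID"].map(idx).to_numpy(int)
        self.dose = subj["DOSE_DLX"].to_numpy(float)
        self.ppl = subj["DOSE_PPL"].to_numpy(float)
        self.dose_row = self.dose[self.si]
        self.eta_names = tuple(eta_names)
        self.q = len(self.eta_names)
        self.metabolite_input = metabolite_input
        self._warm = np.zeros((self.S, self.q))
        # subject-sorted copies + offsets for the compiled kernel
        order = np.argsort(self.si, kind="stable")
        self._t_s = np.ascontiguousarray(self.t[order])
        self._y_s = np.ascontiguousarray(self.y[order])
        self._metab_s = np.ascontiguousarray(self.metab[order])
        counts = np.bincount(self.si, minlength=self.S)
        self._offsets = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        self._eta_tgt = np.array(
            [_STRUCTURAL_NAMES.index(n) for n in self.eta_names], dtype=np.int64
        )
        self.use_kernel = HAVE_NUMBA

    # -- individual predictions ----------------------------------------
    def predict(self, p: StructuralParams, eta: np.ndarray | None) -> np.ndarray:
        """Per-observation model concentration for subject etas ``eta`` (S, q)."""
        vals = {n: getattr(p, n) for n in _STRUCTURAL_NAMES}
        if eta is not None and self.q:
            for j, n in enumerate(self.eta_names):
                # clip so stray inner-Newton excursions cannot overflow
                vals[n] = vals[n] * np.exp(np.clip(eta[:, j], -50.0, 50.0))
        # inline inhibition factors (validated parameters, hot path)
        fpm = np.minimum(
            vals["fpm"] * (1.0 - p.emax_fpm * self.ppl / (self.ppl + p.ic50_fpm)),
            0.9999,
        )
        clpm = vals["clpm"] * (1.0 - p.emax_clpm * self.ppl / (self.ppl + p.ic50_clpm))
        clp = vals["clp"] * (1.0 - p.emax_clp * self.ppl / (self.ppl + p.ic50_clp))

        def row(x):
            return x[self.si] if isinstance(x, np.ndarray) else x

        cp, cm = profile_arrays(
            row(vals["ka"]), row(fpm), row(clp), row(clpm), row(vals["vp"]),
            row(vals["clm"]), row(vals["vm"]), p.tlag, self.dose_row, self.t,
            self.metabolite_input,
        )
        return np.maximum(np.where(self.metab, cm, cp), _PRED_FLOOR)

    def _h(self, p, eta, sig2_row, omega_var) -> np.ndarray:
        """Per-subject -2 log joint density (observations + eta prior)."""
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            f = self.predict(p, eta)
            g = sig2_row * f * f
            dev = np.log(2.0 * np.pi * g) + (self.y - f) ** 2 / g
            dev = np.nan_to_num(dev, nan=1e12, posinf=1e12)
            hs = np.bincount(self.si, weights=dev, minlength=self.S)
            if self.q:
                hs = hs + np.sum(
                    np.clip(eta, -50.0, 50.0) ** 2 / omega_var
                    + np.log(2.0 * np.pi * omega_var),
                    axis=1,
                )
        return hs

    def _inner(self, p, sig2_row, omega_var, tol=1e-6, max_iter=50):
        """Vectorised Newton maximisation of the joint density over eta."""
        q, S = self.q, self.S
        d = 1e-4
        eta = self._warm.copy()
        h0 = self._h(p, eta, sig2_row, omega_var)
        hess = np.tile(np.eye(q), (S, 1, 1))
        for _ in range(max_iter):
            grad = np.empty((S, q))
            hp = np.empty((S, q))
            hm = np.empty((S, q))
            for j in range(q):
                e = eta.copy()
                e[:, j] += d
                hp[:, j] = self._h(p, e, sig2_row, omega_var)
                e[:, j] -= 2 * d
                hm[:, j] = self._h(p, e, sig2_row, omega_var)
                grad[:, j] = (hp[:, j] - hm[:, j]) / (2 * d)
                hess[:, j, j] = (hp[:, j] + hm[:, j] - 2 * h0) / d**2
            for i in range(q):
                for j in range(i + 1, q):
                    e = eta.copy()
                    e[:, i] += d
                    e[:, j] += d
                    hpp = self._h(p, e, sig2_row, omega_var)
                    cross = (hpp - hp[:, i] - hp[:, j] + h0) / d**2
                    hess[:, i, j] = hess[:, j, i] = cross
            # ridge so every subject's Hessian is safely positive definite
            eigmin = np.linalg.eigvalsh(hess)[:, 0]
            ridge = np.maximum(0.0, 1e-6 - eigmin)
            hreg = hess + ridge[:, None, None] * np.eye(q)
            delta = -np.linalg.solve(hreg, grad[..., None])[..., 0]
            # trust-region cap: |eta| steps beyond a few SDs are never useful
            mx = np.max(np.abs(delta), axis=1)
            fac = np.where(mx > 4.0, 4.0 / np.maximum(mx, 1e-300), 1.0)
            delta = delta * fac[:, None]
            scale = np.ones(S)
            applied = np.zeros((S, q))
            remaining = np.ones(S, dtype=bool)
            for _halve in range(20):
                trial = eta + (scale * remaining)[:, None] * delta
                ht = self._h(p, trial, sig2_row, omega_var)
                accept = remaining & (ht <= h0 + 1e-12)
                eta = np.where(accept[:, None], trial, eta)
                applied = np.where(accept[:, None], scale[:, None] * delta, applied)
                h0 = np.where(accept, ht, h0)
                remaining &= ~accept
                if not remaining.any():
                    break
                scale = np.where(remaining, scale * 0.5, scale)
            if np.max(np.abs(applied)) < tol:
                break
        self._warm = eta.copy()
        return eta, h0, hess

    def ofv_components(self, pop: PopulationModel):
        """Per-subject -2 log marginal likelihood plus conditional etas."""
        p = pop.structural
        if self.use_kernel:
            theta = np.array([
                p.ka, p.fpm, p.clp, p.clpm, p.vp, p.clm, p.vm, p.tlag,
                p.emax_fpm, p.ic50_fpm, p.emax_clpm, p.ic50_clpm,
                p.emax_clp, p.ic50_clp,
            ])
            omega_var = np.array(
                [max(pop.omega[n], _OMEGA_FLOOR) for n in self.eta_names]
            )
            comp = ofv_kernel(
                theta, pop.sigma_p, pop.sigma_m, omega_var, self._eta_tgt,
                self._t_s, self._y_s, self._metab_s, self._offsets,
                self.dose, self.ppl, self._warm,
                self.metabolite_input == "depot",
            )
            return comp, self._warm.copy()
        sig2_row = np.where(self.metab, pop.sigma_m**2, pop.sigma_p**2)
        if self.q == 0:
            h = self._h(p, None, sig2_row, None)
            return h, np.zeros((self.S, 0))
        omega_var = np.array(
            [max(pop.omega[n], _OMEGA_FLOOR) for n in self.eta_names]
        )
        eta, h, hess = self._inner(p, sig2_row, omega_var)
        sign, logdet = np.linalg.slogdet(hess / 2.0)
        if np.any(sign <= 0):  # fall back to a ridged determinant
            bad = sign <= 0
            hreg = hess[bad] + 1e-6 * np.eye(self.q)
            _, logdet_bad = np.linalg.slogdet(hreg / 2.0)
            logdet = logdet.copy()
            logdet[bad] = logdet_bad
        comp = h - self.q * math.log(2.0 * math.pi) + logdet
        return comp, eta

    def ofv(self, pop: PopulationModel) -> float:
        comp, _ = self.ofv_components(pop)
        return float(np.sum(comp))


class PopPKResults:
    """Estimates, uncertainty and diagnostics from :meth:`PopPKModel.fit`."""

    def __init__(self, model, params, ofv, se, rse, etas, shrinkage,
                 converged, nfev, message):
        self.model = model
        self.params = params
        self.ofv = ofv
        self.se = se
        self.rse = rse
        self.etas = etas
        self.shrinkage = shrinkage
        self.converged = converged
        self.nfev = nfev
        self.message = message

    def summary(self) -> str:
        pop = self.params
        rows = []
        names = pop.estimated_names()
        for n in names:
            est = pop.get_value(n)
            if n.startswith("omega_"):
                disp = f"IIV {n[6:]} (%)"
                est_disp = 100.0 * math.sqrt(est)
            elif n.startswith("sigma"):
                disp = f"prop. error {'DLX' if n.endswith('p') else '4-HD'} (%)"
                est_disp = 100.0 * est
            else:
                disp = n
                est_disp = est
            rse = self.rse.get(n) if self.rse else None
            shr = self.shrinkage.get(n[6:]) if n.startswith("omega_") else None
            rows.append(
                (disp, est_disp,
                 "" if rse is None else f"{rse:.3g}",
                 "" if shr is None else f"{shr:.3g}")
            )
        tab = pd.DataFrame(rows, columns=["parameter", "estimate", "RSE (%)", "shrinkage (%)"])
        head = (
            f"Population PK fit | OFV = {self.ofv:.3f} | "
            f"converged = {self.converged} | n_subjects = {self.model.engine.S}\n"
        )
        return head + tab.to_string(index=False, float_format=lambda v: f"{v:.4g}")

    def __repr__(self):
        return f"<PopPKResults OFV={self.ofv:.2f} converged={self.converged}>"


class PopPKModel:
    """Population PK model bound to a dataset (statsmodels-style).

    Parameters
    ----------
    data : PKDataset
        Observations (BLQ and pre-dose rows are dropped from the likelihood).
    init : PopulationModel
        Starting values and random-effect / covariate structure.
    metabolite_input : {"depot", "bolus"}
        How first-pass-formed metabolite enters the system.
    """

    def __init__(self, data: PKDataset, init: PopulationModel, *,
                 metabolite_input: str = "depot"):
        self.data = data
        self.init = init
        self.metabolite_input = metabolite_input
        self.engine = _LikelihoodEngine(data, init.eta_names, metabolite_input)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, init: PopulationModel, **kw):
        return cls(PKDataset(df), init, **kw)

    @classmethod
    def from_csv(cls, path, init: PopulationModel, **kw):
        return cls(PKDataset.read_csv(path), init, **kw)

    # ------------------------------------------------------------------
    def ofv(self, pop: PopulationModel | None = None) -> float:
        """-2 x approximate (conditional/Laplace) marginal log-likelihood."""
        pop = pop if pop is not None else self.init
        out = self.engine.ofv(pop)
        if not np.isfinite(out):
            raise InvalidParameterError("non-finite likelihood at these parameters")
        return out

    def _objective_factory(self, names, init=None):
        engine, init = self.engine, init if init is not None else self.init

        def objective(x):
            values = {n: _untransform(n, t) for n, t in zip(names, x)}
            try:
                pop = init.with_values(values)
                return engine.ofv(pop)
            except (InvalidParameterError, FloatingPointError):
                return 1e12

        return objective

    def fit(self, *, n_starts: int = 1, seed: int = 0, compute_se: bool = True,
            maxfev: int | None = None, xatol: float = 1e-4,
            fatol: float = 1e-3, presolve: bool = False) -> PopPKResults:
        """Maximise the approximate marginal likelihood.

        Structural parameters are optimised on the log scale, fractions
        (``fpm``, ``emax_*``) on the logit scale, variances and sigmas on
        the log scale (Nelder-Mead, optionally multi-start with jittered
        initial vectors).  ``presolve`` first fits the naive-pooled model
        (no random effects) to move the structural and residual parameters
        near the optimum cheaply, then refines with the full conditional
        likelihood.
        """
        init = self.init
        if presolve and init.omega:
            pooled = init.replace(omega={})
            pre = PopPKModel(self.data, pooled,
                             metabolite_input=self.metabolite_input).fit(
                compute_se=False, presolve=False, fatol=0.1,
                maxfev=150 * len(pooled.estimated_names()),
            )
            init = init.with_values(
                {n: pre.params.get_value(n) for n in pooled.estimated_names()}
            )
        names = init.estimated_names()
        if not names:
            raise InvalidParameterError("no free parameters to estimate")
        x0 = np.array([_transform(n, init.get_value(n)) for n in names])
        objective = self._objective_factory(names, init)
        rng = np.random.default_rng(seed)
        best = None
        for s in range(n_starts):
            xs = x0 if s == 0 else x0 + rng.normal(0.0, 0.2, len(x0))
            res = minimize(
                objective, xs, method="Nelder-Mead",
                options=dict(
                    maxfev=maxfev or 400 * len(x0),
                    xatol=xatol, fatol=fatol, adaptive=len(x0) > 6,
                ),
            )
            if best is None or res.fun < best.fun:
                best = res
        values = {n: _untransform(n, t) for n, t in zip(names, best.x)}
        pop_hat = init.with_values(values)
        comp, eta = self.engine.ofv_components(pop_hat)
        ofv_hat = float(np.sum(comp))

        etas = pd.DataFrame(
            eta, columns=[f"eta_{n}" for n in self.engine.eta_names]
        )
        etas.insert(0, "ID", self.engine.ids)
        shrinkage = {}
        for j, n in enumerate(self.engine.eta_names):
            w = math.sqrt(max(pop_hat.omega[n], _OMEGA_FLOOR))
            sd = float(np.std(eta[:, j], ddof=1)) if self.engine.S > 1 else 0.0
            shrinkage[n] = 100.0 * (1.0 - sd / w)

        se = rse = None
        message = best.message
        if compute_se:
            se, rse, hess_ok = self._standard_errors(objective, names, best.x, values)
            if not hess_ok:
                message = f"{message}; Hessian not positive definite, RSE omitted"
        return PopPKResults(
            model=self, params=pop_hat, ofv=ofv_hat, se=se, rse=rse,
            etas=etas, shrinkage=shrinkage,
            converged=bool(best.success), nfev=int(best.nfev), message=message,
        )

    def _standard_errors(self, objective, names, xhat, values, step=5e-3):
        n = len(names)

        def f(x):
            # reset the inner warm start so the objective is path-independent
            self.engine._warm[:] = 0.0
            return objective(x)

        f0 = f(xhat)
        hess = np.empty((n, n))
        for i in range(n):
            xi = xhat.copy()
            xi[i] += step
            fp = f(xi)
            xi[i] -= 2 * step
            fm = f(xi)
            hess[i, i] = (fp + fm - 2 * f0) / step**2
        for i in range(n):
            for j in range(i + 1, n):
                x = xhat.copy()
                vals = []
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    x = xhat.copy()
                    x[i] += si * step
                    x[j] += sj * step
                    vals.append(f(x))
                hess[i, j] = hess[j, i] = (
                    vals[0] - vals[1] - vals[2] + vals[3]
                ) / (4 * step**2)
        eig = np.linalg.eigvalsh(hess)
        if eig[0] <= 0:
            warnings.warn("OFV Hessian not positive definite; RSE omitted")
            return None, None, False
        cov = 2.0 * np.linalg.inv(hess)  # OFV = -2 LL
        se_t = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se, rse = {}, {}
        for i, nme in enumerate(names):
            x = values[nme]
            if nme in _LOGIT_NAMES or nme.startswith("emax"):
                s = x * (1.0 - x) * se_t[i]
            else:
                s = x * se_t[i]
            se[nme] = s
            rse[nme] = 100.0 * s / x if x != 0 else math.inf
        return se, rse, True


# ----------------------------------------------------------------------
# module-level operations


def simulate_dataset(pop: PopulationModel, design: StudyDesign, seed: int = 0,
                     *, metabolite_input: str = "depot") -> PKDataset:
    """Draw one replicate study from the generative population model.

    Per subject: ``eta ~ N(0, omega^2)`` on the declared parameters, the
    individual profile is evaluated at the design times, and each
    observation is perturbed by proportional error.  Deterministic for a
    fixed seed.  No quantification-range flags are applied here (see
    :func:`pkbridge.synthetic.generate_study`).
    """
    rng = np.random.default_rng(seed)
    p = pop.structural
    eta_names = pop.eta_names
    times = design.post_dose_times
    rows = []
    for label, ppl, n in design.groups:
        for k in range(n):
            sid = f"{label}-{k + 1}"
            kw = {}
            for nme in eta_names:
                e = rng.normal(0.0, math.sqrt(max(pop.omega[nme], 0.0)))
                kw[nme] = getattr(p, nme) * math.exp(e)
            pi = p.replace(**kw) if kw else p
            from .structural import DoseRegimen, concentrations

            cp, cm = concentrations(
                pi, DoseRegimen(design.dlx_dose, ppl_dose=ppl), times,
                metabolite_input=metabolite_input,
            )
            # proportional error; the rare draw below -1 would imply a
            # negative concentration and is clipped to zero (sub-LLOQ anyway)
            eps_p = np.maximum(rng.normal(0.0, pop.sigma_p, len(times)), -1.0)
            eps_m = np.maximum(rng.normal(0.0, pop.sigma_m, len(times)), -1.0)
            rows.append((sid, label, 0.0, np.nan, design.dlx_dose, np.nan,
                         design.dlx_dose, ppl, 0))
            for t, c, e in zip(times, cp, eps_p):
                rows.append((sid, label, t, c * (1 + e), np.nan, PARENT,
                             design.dlx_dose, ppl, 0))
            for t, c, e in zip(times, cm, eps_m):
                rows.append((sid, label, t, c * (1 + e), np.nan, METABOLITE,
                             design.dlx_dose, ppl, 0))
    df = pd.DataFrame(
        rows,
        columns=["ID", "GROUP", "TIME", "DV", "AMT", "ANALYTE",
                 "DOSE_DLX", "DOSE_PPL", "BLQ"],
    )
    return PKDataset(df)


def ofv(pop: PopulationModel, data: PKDataset, **kw) -> float:
    """Objective function value of ``pop`` on ``data`` (-2 log-likelihood)."""
    return PopPKModel(data, pop, **kw).ofv()


def fit(init: PopulationModel, data: PKDataset, **fit_kw) -> PopPKResults:
    """Fit ``init`` to ``data``; convenience wrapper over PopPKModel.fit."""
    return PopPKModel(data, init).fit(**fit_kw)


def _with_candidate(pop: PopulationModel, target: str,
                    init_emax: float, init_ic50: float) -> PopulationModel:
    struct = pop.structural.replace(
        **{f"emax_{target}": init_emax, f"ic50_{target}": init_ic50}
    )
    return pop.replace(structural=struct,
                       covariates=tuple(pop.covariates) + (target,))


def _without_target(pop: PopulationModel, target: str) -> PopulationModel:
    struct = pop.structural.replace(
        **{f"emax_{target}": 0.0, f"ic50_{target}": 1.0}
    )
    return pop.replace(
        structural=struct,
        covariates=tuple(t for t in pop.covariates if t != target),
    )


def covariate_search(base: PopulationModel, data: PKDataset,
                     candidates=("fpm", "clpm"), *,
                     forward_alpha: float = 0.05,
                     backward_alpha: float = 0.01,
                     init_emax: float = 0.3,
                     init_ic50: float | None = None,
                     fit_kwargs: dict | None = None):
    """Stepwise forward-addition / backward-elimination covariate search.

    Each candidate is a saturable PPL effect on one structural target,
    adding ``emax``+``ic50`` (2 df unless one is in ``fixed``).  Forward
    steps add the candidate with the largest OFV drop while the drop beats
    the chi-square critical value at ``forward_alpha``; backward steps then
    delete any retained effect whose removal costs less than the critical
    value at ``backward_alpha``.  Returns ``(final PopPKResults, step table)``.
    """
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("compute_se", False)
    # every fit in the search starts from the current estimates; a pooled
    # presolve would discard that information (and, on high-IIV models,
    # steer the fit into an inflated-sigma local optimum), so it is forced
    # off here
    fit_kwargs["presolve"] = False
    if init_ic50 is None:
        ppl = data.subject_table()["DOSE_PPL"]
        pos = ppl[ppl > 0]
        init_ic50 = float(pos.median()) if len(pos) else 300.0

    steps = []
    current = PopPKModel(data, base).fit(**fit_kwargs)
    current_pop = current.params
    steps.append(("base", "base model", None, None, None, None, "start"))

    remaining = list(candidates)
    model_no = 1
    while remaining:
        trials = []
        for t in remaining:
            cand_pop = _with_candidate(current_pop, t, init_emax, init_ic50)
            df_added = len(cand_pop.estimated_names()) - len(current_pop.estimated_names())
            res = PopPKModel(data, cand_pop).fit(**fit_kwargs)
            trials.append((t, res, df_added))
        t, res, df_added = min(trials, key=lambda tr: tr[1].ofv)
        delta = res.ofv - current.ofv
        crit = chi2.ppf(1.0 - forward_alpha, df_added)
        pval = float(chi2.sf(max(-delta, 0.0), df_added))
        accept = -delta > crit
        model_no += 1
        steps.append((f"forward-{model_no}", f"+ PPL on {t}", df_added,
                      delta, "current", pval, "add" if accept else "reject"))
        if not accept:
            break
        current, current_pop = res, res.params
        remaining.remove(t)

    removed = True
    while removed and current_pop.covariates:
        removed = False
        trials = []
        for t in current_pop.covariates:
            red_pop = _without_target(current_pop, t)
            df_rem = len(current_pop.estimated_names()) - len(red_pop.estimated_names())
            res = PopPKModel(data, red_pop).fit(**fit_kwargs)
            trials.append((t, res, df_rem))
        t, res, df_rem = min(trials, key=lambda tr: tr[1].ofv)
        rise = res.ofv - current.ofv
        crit = chi2.ppf(1.0 - backward_alpha, df_rem)
        pval = float(chi2.sf(max(rise, 0.0), df_rem))
        drop = rise < crit
        steps.append((f"backward", f"- PPL on {t}", df_rem, rise,
                      "current", pval, "remove" if drop else "keep"))
        if drop:
            current, current_pop = res, res.params
            removed = True

    table = pd.DataFrame(
        steps,
        columns=["step", "description", "df", "delta_ofv",
                 "compared_with", "p_value", "decision"],
    )
    return current, table
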