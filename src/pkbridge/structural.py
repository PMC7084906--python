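"""Deterministic kinetics of the oral parent-metabolite system.

The disposition model is a linear cascade: a single oral depot feeds a
one-compartment parent (duloxetine, DLX) and, through two metabolic routes,
a one-compartment metabolite (4-hydroxy duloxetine, 4-HD):

* a fraction ``fpm`` of each dose is converted pre-systemically (first pass)
  and enters the metabolite path directly;
* the surviving fraction ``1 - fpm`` is absorbed at first-order rate ``ka``
  into the parent compartment, which is cleared by ``clp`` (all routes other
  than conversion) and ``clpm`` (systemic conversion to metabolite);
* the metabolite is cleared by ``clm``.

All clearances and volumes are apparent (CL/F, V/F): the oral design cannot
separate bioavailability from disposition, so the unobserved F's are folded
into the parameter scales.  Co-administered propolis (PPL) inhibits the two
conversion routes through saturable (Michaelis-Menten / Emax) dose factors
acting on ``fpm`` and ``clpm``.

Everything here is closed form.  Concentration units are ng/mL throughout;
amounts are mg (or mg/kg in the rat per-kg convention) and volumes L (or
L/kg), so the single mg -> ng/mL conversion factor is 1e3 (1 mg/L = 1000
ng/mL), applied in :func:`profile_arrays` only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StructuralParams",
    "DoseRegimen",
    "InvalidParameterError",
    "inhibition_factor",
    "effective_params",
    "systemic_fraction",
    "concentrations",
    "derived_metrics",
    "profile_arrays",
]

#: mg/L -> ng/mL
MG_L_TO_NG_ML = 1000.0

#: relative closeness at which repeated-eigenvalue limit forms take over
_EIG_TOL = 1e-9


class InvalidParameterError(ValueError):
    """A kinetic parameter is outside its physical domain."""


@dataclass(frozen=True)
class StructuralParams:
    """Typical-value parameters of the parent-metabolite system.

    Rates are 1/h, clearances volume/time, volumes volume; the per-kg vs
    total-body convention is the caller's (rat: per kg with mg/kg doses;
    human: total with mg doses).  ``emax_*``/``ic50_*`` are the PPL
    inhibition constants (ic50 in the same units as the PPL dose, mg/kg).
    """

    ka: float
    fpm: float
    clp: float
    clpm: float
    vp: float
    clm: float
    vm: float
    tlag: float = 0.0
    emax_fpm: float = 0.0
    ic50_fpm: float = 1.0
    emax_clpm: float = 0.0
    ic50_clpm: float = 1.0
    emax_clp: float = 0.0
    ic50_clp: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ka", "clp", "clpm", "vp", "clm", "vm"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not 0.0 <= self.fpm <= 1.0:
            raise InvalidParameterError("fpm must be in [0, 1]")
        if self.tlag < 0:
            raise InvalidParameterError("tlag must be >= 0")
        for tag in ("fpm", "clpm", "clp"):
            emax = getattr(self, f"emax_{tag}")
            ic50 = getattr(self, f"ic50_{tag}")
            if not 0.0 <= emax <= 1.0:
                raise InvalidParameterError(f"emax_{tag} must be in [0, 1]")
            if not ic50 > 0:
                raise InvalidParameterError(f"ic50_{tag} must be > 0")

    # elimination rate constants -------------------------------------
    @property
    def ke_parent(self) -> float:
        """Total parent elimination rate constant (clp + clpm) / vp."""
        return (self.clp + self.clpm) / self.vp

    @property
    def kpm(self) -> float:
        """Systemic conversion rate constant clpm / vp."""
        return self.clpm / self.vp

    @property
    def ke_metab(self) -> float:
        return self.clm / self.vm

    def replace(self, **kw) -> "StructuralParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class DoseRegimen:
    """An oral dosing schedule plus the static PPL covariate dose.

    ``dose`` is per administration (mg/kg in rats, mg total in humans);
    ``ppl_dose`` is on the covariate scale of the inhibition model (mg/kg).
    """

    dose: float
    interval: float | None = None
    n_doses: int = 1
    ppl_dose: float = 0.0

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise InvalidParameterError("dose must be > 0")
        if self.n_doses < 1:
            raise InvalidParameterError("n_doses must be >= 1")
        if self.n_doses > 1 and not (self.interval and self.interval > 0):
            raise InvalidParameterError("interval must be > 0 for multiple doses")
        if self.ppl_dose < 0:
            raise InvalidParameterError("ppl_dose must be >= 0")


def inhibition_factor(emax: float, ic50: float, ppl_dose: float):
    """Saturable inhibition multiplier ``1 - emax * D / (D + ic50)``.

    Equals 1 at D = 0, ``1 - emax/2`` at D = ic50 and tends to ``1 - emax``
    as D grows; strictly decreasing in D whenever emax > 0.
    """
    emax = np.asarray(emax, dtype=float) if np.ndim(emax) else float(emax)
    if np.any(np.asarray(emax) < 0) or np.any(np.asarray(emax) > 1):
        raise InvalidParameterError("emax must be in [0, 1]")
    if np.any(np.asarray(ic50) <= 0):
        raise InvalidParameterError("ic50 must be > 0")
    if np.any(np.asarray(ppl_dose) < 0):
        raise InvalidParameterError("ppl_dose must be >= 0")
    return 1.0 - emax * ppl_dose / (ppl_dose + ic50)


def effective_params(p: StructuralParams, ppl_dose: float) -> StructuralParams:
    """Apply the PPL inhibition factors to ``fpm``, ``clpm`` (and ``clp``).

    Returns a copy with each targeted parameter multiplied by its own
    inhibition factor; with the default ``emax_* = 0`` a target is left
    untouched, so models without a given covariate need no special casing.
    """
    return p.replace(
        fpm=p.fpm * inhibition_factor(p.emax_fpm, p.ic50_fpm, ppl_dose),
        clpm=p.clpm * inhibition_factor(p.emax_clpm, p.ic50_clpm, ppl_dose),
        clp=p.clp * inhibition_factor(p.emax_clp, p.ic50_clp, ppl_dose),
    )


def systemic_fraction(fpm: float) -> float:
    """Dose fraction surviving first pass, ``1 - fpm`` (apparent scale)."""
    if not 0.0 <= fpm <= 1.0:
        raise InvalidParameterError("fpm must be in [0, 1]")
    return 1.0 - fpm


# ----------------------------------------------------------------------
# closed-form exponential kernels
#
# The cascade is linear, so every amount is an inverse Laplace transform of
# 1 / prod_i (s + k_i) terms.  _b2 and _b3 are those transforms for two and
# three (possibly coincident) rate constants; repeated eigenvalues use the
# analytic limit forms so the profile is never NaN.

def _b2(a, b, t):
    """Inverse Laplace of 1/((s+a)(s+b)) = (exp(-a t) - exp(-b t))/(b - a)."""
    a, b, t = np.asarray(a), np.asarray(b), np.asarray(t)
    scale = np.maximum(np.abs(a), np.abs(b))
    close = np.abs(a - b) <= _EIG_TOL * scale
    if not close.any():
        return (np.exp(-a * t) - np.exp(-b * t)) / (b - a)
    den = np.where(close, 1.0, b - a)
    return np.where(
        close,
        t * np.exp(-a * t),
        (np.exp(-a * t) - np.exp(-b * t)) / den,
    )


def _b3(a, b, c, t):
    """Inverse Laplace of 1/((s+a)(s+b)(s+c)), any eigenvalue multiplicity."""
    a, b, c, t = np.asarray(a), np.asarray(b), np.asarray(c), np.asarray(t)
    scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), np.abs(c))
    ab = np.abs(a - b) <= _EIG_TOL * scale
    ac = np.abs(a - c) <= _EIG_TOL * scale
    bc = np.abs(b - c) <= _EIG_TOL * scale
    ea, eb, ec = np.exp(-a * t), np.exp(-b * t), np.exp(-c * t)
    if not (ab.any() or ac.any() or bc.any()):
        return (
            ea / ((b - a) * (c - a))
            + eb / ((a - b) * (c - b))
            + ec / ((a - c) * (b - c))
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        generic = np.where(
            ab | ac | bc,
            0.0,
            ea / np.where(ab | ac, 1.0, (b - a) * (c - a))
            + eb / np.where(ab | bc, 1.0, (a - b) * (c - b))
            + ec / np.where(ac | bc, 1.0, (a - c) * (b - c)),
        )

        def _pair(k, m):
            """repeated-eigenvalue limit: 1/((s+k)^2 (s+m))"""
            d = np.where(np.abs(m - k) <= _EIG_TOL * scale, 1.0, m - k)
            return (t * np.exp(-k * t) * d - np.exp(-k * t) + np.exp(-m * t)) / d**2

        triple = 0.5 * t**2 * ea

        out = np.where(ab, _pair(a, c), generic)
        out = np.where(ac & ~ab, _pair(a, b), out)
        out = np.where(bc & ~ab & ~ac, _pair(b, a), out)
        out = np.where(ab & ac, triple, out)
    return out


def profile_arrays(
    ka,
    fpm,
    clp,
    clpm,
    vp,
    clm,
    vm,
    tlag,
    dose,
    times,
    metabolite_input: str = "depot",
):
    """Single-dose concentration profiles, broadcasting over parameters.

    All parameter arguments broadcast against each other and against
    ``times`` (hours since this dose).  ``fpm``/``clpm`` must already be the
    effective (PPL-adjusted) values.  Returns ``(parent, metabolite)`` in
    ng/mL; both are 0 for times <= tlag.

    ``metabolite_input`` selects how the first-pass-formed metabolite enters:
    ``"depot"`` (absorbed at ka alongside parent, the default) or ``"bolus"``
    (instantaneously at t = tlag).
    """
    (ka, fpm, clp, clpm, vp, clm, vm, tlag, dose, times) = map(
        np.asarray, (ka, fpm, clp, clpm, vp, clm, vm, tlag, dose, times)
    )
    t = times - tlag
    active = t > 0
    t = np.where(active, t, 0.0)

    kel = (clp + clpm) / vp  # total parent elimination
    kpm = clpm / vp  # conversion flux rate constant
    kem = clm / vm

    dose_p = dose * (1.0 - fpm)
    dose_m = dose * fpm

    a_parent = dose_p * ka * _b2(kel, ka, t)
    conv = dose_p * ka * kpm * _b3(ka, kel, kem, t)
    if metabolite_input == "depot":
        first_pass = dose_m * ka * _b2(kem, ka, t)
    elif metabolite_input == "bolus":
        first_pass = dose_m * np.exp(-kem * t)
    else:  # pragma: no cover - guarded API
        raise ValueError(f"unknown metabolite_input {metabolite_input!r}")
    a_metab = first_pass + conv

    cp = np.where(active, a_parent / vp * MG_L_TO_NG_ML, 0.0)
    cm = np.where(active, a_metab / vm * MG_L_TO_NG_ML, 0.0)
    return cp, cm


def _superpose(p: StructuralParams, regimen_dose, interval, n_doses, times,
               metabolite_input="depot"):
    """Sum single-dose profiles over the dosing history (linear kinetics)."""
    times = np.asarray(times, dtype=float)
    cp = np.zeros_like(times)
    cm = np.zeros_like(times)
    for d in range(n_doses):
        shift = 0.0 if d == 0 else d * interval
        cpd, cmd = profile_arrays(
            p.ka, p.fpm, p.clp, p.clpm, p.vp, p.clm, p.vm, p.tlag,
            regimen_dose, times - shift, metabolite_input,
        )
        cp += cpd
        cm += cmd
    return cp, cm


def n_doses_to_steady_state(p: StructuralParams, interval: float,
                            rel_tol: float = 1e-10) -> int:
    """Doses needed before the oldest dose contributes < rel_tol."""
    k_min = min(p.ka, p.ke_parent, p.ke_metab)
    n = int(math.ceil(-math.log(rel_tol) / (k_min * interval))) + 2
    return min(max(n, 3), 5000)


def concentrations(
    p: StructuralParams,
    r: DoseRegimen,
    times,
    *,
    apply_covariate: bool = True,
    metabolite_input: str = "depot",
):
    """Parent and metabolite concentrations (ng/mL) at ``times`` (h).

    ``times`` are hours since the first dose.  With ``apply_covariate`` the
    PPL inhibition factors are applied from ``r.ppl_dose`` first.  Multiple
    doses are handled by superposition.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise InvalidParameterError("times must be >= 0")
    pe = effective_params(p, r.ppl_dose) if apply_covariate else p
    return _superpose(pe, r.dose, r.interval, r.n_doses, times, metabolite_input)


def _argmax_refine(fun, lo, hi, n_grid=256, xtol=1e-6):
    """Locate the maximum of a smooth profile: coarse grid + golden refine."""
    from scipy.optimize import minimize_scalar

    grid = np.linspace(lo, hi, n_grid)
    vals = fun(grid)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    if b <= a:
        return grid[i], float(vals[i])
    res = minimize_scalar(lambda t: -fun(np.asarray([t]))[0],
                          bounds=(a, b), method="bounded",
                          options={"xatol": xtol})
    return float(res.x), float(-res.fun)


def derived_metrics(p: StructuralParams, r: DoseRegimen,
                    *, metabolite_input: str = "depot") -> dict:
    """Summary pharmacokinetic metrics of the parent (DLX) profile.

    Returns ``ke`` (1/h), ``half_life`` (h), single-dose ``cmax``/``tmax``
    (ng/mL, h since first dose), ``auc_inf`` = steady-state ``auc_tau_ss``
    (h*ng/mL, interval-independent under linear kinetics), and, when the
    regimen has an interval, steady-state ``cmax_ss``/``tmax_ss`` (tmax_ss in
    hours within the dosing interval).
    """
    pe = effective_params(p, r.ppl_dose)
    ke = pe.ke_parent
    half_life = math.log(2.0) / ke
    auc = (1.0 - pe.fpm) * r.dose / (pe.clp + pe.clpm) * MG_L_TO_NG_ML

    def single(t):
        cp, _ = _superpose(pe, r.dose, None, 1, t, metabolite_input)
        return cp

    hi = pe.tlag + 5.0 * max(half_life, math.log(2.0) / pe.ka)
    tmax, cmax = _argmax_refine(single, pe.tlag, hi)

    out = {
        "ke": ke,
        "half_life": half_life,
        "cmax": cmax,
        "tmax": tmax,
        "auc_inf": auc,
        "auc_tau_ss": auc,
    }

    if r.interval:
        tau = r.interval
        n_ss = n_doses_to_steady_state(pe, tau)

        def ss(u):
            # u is time within one steady-state interval
            t = (n_ss - 1) * tau + np.asarray(u)
            cp, _ = _superpose(pe, r.dose, tau, n_ss, t, metabolite_input)
            return cp

        tmax_ss, cmax_ss = _argmax_refine(ss, 0.0, tau)
        out["cmax_ss"] = cmax_ss
        out["tmax_ss"] = tmax_ss
    else:
        out["cmax_ss"] = cmax
        out["tmax_ss"] = tmax
    return out
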