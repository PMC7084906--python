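"""Rat-to-human translation of the parent-metabolite parameters.

Volumes scale allometrically with body weight using a fixed exponent of
1.0 (``V_human = V_rat_per_kg * BW_human``); clearances scale by the
liver-blood-flow (LBF) ratio, appropriate for a drug cleared almost
entirely by hepatic CYP metabolism (``CL_human = CL_rat_per_kg *
LBF_human/LBF_rat * BW_human``).  The absorption rate constant is solved
from the one-compartment relation between Tmax, Ka and Ke on the
absorption-faster-than-elimination branch, after subtracting the 2-h
enteric-coating lag.  First-pass and inhibition fractions (fpm, emax,
ic50) are dimensionless and carried across species unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.optimize import brentq

from .structural import InvalidParameterError, StructuralParams

__all__ = [
    "SpeciesContext",
    "HumanParams",
    "RAT",
    "HUMAN",
    "scale_volume",
    "scale_clearance",
    "solve_ka",
    "extrapolate",
    "two_fold_check",
]


@dataclass(frozen=True)
class SpeciesContext:
    """Body weight (kg) and liver blood flow (mL/min per kg)."""

    body_weight: float
    lbf: float

    def __post_init__(self):
        if not (self.body_weight > 0 and self.lbf > 0):
            raise InvalidParameterError("body_weight and lbf must be > 0")


#: reference species contexts (rat weight only matters if parameters are
#: totals rather than per-kg; the default rat scale is per-kg)
RAT = SpeciesContext(body_weight=0.25, lbf=85.0)
HUMAN = SpeciesContext(body_weight=70.0, lbf=21.0)


def scale_volume(v_rat: float, ctx: SpeciesContext = HUMAN) -> float:
    """Allometric volume scaling, exponent fixed at 1.0.

    ``v_rat`` is the per-kg rat volume (L/kg); the result is the total
    human volume (L).
    """
    if not v_rat > 0:
        raise InvalidParameterError("volume must be > 0")
    return v_rat * ctx.body_weight


def scale_clearance(cl_rat: float, ctx_rat: SpeciesContext = RAT,
                    ctx_human: SpeciesContext = HUMAN) -> float:
    """Liver-blood-flow clearance scaling, per-kg rat -> total human L/h."""
    if not cl_rat > 0:
        raise InvalidParameterError("clearance must be > 0")
    return cl_rat * (ctx_human.lbf / ctx_rat.lbf) * ctx_human.body_weight


def solve_ka(tmax_post_dose: float, tlag: float, ke: float) -> float:
    """Absorption rate from ``Tmax = (ln Ka - ln Ke) / (Ka - Ke)``.

    ``tmax_post_dose`` is the observed time of the maximum since dosing;
    the lag is subtracted first.  The relation has two roots; the branch
    with ``ka > ke`` (absorption faster than elimination) is returned.
    As the effective Tmax approaches its supremum ``1/ke`` the root
    collapses onto ``ke``; beyond it no ka > ke exists.
    """
    if ke <= 0:
        raise InvalidParameterError("ke must be > 0")
    tmax = tmax_post_dose - tlag
    if tmax <= 0:
        raise InvalidParameterError("tmax_post_dose must exceed tlag")
    if tmax >= 1.0 / ke:
        raise InvalidParameterError(
            f"effective tmax {tmax:g} h >= 1/ke = {1.0 / ke:g} h: no root "
            "with ka > ke exists"
        )

    def f(ka):
        return (math.log(ka) - math.log(ke)) / (ka - ke) - tmax

    lo = ke * (1.0 + 1e-6)
    hi = 1e3
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


@dataclass(frozen=True)
class HumanParams:
    """Human-scale structural parameters plus derived composites.

    ``structural`` is on the total-body apparent scale (L, L/h, doses mg).
    ``cl_total_over_fp`` is the total parent clearance CL/Fp; dividing by
    the systemic fraction ``1 - fpm`` gives the fully apparent
    ``cl_dlx_over_fdlx`` (CL/FDLX) and ``v_dlx_over_fdlx`` (V/FDLX) that
    published human estimates are reported on.  ``omega``/``sigma_p``/
    ``sigma_m`` carry the rat variability across (assumed species-invariant)
    for simulation.
    """

    structural: StructuralParams
    ke: float
    half_life: float
    cl_total_over_fp: float
    cl_dlx_over_fdlx: float
    v_dlx_over_fdlx: float
    tmax_post_dose: float
    omega: dict = field(default_factory=dict)
    sigma_p: float | None = None
    sigma_m: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Human parameter table (predicted-value column, units in rows)."""
        p = self.structural
        rows = [
            ("Ka", "1/h", p.ka),
            ("CLp/Fp", "L/h", p.clp),
            ("CLpm/Fp", "L/h", p.clpm),
            ("Vp/Fp", "L", p.vp),
            ("Kep", "1/h", self.ke),
            ("CLm/Fm", "L/h", p.clm),
            ("Vm/Fm", "L", p.vm),
            ("CLDLX/FDLX", "L/h", self.cl_dlx_over_fdlx),
            ("VDLX/FDLX", "L", self.v_dlx_over_fdlx),
            ("t1/2", "h", self.half_life),
        ]
        return pd.DataFrame(rows, columns=["parameter", "unit", "predicted"])


def _structural_of(rat) -> tuple[StructuralParams, dict, float | None, float | None]:
    """Accept PopPKResults, PopulationModel or StructuralParams."""
    if isinstance(rat, StructuralParams):
        return rat, {}, None, None
    if hasattr(rat, "params"):  # PopPKResults
        rat = rat.params
    return rat.structural, dict(rat.omega), rat.sigma_p, rat.sigma_m


def extrapolate(rat, ctx_rat: SpeciesContext = RAT,
                ctx_human: SpeciesContext = HUMAN,
                tmax_post_dose: float = 6.0,
                tlag: float = 2.0) -> HumanParams:
    """Translate rat estimates (per-kg apparent scale) to a human adult.

    Volumes scale allometrically, clearances by LBF ratio; ``fpm`` and the
    PPL inhibition constants are carried over unchanged (the interaction is
    assumed species-invariant); ``ke`` follows from the scaled clearances
    and volume, and ``ka`` from the literature Tmax after removing the
    enteric-coating lag.
    """
    p, omega, sp, sm = _structural_of(rat)
    clp = scale_clearance(p.clp, ctx_rat, ctx_human)
    clpm = scale_clearance(p.clpm, ctx_rat, ctx_human)
    clm = scale_clearance(p.clm, ctx_rat, ctx_human)
    vp = scale_volume(p.vp, ctx_human)
    vm = scale_volume(p.vm, ctx_human)
    ke = (clp + clpm) / vp
    ka = solve_ka(tmax_post_dose, tlag, ke)
    structural = p.replace(
        ka=ka, clp=clp, clpm=clpm, clm=clm, vp=vp, vm=vm, tlag=tlag
    )
    fsys = 1.0 - p.fpm
    return HumanParams(
        structural=structural,
        ke=ke,
        half_life=math.log(2.0) / ke,
        cl_total_over_fp=clp + clpm,
        cl_dlx_over_fdlx=(clp + clpm) / fsys,
        v_dlx_over_fdlx=vp / fsys,
        tmax_post_dose=tmax_post_dose,
        omega=omega,
        sigma_p=sp,
        sigma_m=sm,
    )


def two_fold_check(predicted: float, observed: float) -> bool:
    """Is the prediction within two-fold of the observed value?"""
    if not (predicted > 0 and observed > 0):
        raise InvalidParameterError("two_fold_check requires positive values")
    ratio = predicted / observed
    return 0.5 <= ratio <= 2.0
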