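"""Reference parameter sets for the rat duloxetine-propolis study.

``rat_final_model`` is the covariate model of record (PPL inhibition on the
first-pass fraction and on the systemic conversion clearance, IIV on CLp
only) with the published rat estimates; it doubles as the default truth of
the synthetic-data generator.  ``rat_base_model`` is the pre-covariate
model: no PPL effects and IIV on both CLp (18.4%) and CLpm (149%), as used
when exercising the covariate search.

Rat parameters are on the per-kg apparent scale (doses mg/kg, volumes L/kg,
clearances L/h/kg); IIV percentages convert to lognormal variances as
``omega^2 = (IIV%/100)^2``.
"""

from __future__ import annotations

from .population import PopulationModel
from .structural import StructuralParams

__all__ = ["rat_final_model", "rat_base_model"]


def rat_final_model() -> PopulationModel:
    """Final covariate model with the reference rat estimates."""
    structural = StructuralParams(
        ka=1.35,
        fpm=0.589,
        clp=1.97,
        clpm=1.26,
        vp=14.6,
        clm=12.3,
        vm=84.2,
        tlag=0.0,  # no absorption lag observed in rats
        emax_fpm=0.147,
        ic50_fpm=538.0,
        emax_clpm=1.00,  # boundary estimate, held fixed
        ic50_clpm=276.0,
    )
    return PopulationModel(
        structural=structural,
        omega={"clp": 0.079**2},
        sigma_p=0.199,
        sigma_m=0.240,
        covariates=("fpm", "clpm"),
        fixed=("emax_clpm",),
    )


def rat_base_model() -> PopulationModel:
    """Pre-covariate model: no PPL effects, IIV on CLp and CLpm."""
    final = rat_final_model()
    structural = final.structural.replace(
        emax_fpm=0.0, ic50_fpm=1.0, emax_clpm=0.0, ic50_clpm=1.0
    )
    return PopulationModel(
        structural=structural,
        omega={"clp": 0.184**2, "clpm": 1.49**2},
        sigma_p=final.sigma_p,
        sigma_m=final.sigma_m,
        covariates=(),
        fixed=(),
    )
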