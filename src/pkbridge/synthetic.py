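"""Synthetic rat-study generator.

The raw concentration data behind the rat study are not published, so this
module generates datasets with the statistical structure the analysis
assumes: the reference population model (lognormal IIV, proportional
residual error per analyte) evaluated on the 3x6-rat single-dose design,
with the 5-1000 ng/mL quantifiable range applied as flags.  Values outside
the range are flagged (``BLQ`` below, ``ALQ`` above), never truncated, so
downstream exclusion policies remain observable.
"""

from __future__ import annotations

import pandas as pd

from .data import PKDataset, StudyDesign
from .population import PopulationModel, simulate_dataset
from .presets import rat_final_model

__all__ = ["generate_study", "truth_report", "DEFAULT_DESIGN"]

DEFAULT_DESIGN = StudyDesign()


def generate_study(truth: PopulationModel | None = None,
                   design: StudyDesign | None = None,
                   seed: int = 0) -> PKDataset:
    """One replicate rat study with quantification-range flags.

    ``truth`` defaults to the reference final model; ``design`` to the
    3-group rat design.  Deterministic for a fixed seed.
    """
    truth = truth if truth is not None else rat_final_model()
    design = design if design is not None else DEFAULT_DESIGN
    ds = simulate_dataset(truth, design, seed=seed)
    df = ds.df.copy()
    obs = df["DV"].notna()
    df["BLQ"] = ((df["DV"] < design.lloq) & obs).astype(int)
    df["ALQ"] = ((df["DV"] > design.uloq) & obs).astype(int)
    return PKDataset(df)


def truth_report(truth: PopulationModel | None = None,
                 design: StudyDesign | None = None) -> pd.DataFrame:
    """Generating parameter values, for scoring recovery against."""
    truth = truth if truth is not None else rat_final_model()
    design = design if design is not None else DEFAULT_DESIGN
    p = truth.structural
    rows = [
        ("ka", "1/h", p.ka),
        ("fpm", "", p.fpm),
        ("clp", "L/h/kg", p.clp),
        ("clpm", "L/h/kg", p.clpm),
        ("vp", "L/kg", p.vp),
        ("clm", "L/h/kg", p.clm),
        ("vm", "L/kg", p.vm),
        ("tlag", "h", p.tlag),
        ("emax_fpm", "", p.emax_fpm),
        ("ic50_fpm", "mg/kg", p.ic50_fpm),
        ("emax_clpm", "", p.emax_clpm),
        ("ic50_clpm", "mg/kg", p.ic50_clpm),
        ("sigma_p", "proportional SD", truth.sigma_p),
        ("sigma_m", "proportional SD", truth.sigma_m),
    ]
    for k, v in truth.omega.items():
        rows.append((f"omega2_{k}", "variance", v))
        rows.append((f"iiv_{k}", "CV %", truth.iiv_percent()[k]))
    rows.append(("dlx_dose", "mg/kg", design.dlx_dose))
    for label, ppl, n in design.groups:
        rows.append((f"ppl_dose_{label}", "mg/kg", ppl))
    return pd.DataFrame(rows, columns=["parameter", "unit", "value"])
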