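"""Long-format concentration-time datasets and the rat study design.

The on-disk dialect is a plain CSV with columns

    ID, TIME, DV, AMT, ANALYTE, DOSE_DLX, DOSE_PPL, BLQ

one dosing row per subject at TIME = 0 (AMT set, DV empty) and one row per
observation (DV set, AMT empty, ANALYTE ``parent`` or ``metabolite``).
Units travel with the columns: TIME h, DV ng/mL, AMT and DOSE_DLX mg/kg
(rat) or mg (human), DOSE_PPL mg/kg.  Optional extra columns ``GROUP``
(label) and ``ALQ`` (above the calibrated range) are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PKDataset", "StudyDesign", "DatasetError", "PARENT", "METABOLITE"]

PARENT = "parent"
METABOLITE = "metabolite"

_REQUIRED = ["ID", "TIME", "DV", "AMT", "ANALYTE", "DOSE_DLX", "DOSE_PPL", "BLQ"]


class DatasetError(ValueError):
    """The dataset violates the schema or its invariants."""


@dataclass(frozen=True)
class StudyDesign:
    """A balanced single-oral-dose design with a per-group PPL covariate.

    Defaults reproduce the rat drug-interaction study: 3 groups of 6 rats
    given DLX 40 mg/kg with PPL 0/500/1500 mg/kg, sampled at 0-24 h, with a
    5-1000 ng/mL calibrated range.
    """

    groups: tuple = (("G1", 0.0, 6), ("G2", 500.0, 6), ("G3", 1500.0, 6))
    dlx_dose: float = 40.0
    sample_times: tuple = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
    lloq: float = 5.0
    uloq: float = 1000.0

    @property
    def n_subjects(self) -> int:
        return sum(n for _, _, n in self.groups)

    @property
    def post_dose_times(self) -> np.ndarray:
        return np.asarray([t for t in self.sample_times if t > 0], dtype=float)


class PKDataset:
    """Validated long-format observations with dosing and the PPL covariate."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    # -- construction ---------------------------------------------------
    @classmethod
    def read_csv(cls, path) -> "PKDataset":
        df = pd.read_csv(path)
        return cls(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def _validate(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        df = self.df
        if (df["TIME"] < 0).any():
            rows = df.index[df["TIME"] < 0].tolist()
            raise DatasetError(f"negative TIME at rows {rows}")
        obs = df[df["DV"].notna()]
        if (obs["DV"] < 0).any():
            rows = obs.index[obs["DV"] < 0].tolist()
            raise DatasetError(f"negative DV at rows {rows}")
        dup = obs.duplicated(subset=["ID", "TIME", "ANALYTE"])
        if dup.any():
            rows = obs.index[dup].tolist()
            raise DatasetError(f"duplicate (ID, TIME, ANALYTE) at rows {rows}")
        dose_rows = df[df["AMT"].notna()]
        for sid, sub in dose_rows.groupby("ID"):
            if len(sub) > 1:
                raise DatasetError(f"subject {sid} has multiple dose rows")
            if (sub["TIME"] != 0).any():
                raise DatasetError(f"subject {sid} dose row not at TIME=0")
        bad = obs[~obs["ANALYTE"].isin([PARENT, METABOLITE])]
        if len(bad):
            raise DatasetError(f"unknown ANALYTE at rows {bad.index.tolist()}")

    # -- views -----------------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.df["ID"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def observations(self, drop_blq: bool = True,
                     drop_predose: bool = True) -> pd.DataFrame:
        """Observation rows usable in a likelihood (BLQ and t=0 excluded)."""
        obs = self.df[self.df["DV"].notna()]
        if drop_blq:
            obs = obs[obs["BLQ"] == 0]
        if drop_predose:
            obs = obs[obs["TIME"] > 0]
        return obs

    def subject_table(self) -> pd.DataFrame:
        """One row per subject: DLX dose and PPL covariate dose."""
        return (
            self.df.groupby("ID", sort=False)[["DOSE_DLX", "DOSE_PPL"]]
            .first()
            .reset_index()
        )

    def resample_subjects(self, ids, new_ids=None) -> "PKDataset":
        """Dataset made of the given subjects (with replacement allowed).

        ``new_ids`` relabels the drawn subjects so repeated draws stay
        distinct individuals.
        """
        if new_ids is None:
            new_ids = [f"B{i}" for i in range(len(ids))]
        parts = []
        for new, old in zip(new_ids, ids):
            sub = self.df[self.df["ID"] == old].copy()
            sub["ID"] = new
            parts.append(sub)
        return PKDataset(pd.concat(parts, ignore_index=True), validate=False)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PKDataset):
            return NotImplemented
        return self.df.equals(other.df)
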