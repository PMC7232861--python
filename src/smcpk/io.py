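"""NONMEM-style tabular datasets.

A dataset is a CSV with one row per dosing or observation event:

==========  =================================================================
Column      Meaning
==========  =================================================================
ID          subject identifier
TIME        hours since the subject's first scheduled dose
EVID        1 = dosing event, 0 = observation
CMT         compartment: 1 depot (doses), 2 AQ central, 4 DEAQ central (obs)
AMT         dose amount in micromol AQ base (dosing rows only)
DV          observed concentration in nmol/L (observation rows, MDV=0)
MDV         1 = DV missing/not applicable
BLQ         1 = below the lower limit of quantification (M1: excluded from
            likelihood and statistics but retained in the file)
AGE         age in months
WT          body weight in kg
==========  =================================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .params import Subject
from .pk import DoseEvent

__all__ = ["Dataset", "SubjectData", "read_dataset", "write_dataset", "DatasetError"]

COLUMNS = ["ID", "TIME", "EVID", "CMT", "AMT", "DV", "MDV", "BLQ", "AGE", "WT"]
CMT_DEPOT = 1
OBS_CMT = {2: "AQ", 4: "DEAQ"}
ANALYTE_CMT = {"AQ": 2, "DEAQ": 4}


class DatasetError(ValueError):
    """Structural problem in a dataset; message lists offending rows."""


@dataclass
class SubjectData:
    """All events of one subject, unpacked for model evaluation."""

    subject: Subject
    dose_times: np.ndarray
    dose_amounts: np.ndarray
    obs_times: np.ndarray
    analytes: np.ndarray      # "AQ"/"DEAQ" per observation
    dv: np.ndarray            # nmol/L
    blq: np.ndarray           # bool

    @property
    def doses(self) -> list[DoseEvent]:
        return [
            DoseEvent(float(t), float(a))
            for t, a in zip(self.dose_times, self.dose_amounts)
        ]


@dataclass
class Dataset:
    """Validated tabular dataset wrapping a pandas DataFrame."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        problems = []

        def flag(mask, msg):
            rows = df.index[mask].tolist()
            if rows:
                problems.append(f"{msg} (rows {rows[:10]})")

        flag(df["TIME"] < 0, "negative TIME")
        flag(~df["EVID"].isin([0, 1]), "EVID must be 0 or 1")
        doses = df["EVID"] == 1
        obs = ~doses
        flag(doses & df["DV"].notna() & (df["MDV"] == 0), "DV on a dosing row")
        flag(doses & (df["AMT"].fillna(-1) < 0), "dosing row without AMT >= 0")
        flag(doses & (df["CMT"] != CMT_DEPOT), "doses must go to the depot (CMT=1)")
        flag(obs & ~df["CMT"].isin(list(OBS_CMT)), "observation CMT must be 2 or 4")
        flag(obs & (df["MDV"] == 0) & df["DV"].isna(), "MDV=0 requires DV")
        flag(obs & (df["MDV"] == 1) & df["DV"].notna(), "MDV=1 forbids DV")
        flag(obs & (df["DV"].fillna(0) < 0), "negative DV")
        flag((df["WT"] <= 0) | df["WT"].isna(), "WT must be positive")
        flag((df["AGE"] < 0) | df["AGE"].isna(), "AGE must be non-negative")
        for sid, sub in df.groupby("ID", sort=False):
            if not np.all(np.diff(sub["TIME"].to_numpy()) >= 0):
                problems.append(f"times not non-decreasing for subject {sid!r}")
        if problems:
            raise DatasetError("; ".join(problems))

    def subjects(self) -> Iterator[SubjectData]:
        for sid, sub in self.df.groupby("ID", sort=False):
            doses = sub[sub["EVID"] == 1]
            obs = sub[sub["EVID"] == 0]
            yield SubjectData(
                subject=Subject(
                    id=str(sid),
                    age_months=float(sub["AGE"].iloc[0]),
                    weight_kg=float(sub["WT"].iloc[0]),
                ),
                dose_times=doses["TIME"].to_numpy(dtype=float),
                dose_amounts=doses["AMT"].to_numpy(dtype=float),
                obs_times=obs["TIME"].to_numpy(dtype=float),
                analytes=obs["CMT"].map(OBS_CMT).to_numpy(),
                dv=obs["DV"].fillna(0.0).to_numpy(dtype=float),
                blq=obs["BLQ"].to_numpy(dtype=int).astype(bool),
            )

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()


def read_dataset(path) -> Dataset:
    """Read and validate a CSV dataset (units: h, micromol, nmol/L)."""
    df = pd.read_csv(path, comment="#")
    return Dataset(df[COLUMNS] if all(c in df.columns for c in COLUMNS) else df)


def write_dataset(dataset: Dataset, path_or_buf) -> None:
    """Write a dataset as CSV with a unit-recording header comment."""
    header = ("# units: TIME h, AMT micromol AQ base, DV nmol/L, "
              "AGE months, WT kg\n")
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(header)
        dataset.df.to_csv(path_or_buf, index=False)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(header)
            dataset.df.to_csv(fh, index=False)
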