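"""Synthetic study-data generators.

Emulates the two study designs end to end so every stage of the pipeline can
be exercised without access to measured concentrations:

* the PK cohort — 136 children aged 3-59 months, dosed with the full 3-day
  SMC regimen under direct observation and sampled in 3 of 6 protocol
  sampling windows for both analytes;
* the case-control design — one DEAQ measurement per child at a random time
  within 30 days of the first dose, with the child's true dosing pattern
  drawn from a known mixture of adherence scenarios.

Body weight is predicted from age because weights were not measured in the
source setting; the linear default below is a synthetic stand-in anchored to
the single published pair (36 months -> 11.5 kg) and is fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .adherence import AdherenceScenario, enumerate_scenarios
from .io import ANALYTE_CMT, CMT_DEPOT, COLUMNS, Dataset
from .params import (
    IIV_PARAMETERS,
    PopulationParameters,
    Subject,
    VariabilityParameters,
)
from .pk import build_regimen, individual_parameters, predict_profile
from .popsim import apply_etas, draw_etas, observe

__all__ = [
    "CohortDesign",
    "CaseControlDesign",
    "weight_from_age",
    "generate_pk_cohort",
    "generate_case_control",
]

# Six protocol sampling windows, hours after the first dose (dose 3 at 48 h):
# 0-8 h after dose 1; 0-6, 6-12 and 12-24 h after the last dose; 4-7 days and
# 14-35 days after the first dose.
PROTOCOL_WINDOWS = (
    (0.0, 8.0),
    (48.0, 54.0),
    (54.0, 60.0),
    (60.0, 72.0),
    (96.0, 168.0),
    (336.0, 840.0),
)


def weight_from_age(age_months: float) -> float:
    """Default age-to-bodyweight prediction (kg): 4.0 + 0.2083 x age.

    A linear stand-in anchored so a 36-month child weighs 11.5 kg; real
    anthropometry should replace it where available.
    """
    if not 3 <= age_months <= 59:
        raise ValueError("age must be within 3-59 months")
    return 4.0 + 0.2083 * age_months


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of the densely-designed PK cohort."""

    n_subjects: int = 136
    windows: tuple = PROTOCOL_WINDOWS
    windows_per_subject: int = 3
    weight_model: Callable[[float], float] = weight_from_age
    weight_jitter_cv: float = 10.0  # log-normal CV (%) around the predicted weight

    def __post_init__(self) -> None:
        if self.windows_per_subject > len(self.windows):
            raise ValueError("more windows per subject than windows")


def _draw_subjects(design: CohortDesign, rng: np.random.Generator) -> list[Subject]:
    ages = rng.uniform(3.0, 59.0, design.n_subjects)
    omega_wt = np.sqrt(np.log1p((design.weight_jitter_cv / 100.0) ** 2))
    subjects = []
    for i, age in enumerate(ages):
        wt = design.weight_model(float(age)) * float(
            np.exp(rng.normal(0.0, omega_wt))
        )
        subjects.append(Subject(id=f"S{i + 1:03d}", age_months=float(age),
                                weight_kg=wt))
    return subjects


def generate_pk_cohort(
    design: CohortDesign,
    pop: PopulationParameters,
    var: VariabilityParameters,
    seed: int | np.random.SeedSequence,
) -> tuple[Dataset, pd.DataFrame]:
    """Simulate the PK cohort; returns (dataset, ground-truth sidecar).

    Every child takes all 3 doses (the cohort was directly observed); each is
    sampled at one uniform time in each of 3 distinct protocol windows, for
    both analytes, on the observed (residual-error) scale with BLQ flags.
    The sidecar table records the true etas and covariates per subject.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.Generator(np.random.PCG64(ss))
    subjects = _draw_subjects(design, rng)
    rows: list[dict] = []
    truth: list[dict] = []
    for subject in subjects:
        doses = build_regimen(subject.age_months)
        etas = draw_etas(var, rng)
        ind = apply_etas(individual_parameters(pop, subject), etas)
        windows = [
            design.windows[k]
            for k in rng.choice(
                len(design.windows), design.windows_per_subject, replace=False
            )
        ]
        times = np.sort([rng.uniform(lo, hi) for lo, hi in windows])
        for d in doses:
            rows.append({
                "ID": subject.id, "TIME": d.time, "EVID": 1, "CMT": CMT_DEPOT,
                "AMT": d.amount, "DV": np.nan, "MDV": 1, "BLQ": 0,
                "AGE": subject.age_months, "WT": subject.weight_kg,
            })
        conc_aq, conc_deaq = predict_profile(ind, doses, times)
        for t, c_aq, c_dq in zip(times, conc_aq, conc_deaq):
            for analyte, c in (("AQ", c_aq), ("DEAQ", c_dq)):
                rec = observe(float(c), analyte, var, rng, subject.id, float(t))
                rows.append({
                    "ID": subject.id, "TIME": float(t), "EVID": 0,
                    "CMT": ANALYTE_CMT[analyte], "AMT": np.nan,
                    "DV": rec.value, "MDV": 0, "BLQ": int(rec.blq),
                    "AGE": subject.age_months, "WT": subject.weight_kg,
                })
        truth.append({
            "ID": subject.id, "AGE": subject.age_months, "WT": subject.weight_kg,
            **{f"eta_{k}": etas[k] for k in IIV_PARAMETERS},
        })
    df = pd.DataFrame(rows, columns=COLUMNS).sort_values(
        ["ID", "TIME", "EVID"], kind="stable", ascending=[True, True, False]
    ).reset_index(drop=True)
    return Dataset(df), pd.DataFrame(truth)


@dataclass(frozen=True)
class CaseControlDesign:
    """Single-sample case-control adherence design.

    ``mixture`` maps scenario id -> probability; scenarios refer to the
    ``dot`` regimen's scenario set.  Sampling times are uniform over
    (0, 30] days after the first scheduled dose.
    """

    n_children: int
    dot: bool
    mixture: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}
    )
    weight_model: Callable[[float], float] = weight_from_age

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mixture probabilities must sum to 1")
        valid = {sc.id for sc in enumerate_scenarios(self.dot)}
        if not set(self.mixture) <= valid:
            raise ValueError("mixture refers to unknown scenario ids")


def generate_case_control(
    design: CaseControlDesign,
    pop: PopulationParameters,
    var: VariabilityParameters,
    seed: int | np.random.SeedSequence,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the case-control sample; returns (measurements, truth labels).

    Each child is assigned a dosing pattern from the mixture, simulated with
    IIV and residual error, and measured once (DEAQ) at a uniform random time
    within 30 days.  The truth table carries the scenario id and the
    ``complete``/``poor`` adherence label (complete = all doses taken).
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.Generator(np.random.PCG64(ss))
    scenarios = {sc.id: sc for sc in enumerate_scenarios(design.dot)}
    ids = sorted(design.mixture)
    probs = np.array([design.mixture[i] for i in ids])
    rows, truth = [], []
    for i in range(design.n_children):
        age = float(rng.uniform(3.0, 59.0))
        subject = Subject(
            id=f"C{i + 1:04d}", age_months=age,
            weight_kg=design.weight_model(age),
        )
        sc: AdherenceScenario = scenarios[ids[rng.choice(len(ids), p=probs)]]
        t = float(rng.uniform(0.0, 30.0 * 24.0))
        while t == 0.0:  # open interval at 0
            t = float(rng.uniform(0.0, 30.0 * 24.0))
        doses = build_regimen(subject.age_months, sc.taken)
        ind = apply_etas(individual_parameters(pop, subject), draw_etas(var, rng))
        _, deaq = predict_profile(ind, doses, np.array([t]))
        rec = observe(float(deaq[0]), "DEAQ", var, rng, subject.id, t)
        rows.append({
            "ID": subject.id, "TIME": t, "DV": rec.value, "BLQ": int(rec.blq),
            "AGE": subject.age_months, "WT": subject.weight_kg,
        })
        truth.append({
            "ID": subject.id, "scenario": sc.id, "pattern": sc.label,
            "label": "complete" if sc.full_adherence else "poor",
        })
    return pd.DataFrame(rows), pd.DataFrame(truth)
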