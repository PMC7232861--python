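"""Stochastic population layer.

Adds log-normal inter-individual variability (IIV) on six structural
parameters, log-scale additive residual error on observations, and censoring
at the lower limit of quantification (LLOQ).  Records flagged below the LLOQ
(BLQ) are retained but excluded from likelihoods and statistics (M1 handling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .params import (
    IIV_PARAMETERS,
    IndividualParameters,
    PopulationParameters,
    Subject,
    VariabilityParameters,
)
from .pk import DoseEvent, individual_parameters, predict_profile

__all__ = [
    "ConcentrationRecord",
    "sample_individual",
    "apply_etas",
    "observe",
    "simulate_population",
]


@dataclass(frozen=True)
class ConcentrationRecord:
    """One observed (or simulated-observed) drug level."""

    subject_id: str
    time: float          # hours since first scheduled dose
    analyte: str         # "AQ" | "DEAQ"
    value: float         # nmol/L, on the observed (residual-error) scale
    blq: bool            # below the lower limit of quantification
    lloq: float          # nmol/L

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("concentration values must be non-negative")


def apply_etas(
    base: IndividualParameters, etas: dict[str, float]
) -> IndividualParameters:
    """Multiply IIV-bearing parameters of covariate-scaled values by exp(eta)."""
    unknown = set(etas) - set(IIV_PARAMETERS)
    if unknown:
        raise ValueError(f"no IIV supported on: {sorted(unknown)}")
    updates = {k: getattr(base, k) * float(np.exp(v)) for k, v in etas.items()}
    fields = {
        k: updates.get(k, getattr(base, k))
        for k in (
            "f_aq", "ka", "cl_aq", "vc_aq", "q_aq", "vp_aq",
            "cl_deaq", "vc_deaq", "q1_deaq", "vp1_deaq", "q2_deaq", "vp2_deaq",
        )
    }
    return IndividualParameters(**fields, eta=dict(etas))


def draw_etas(var: VariabilityParameters, rng: np.random.Generator) -> dict[str, float]:
    """Independent normal log-scale random effects (diagonal omega)."""
    return {k: float(rng.normal(0.0, var.omega_for(k))) for k in IIV_PARAMETERS}


def sample_individual(
    pop: PopulationParameters,
    var: VariabilityParameters,
    subject: Subject,
    rng: np.random.Generator,
) -> IndividualParameters:
    """Covariate scaling followed by one log-normal IIV draw per parameter."""
    return apply_etas(individual_parameters(pop, subject), draw_etas(var, rng))


def observe(
    true_conc: float,
    analyte: str,
    var: VariabilityParameters,
    rng: np.random.Generator,
    subject_id: str = "",
    time: float = 0.0,
) -> ConcentrationRecord:
    """Apply log-scale residual error and LLOQ censoring to a model prediction.

    A zero prediction yields a zero-valued BLQ record (nothing to assay);
    otherwise value = true * exp(eps), eps ~ N(0, sigma^2), flagged BLQ when
    it falls below the analyte's LLOQ.
    """
    if true_conc < 0:
        raise ValueError("true concentration must be non-negative")
    lloq = var.lloq_for(analyte)
    if true_conc == 0.0:
        return ConcentrationRecord(subject_id, time, analyte, 0.0, True, lloq)
    sigma = var.sigma_for(analyte)
    value = float(true_conc * np.exp(rng.normal(0.0, sigma)))
    return ConcentrationRecord(subject_id, time, analyte, value, value < lloq, lloq)


def simulate_population(
    pop: PopulationParameters,
    var: VariabilityParameters,
    subjects: Sequence[Subject],
    doses_for: "callable | Sequence[DoseEvent]",
    times: Sequence[float],
    seed: int | np.random.SeedSequence,
    analytes: Iterable[str] = ("AQ", "DEAQ"),
) -> list[ConcentrationRecord]:
    """Simulate observed concentrations for a set of subjects.

    ``doses_for`` is either a fixed dose list or a callable mapping a Subject
    to its dose list.  Each subject gets an independent substream spawned from
    the seed, so results are reproducible and independent of subject order.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("time grid must be non-empty")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = ss.spawn(len(subjects))
    analytes = tuple(analytes)
    records: list[ConcentrationRecord] = []
    for subject, child_ss in zip(subjects, streams):
        rng = np.random.Generator(np.random.PCG64(child_ss))
        ind = sample_individual(pop, var, subject, rng)
        doses = doses_for(subject) if callable(doses_for) else doses_for
        conc_aq, conc_deaq = predict_profile(ind, doses, times)
        by_analyte = {"AQ": conc_aq, "DEAQ": conc_deaq}
        for analyte in analytes:
            for t, c in zip(times, by_analyte[analyte]):
                records.append(
                    observe(float(c), analyte, var, rng, subject.id, float(t))
                )
    return records
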