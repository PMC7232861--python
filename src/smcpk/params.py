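"""Parameter containers for the amodiaquine (AQ) / desethylamodiaquine (DEAQ)
population pharmacokinetic model.

The default fixed-effect values describe a typical 10-kg child with fully
matured drug-metabolising enzymes: AQ follows two-compartment disposition with
first-order absorption, and its active metabolite DEAQ follows
three-compartment disposition.  All clearances and volumes are apparent
(scaled by the unknown oral bioavailability F) and are allometrically scaled
to a 10-kg reference body weight; the two elimination clearances additionally
carry an age-dependent maturation factor ``age / (age50 + age)``.

Units: clearances L/h, volumes L, absorption rate 1/h, ages months,
amounts micromol, concentrations nmol/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional

import yaml

__all__ = [
    "MW_AQ",
    "MW_DEAQ",
    "IIV_PARAMETERS",
    "PopulationParameters",
    "VariabilityParameters",
    "Subject",
    "IndividualParameters",
    "cv_to_omega",
    "omega_to_cv",
    "load_parameters",
    "save_parameters",
    "default_parameters",
]

# Molar masses of the free bases (g/mol); used only to express mg doses on the
# micromolar amount scale that the concentration units (nmol/L) imply.
MW_AQ = 355.86
MW_DEAQ = 327.85

# The six structural parameters that carry log-normal inter-individual
# variability (IIV); all other parameters are shared across subjects.
IIV_PARAMETERS = ("f_aq", "ka", "cl_aq", "vc_aq", "cl_deaq", "vp1_deaq")


@dataclass(frozen=True)
class PopulationParameters:
    """Typical-value (fixed-effect) parameters.

    Defaults are the final population estimates for SMC-dosed children aged
    3-59 months, quoted for a 10-kg, fully matured reference child.
    """

    f_aq: float = 1.0          # relative oral bioavailability (fraction)
    ka: float = 2.85           # first-order absorption rate (1/h)
    cl_aq: float = 101.0       # AQ elimination clearance CL/F (L/h)
    vc_aq: float = 314.0       # AQ central volume Vc/F (L)
    q_aq: float = 119.0        # AQ intercompartmental clearance Q/F (L/h)
    vp_aq: float = 1820.0      # AQ peripheral volume Vp/F (L)
    cl_deaq: float = 2.33      # DEAQ elimination clearance CL/F (L/h)
    vc_deaq: float = 49.1      # DEAQ central volume Vc/F (L)
    q1_deaq: float = 2.31      # DEAQ first intercompartmental clearance (L/h)
    vp1_deaq: float = 363.0    # DEAQ first peripheral volume (L)
    q2_deaq: float = 4.34      # DEAQ second intercompartmental clearance (L/h)
    vp2_deaq: float = 98.1     # DEAQ second peripheral volume (L)
    age50_aq: float = 4.66     # age of half-maximal AQ clearance maturation (months)
    age50_deaq: float = 2.42   # age of half-maximal DEAQ clearance maturation (months)
    ref_weight: float = 10.0   # allometric reference body weight (kg)
    allo_exp_cl: float = 0.75  # allometric exponent on clearances (fixed)
    allo_exp_v: float = 1.0    # allometric exponent on volumes (fixed)

    def __post_init__(self) -> None:
        for name in (
            "f_aq", "ka", "cl_aq", "vc_aq", "q_aq", "vp_aq",
            "cl_deaq", "vc_deaq", "q1_deaq", "vp1_deaq", "q2_deaq",
            "vp2_deaq", "ref_weight",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.age50_aq < 0 or self.age50_deaq < 0:
            raise ValueError("half-maturation ages must be non-negative")

    def with_updates(self, **kwargs: float) -> "PopulationParameters":
        return replace(self, **kwargs)


def cv_to_omega(cv_percent: float) -> float:
    """Convert a log-normal coefficient of variation (%) to the log-scale SD.

    Uses the standard relation ``omega = sqrt(ln(1 + (CV/100)^2))`` for a
    log-normal random effect with multiplicative interpretation.
    """
    if cv_percent < 0:
        raise ValueError("CV must be non-negative")
    return math.sqrt(math.log1p((cv_percent / 100.0) ** 2))


def omega_to_cv(omega: float) -> float:
    """Inverse of :func:`cv_to_omega` (returns percent)."""
    return 100.0 * math.sqrt(math.expm1(omega ** 2))


def _default_omega() -> dict:
    # Printed IIV coefficients of variation (%): F 37.5, ka 173, CL_AQ 22.2,
    # Vc_AQ 80.4, CL_DEAQ 15.2, Vp1_DEAQ 68.3.
    cvs = {
        "f_aq": 37.5,
        "ka": 173.0,
        "cl_aq": 22.2,
        "vc_aq": 80.4,
        "cl_deaq": 15.2,
        "vp1_deaq": 68.3,
    }
    return {k: cv_to_omega(v) for k, v in cvs.items()}


@dataclass(frozen=True)
class VariabilityParameters:
    """Random-effect magnitudes: log-normal IIV, log-scale residual error and
    lower limits of quantification (LLOQ).

    ``omega`` maps each IIV-bearing parameter name to its log-scale SD;
    only the six parameters in :data:`IIV_PARAMETERS` may appear.
    ``sigma_*`` are additive residual SDs on the log-concentration scale.
    """

    omega: Mapping[str, float] = field(default_factory=_default_omega)
    sigma_aq: float = 0.829
    sigma_deaq: float = 0.204
    lloq_aq: float = 1.0     # nmol/L
    lloq_deaq: float = 1.0   # nmol/L

    def __post_init__(self) -> None:
        extra = set(self.omega) - set(IIV_PARAMETERS)
        if extra:
            raise ValueError(f"IIV not supported on parameters: {sorted(extra)}")
        if any(v < 0 for v in self.omega.values()):
            raise ValueError("omega entries must be non-negative")
        if self.sigma_aq < 0 or self.sigma_deaq < 0:
            raise ValueError("residual SDs must be non-negative")
        object.__setattr__(self, "omega", dict(self.omega))

    def omega_for(self, name: str) -> float:
        return float(self.omega.get(name, 0.0))

    def sigma_for(self, analyte: str) -> float:
        return self.sigma_aq if analyte == "AQ" else self.sigma_deaq

    def lloq_for(self, analyte: str) -> float:
        return self.lloq_aq if analyte == "AQ" else self.lloq_deaq

    def with_no_variability(self) -> "VariabilityParameters":
        return VariabilityParameters(
            omega={k: 0.0 for k in self.omega},
            sigma_aq=0.0,
            sigma_deaq=0.0,
            lloq_aq=self.lloq_aq,
            lloq_deaq=self.lloq_deaq,
        )


@dataclass(frozen=True)
class Subject:
    """A study child; ages are restricted to the SMC target range by the
    cohort generators, not here."""

    id: str
    age_months: float
    weight_kg: float
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight must be strictly positive")
        if self.age_months < 0:
            raise ValueError("age must be non-negative")


@dataclass(frozen=True)
class IndividualParameters:
    """Structural parameters after covariate scaling and (optionally) IIV.

    ``eta`` records the log-scale random effects actually applied; all zeros
    reproduce the covariate-only values.
    """

    f_aq: float
    ka: float
    cl_aq: float
    vc_aq: float
    q_aq: float
    vp_aq: float
    cl_deaq: float
    vc_deaq: float
    q1_deaq: float
    vp1_deaq: float
    q2_deaq: float
    vp2_deaq: float
    eta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "f_aq", "ka", "cl_aq", "vc_aq", "q_aq", "vp_aq",
            "cl_deaq", "vc_deaq", "q1_deaq", "vp1_deaq", "q2_deaq", "vp2_deaq",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        object.__setattr__(self, "eta", dict(self.eta))


# ---------------------------------------------------------------------------
# Flat key-value (YAML) serialisation of a parameter set
# ---------------------------------------------------------------------------

_POP_KEYS = [
    "f_aq", "ka", "cl_aq", "vc_aq", "q_aq", "vp_aq",
    "cl_deaq", "vc_deaq", "q1_deaq", "vp1_deaq", "q2_deaq", "vp2_deaq",
    "age50_aq", "age50_deaq", "ref_weight", "allo_exp_cl", "allo_exp_v",
]


def save_parameters(path, pop: PopulationParameters,
                    var: Optional[VariabilityParameters] = None) -> None:
    """Write a parameter set as a flat key-value YAML file."""
    data = {k: float(getattr(pop, k)) for k in _POP_KEYS}
    if var is not None:
        for k in IIV_PARAMETERS:
            data[f"omega_{k}"] = float(var.omega_for(k))
        data["sigma_aq"] = float(var.sigma_aq)
        data["sigma_deaq"] = float(var.sigma_deaq)
        data["lloq_aq"] = float(var.lloq_aq)
        data["lloq_deaq"] = float(var.lloq_deaq)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _parse_parameters(data: Mapping) -> tuple:
    pop = PopulationParameters(**{k: float(data[k]) for k in _POP_KEYS if k in data})
    omega = {
        k: float(data[f"omega_{k}"])
        for k in IIV_PARAMETERS
        if f"omega_{k}" in data
    }
    var = VariabilityParameters(
        omega=omega or _default_omega(),
        sigma_aq=float(data.get("sigma_aq", 0.829)),
        sigma_deaq=float(data.get("sigma_deaq", 0.204)),
        lloq_aq=float(data.get("lloq_aq", 1.0)),
        lloq_deaq=float(data.get("lloq_deaq", 1.0)),
    )
    return pop, var


def load_parameters(path) -> tuple:
    """Read (PopulationParameters, VariabilityParameters) from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return _parse_parameters(data)


def default_parameters() -> tuple:
    """The packaged default parameter set (published population estimates)."""
    ref = resources.files("smcpk.data").joinpath("default_parameters.yaml")
    data = yaml.safe_load(ref.read_text())
    return _parse_parameters(data)
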