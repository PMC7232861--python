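"""Deterministic parent-metabolite compartmental model.

Amodiaquine (AQ) kinetics follow a two-compartment disposition model with
first-order absorption from a depot; the entire AQ elimination flux is
converted into desethylamodiaquine (DEAQ), which follows three-compartment
disposition with first-order elimination.  The six amounts (depot, AQ
central/peripheral, DEAQ central and two peripherals) obey a linear,
time-invariant ODE system that is solved analytically by eigendecomposition
of the rate matrix, with superposition across dose events.  A stiff numeric
integrator is used as fallback for (numerically) degenerate eigenvalues.

Amounts are carried in micromol so central-compartment concentrations are
micromol/L; reported concentrations are multiplied by 1000 to the nmol/L
scale used by the assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import quad, solve_ivp

from .params import (
    MW_AQ,
    IndividualParameters,
    PopulationParameters,
    Subject,
)

__all__ = [
    "DoseEvent",
    "mg_to_micromol",
    "build_regimen",
    "individual_parameters",
    "rate_matrix",
    "predict_profile",
    "predict_amounts",
    "terminal_half_life",
    "auc_infinity",
    "summarize_exposure",
    "AQ_DOSE_MG_INFANT",
    "AQ_DOSE_MG_CHILD",
]

# Daily AQ base doses by age band (mg): 57.5 mg for 3-11 months,
# 153 mg for 12-59 months; 3 daily doses in both bands.
AQ_DOSE_MG_INFANT = 57.5
AQ_DOSE_MG_CHILD = 153.0

# State indexing of the linear system
_DEPOT, _AQ_C, _AQ_P, _DEAQ_C, _DEAQ_P1, _DEAQ_P2 = range(6)


@dataclass(frozen=True)
class DoseEvent:
    """One scheduled oral AQ dose.

    time is hours since the first scheduled dose; amount is micromol AQ base;
    ``taken=False`` marks a missed dose that contributes nothing.
    """

    time: float
    amount: float
    taken: bool = True

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")
        if self.time < 0:
            raise ValueError("dose time must be non-negative")


def mg_to_micromol(dose_mg: float) -> float:
    """Convert an AQ base dose in mg to micromol (molar mass 355.86 g/mol)."""
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    return dose_mg / MW_AQ * 1000.0


def build_regimen(
    age_months: float,
    taken: Sequence[bool] = (True, True, True),
    dose_interval: float = 24.0,
) -> list[DoseEvent]:
    """The 3-daily-dose SMC regimen for a child of the given age.

    Doses fall at 0, ``dose_interval`` and 2x``dose_interval`` hours (24 h by
    default); the per-dose amount is the age-band AQ dose converted to
    micromol.  ``taken`` flags (dose 1, 2, 3) mark adherence.
    """
    if not 3 <= age_months <= 59:
        raise ValueError("age must be within 3-59 months for the SMC regimen")
    if len(taken) != 3:
        raise ValueError("taken must have exactly 3 flags")
    mg = AQ_DOSE_MG_INFANT if age_months < 12 else AQ_DOSE_MG_CHILD
    amount = mg_to_micromol(mg)
    return [
        DoseEvent(time=i * dose_interval, amount=amount, taken=bool(t))
        for i, t in enumerate(taken)
    ]


def maturation(age_months: float, age50: float) -> float:
    """Fraction of adult-equivalent clearance attained: age/(age50 + age)."""
    if age_months < 0:
        raise ValueError("age must be non-negative")
    if age50 == 0:
        return 1.0
    return age_months / (age50 + age_months)


def individual_parameters(
    pop: PopulationParameters, subject: Subject
) -> IndividualParameters:
    """Apply allometric and maturation covariate scaling (no random effects).

    All clearances scale with (weight/ref)^0.75 and all volumes with
    (weight/ref)^1.0; the two elimination clearances are additionally
    multiplied by the maturation fraction age/(age50 + age).
    """
    if subject.weight_kg <= 0:
        raise ValueError("weight must be strictly positive")
    wt = subject.weight_kg / pop.ref_weight
    f_cl = wt ** pop.allo_exp_cl
    f_v = wt ** pop.allo_exp_v
    return IndividualParameters(
        f_aq=pop.f_aq,
        ka=pop.ka,
        cl_aq=pop.cl_aq * f_cl * maturation(subject.age_months, pop.age50_aq),
        vc_aq=pop.vc_aq * f_v,
        q_aq=pop.q_aq * f_cl,
        vp_aq=pop.vp_aq * f_v,
        cl_deaq=pop.cl_deaq * f_cl * maturation(subject.age_months, pop.age50_deaq),
        vc_deaq=pop.vc_deaq * f_v,
        q1_deaq=pop.q1_deaq * f_cl,
        vp1_deaq=pop.vp1_deaq * f_v,
        q2_deaq=pop.q2_deaq * f_cl,
        vp2_deaq=pop.vp2_deaq * f_v,
        eta={},
    )


def rate_matrix(ind: IndividualParameters) -> np.ndarray:
    """First-order rate matrix of the 6-state amount system."""
    ka = ind.ka
    ke_aq = ind.cl_aq / ind.vc_aq
    k23 = ind.q_aq / ind.vc_aq
    k32 = ind.q_aq / ind.vp_aq
    ke_d = ind.cl_deaq / ind.vc_deaq
    k45 = ind.q1_deaq / ind.vc_deaq
    k54 = ind.q1_deaq / ind.vp1_deaq
    k46 = ind.q2_deaq / ind.vc_deaq
    k64 = ind.q2_deaq / ind.vp2_deaq
    A = np.zeros((6, 6))
    A[_DEPOT, _DEPOT] = -ka
    A[_AQ_C, _DEPOT] = ka
    A[_AQ_C, _AQ_C] = -(ke_aq + k23)
    A[_AQ_C, _AQ_P] = k32
    A[_AQ_P, _AQ_C] = k23
    A[_AQ_P, _AQ_P] = -k32
    A[_DEAQ_C, _AQ_C] = ke_aq          # complete molar conversion AQ -> DEAQ
    A[_DEAQ_C, _DEAQ_C] = -(ke_d + k45 + k46)
    A[_DEAQ_C, _DEAQ_P1] = k54
    A[_DEAQ_C, _DEAQ_P2] = k64
    A[_DEAQ_P1, _DEAQ_C] = k45
    A[_DEAQ_P1, _DEAQ_P1] = -k54
    A[_DEAQ_P2, _DEAQ_C] = k46
    A[_DEAQ_P2, _DEAQ_P2] = -k64
    return A


def _impulse_eigensystem(ind: IndividualParameters):
    """Eigen-expansion of the unit-depot impulse response.

    Returns (lam, coef) with coef shape (6, 6) such that the state vector of
    a unit depot dose at elapsed time tau is ``coef @ exp(lam * tau)``.
    Raises ArithmeticError when eigenvalues are numerically degenerate.
    """
    A = rate_matrix(ind)
    lam, vec = np.linalg.eig(A)
    if np.max(np.abs(lam.imag)) > 1e-9 * np.max(np.abs(lam.real)):
        raise ArithmeticError("complex eigenvalues")
    lam = lam.real
    vec = vec.real
    gaps = np.abs(np.subtract.outer(lam, lam))
    np.fill_diagonal(gaps, np.inf)
    if gaps.min() < 1e-9 * np.max(np.abs(lam)):
        raise ArithmeticError("near-degenerate eigenvalues")
    e0 = np.zeros(6)
    e0[_DEPOT] = 1.0
    w = np.linalg.solve(vec, e0)
    coef = vec * w  # coef[j, k] = vec[j, k] * w[k]
    return lam, coef


def _unit_states_eigen(ind: IndividualParameters, tau: np.ndarray) -> np.ndarray:
    lam, coef = _impulse_eigensystem(ind)
    return np.exp(np.outer(tau, lam)) @ coef.T  # (ntau, 6)


def _unit_states_ode(ind: IndividualParameters, tau: np.ndarray) -> np.ndarray:
    """Stiff-integrator fallback for degenerate eigensystems."""
    A = rate_matrix(ind)
    y0 = np.zeros(6)
    y0[_DEPOT] = 1.0
    out = np.zeros((len(tau), 6))
    order = np.argsort(tau)
    ts = np.asarray(tau)[order]
    positive = ts > 0
    if positive.any():
        sol = solve_ivp(
            lambda t, y: A @ y,
            (0.0, float(ts[positive][-1])),
            y0,
            t_eval=ts[positive],
            method="BDF",
            jac=lambda t, y: A,
            rtol=1e-10,
            atol=1e-14,
        )
        if not sol.success:
            raise RuntimeError(f"ODE fallback failed: {sol.message}")
        out[order[positive]] = sol.y.T
    out[np.asarray(tau) == 0] = y0
    return out


def predict_amounts(
    ind: IndividualParameters,
    doses: Iterable[DoseEvent],
    times: Sequence[float],
) -> np.ndarray:
    """Compartment amounts (micromol, shape (ntimes, 6)) by superposition of
    single-dose impulse responses."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    try:
        lam, coef = _impulse_eigensystem(ind)
        unit = lambda tau: np.exp(np.outer(tau, lam)) @ coef.T
    except ArithmeticError:
        unit = lambda tau: _unit_states_ode(ind, tau)
    out = np.zeros((len(times), 6))
    for d in doses:
        if not d.taken or d.amount == 0:
            continue
        tau = times - d.time
        mask = tau >= 0
        if mask.any():
            out[mask] += ind.f_aq * d.amount * unit(tau[mask])
    return out


def predict_profile(
    ind: IndividualParameters,
    doses: Iterable[DoseEvent],
    times: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """AQ and DEAQ central concentrations (nmol/L) at the requested times."""
    amounts = predict_amounts(ind, doses, times)
    conc_aq = amounts[:, _AQ_C] / ind.vc_aq * 1000.0
    conc_deaq = amounts[:, _DEAQ_C] / ind.vc_deaq * 1000.0
    floor = -1e-6 * max(1.0, float(np.max(np.abs(amounts))))
    if (conc_aq < floor).any() or (conc_deaq < floor).any():
        raise ArithmeticError("negative concentration beyond numerical tolerance")
    return np.maximum(conc_aq, 0.0), np.maximum(conc_deaq, 0.0)


def _disposition_matrix(ind: IndividualParameters, analyte: str) -> np.ndarray:
    if analyte == "AQ":
        ke = ind.cl_aq / ind.vc_aq
        k23 = ind.q_aq / ind.vc_aq
        k32 = ind.q_aq / ind.vp_aq
        return np.array([[-(ke + k23), k32], [k23, -k32]])
    if analyte == "DEAQ":
        ke = ind.cl_deaq / ind.vc_deaq
        k45 = ind.q1_deaq / ind.vc_deaq
        k54 = ind.q1_deaq / ind.vp1_deaq
        k46 = ind.q2_deaq / ind.vc_deaq
        k64 = ind.q2_deaq / ind.vp2_deaq
        return np.array(
            [
                [-(ke + k45 + k46), k54, k64],
                [k45, -k54, 0.0],
                [k46, 0.0, -k64],
            ]
        )
    raise ValueError(f"unknown analyte: {analyte!r}")


def terminal_half_life(ind: IndividualParameters, analyte: str) -> float:
    """Terminal elimination half-life (hours): ln 2 over the smallest-magnitude
    eigenvalue of the analyte's disposition matrix."""
    lam = np.linalg.eigvals(_disposition_matrix(ind, analyte))
    lam = np.real_if_close(lam, tol=1e6)
    if np.iscomplexobj(lam) or (lam >= 0).any():
        raise ArithmeticError("disposition eigenvalues must be real and negative")
    return float(np.log(2.0) / np.abs(lam).min())


def auc_infinity(ind: IndividualParameters, total_dose: float, analyte: str) -> float:
    """Area under the curve to infinity (h*micromol/L): F x dose / CL.

    Valid for any linear dosing history; for DEAQ the full molar dose applies
    because AQ elimination converts completely to DEAQ.
    """
    if total_dose < 0:
        raise ValueError("dose must be non-negative")
    cl = ind.cl_aq if analyte == "AQ" else ind.cl_deaq
    if analyte not in ("AQ", "DEAQ"):
        raise ValueError(f"unknown analyte: {analyte!r}")
    if cl <= 0:
        raise ZeroDivisionError("clearance must be strictly positive")
    return ind.f_aq * total_dose / cl


def auc_by_quadrature(
    ind: IndividualParameters,
    doses: Sequence[DoseEvent],
    analyte: str,
    t_end: float | None = None,
) -> float:
    """Adaptive-quadrature AUC (h*micromol/L) of the predicted profile; an
    independent check on the closed form."""
    idx = 0 if analyte == "AQ" else 1
    if t_end is None:
        t_end = max(d.time for d in doses) + 40.0 * terminal_half_life(ind, analyte)

    def f(t: float) -> float:
        return predict_profile(ind, doses, np.array([t]))[idx][0] / 1000.0

    pts = sorted({d.time for d in doses})
    total, _ = quad(f, 0.0, t_end, points=pts, limit=400)
    return total


@dataclass(frozen=True)
class ExposureSummary:
    cmax: float   # nmol/L
    tmax: float   # hours
    half_life: float  # hours
    auc: float    # h*micromol/L


def summarize_exposure(
    ind: IndividualParameters,
    doses: Sequence[DoseEvent],
    grid: Sequence[float] | None = None,
) -> dict[str, ExposureSummary]:
    """Secondary exposure parameters per analyte.

    Cmax/Tmax are read off a dense grid (default 0.25-h resolution over the
    first 72 h, then coarser out to several DEAQ half-lives); half-life and
    AUC use the analytic forms.
    """
    doses = list(doses)
    if grid is None:
        t_end = max(d.time for d in doses) + 5 * terminal_half_life(ind, "DEAQ")
        grid = np.concatenate(
            [np.arange(0.0, 72.0, 0.25), np.linspace(72.0, t_end, 400)]
        )
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    conc_aq, conc_deaq = predict_profile(ind, doses, grid)
    total_dose = sum(d.amount for d in doses if d.taken)
    out = {}
    for analyte, conc in (("AQ", conc_aq), ("DEAQ", conc_deaq)):
        i = int(np.argmax(conc))
        out[analyte] = ExposureSummary(
            cmax=float(conc[i]),
            tmax=float(grid[i]),
            half_life=terminal_half_life(ind, analyte),
            auc=auc_infinity(ind, total_dose, analyte),
        )
    return out
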