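"""Hierarchical two-compartment model of continuous-IV tacrolimus.

The structural model is a linear two-compartment system with zero-order
(infusion) input into the central compartment:

    dA1/dt = R(t) - (CL/V1) A1 - (Q/V1) A1 + (Q/V2) A2
    dA2/dt =        (Q/V1) A1 - (Q/V2) A2

with concentration C = A1/V1 (amounts in µg, volumes in L, so C is in
µg/L ≡ ng/ml).  Intercompartmental clearance and peripheral volume are tied
to CL and V1 by a fixed multiplier: Q = Fact·CL, V2 = Fact·V1.

Individual parameters combine allometric weight scaling (reference 70 kg),
a binary CYP3A4/5-inhibitor effect on clearance, a subject-level log-normal
random effect on CL and V1, and an occasion-level (per 24-h infusion bag)
log-normal effect on CL:

    CL_ij = θ_CL (WT/70)^0.75 θ_INH^INH exp(η_CL,i + κ_ij)
    V1_i  = θ_V1 (WT/70)^1    exp(η_V1,i)

Residual error is proportional: DV = IPRED·(1 + ε), ε ~ N(0, σ²).

The kinetics are solved in closed form (eigen-decomposition of the 2×2
rate matrix); numerical ODE integration is used only as a test oracle.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Sequence, Union

import numpy as np

__all__ = [
    "PopulationParameters",
    "SubjectProfile",
    "InfusionSegment",
    "IndividualParameters",
    "PKState",
    "individual_parameters",
    "propagate_state",
    "simulate_profile",
    "apply_residual_error",
]


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, variance components and structural constants.

    Defaults are the final published estimates for a 70-kg reference
    patient; ``omega_v1`` is an assumed value (the between-subject
    variability of V1 was included in the model but its magnitude was
    not reported).
    """

    theta_cl: float = 4.2       #: typical clearance at 70 kg (L/h)
    theta_v1: float = 61.9      #: typical central volume at 70 kg (L)
    theta_inh: float = 0.8      #: CL multiplier under CYP3A4/5-inhibitor co-treatment
    fact: float = 2.0           #: fixed multiplier: Q = fact·CL, V2 = fact·V1
    exp_cl: float = 0.75        #: allometric exponent on CL (theoretic value)
    exp_v: float = 1.0          #: allometric exponent on V1 (theoretic value)
    ref_weight: float = 70.0    #: reference body weight (kg)
    omega_cl: float = 0.261     #: SD of eta_CL (log scale; ≈ CV)
    omega_v1: float = 0.30      #: SD of eta_V1 (log scale; assumed)
    pi_cl: float = 0.287        #: SD of kappa (per-occasion effect on CL)
    sigma_prop: float = 0.179   #: proportional residual SD (fraction)

    def __post_init__(self) -> None:
        for name in ("theta_cl", "theta_v1", "theta_inh", "fact", "exp_cl",
                     "exp_v", "ref_weight"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("omega_cl", "omega_v1", "pi_cl", "sigma_prop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.theta_inh > 1:
            raise ValueError("theta_inh must lie in (0, 1]")

    def replace(self, **changes) -> "PopulationParameters":
        """Return a copy with the given fields replaced."""
        return _dc_replace(self, **changes)

    # percent-CV style reporting, matching the convention used for the
    # published variability figures (100 × SD of the log-scale effect)
    @property
    def iiv_cl_percent(self) -> float:
        return 100.0 * self.omega_cl

    @property
    def iiv_v1_percent(self) -> float:
        return 100.0 * self.omega_v1

    @property
    def iov_cl_percent(self) -> float:
        return 100.0 * self.pi_cl

    @property
    def sigma_percent(self) -> float:
        return 100.0 * self.sigma_prop


@dataclass(frozen=True)
class InfusionSegment:
    """Zero-order infusion: ``rate`` µg/h over [start, start+duration) h."""

    start: float
    duration: float
    rate: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("segment start must be non-negative")
        if not self.duration > 0:
            raise ValueError("segment duration must be strictly positive")
        if self.rate < 0:
            raise ValueError("segment rate must be non-negative")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class SubjectProfile:
    """Covariates, infusion regimen and occasion structure of one subject.

    ``inhibitor_schedule`` is a piecewise-constant 0/1 indicator given as
    ordered ``(time, flag)`` pairs; the flag holds from its time until the
    next entry.  ``occasion_breaks`` are the interior boundaries splitting
    the record into occasions (occasion k covers [break_{k-1}, break_k),
    with an implicit start at 0).
    """

    subject_id: Union[int, str]
    weight: float
    regimen: tuple = ()
    inhibitor_schedule: tuple = ((0.0, 0),)
    occasion_breaks: tuple = ()

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError("weight must be strictly positive")
        times = [t for t, _ in self.inhibitor_schedule]
        if times != sorted(times):
            raise ValueError("inhibitor_schedule times must be increasing")
        starts = [s.start for s in self.regimen]
        if starts != sorted(starts):
            raise ValueError("regimen segments must be ordered by start time")
        brk = list(self.occasion_breaks)
        if brk != sorted(brk) or len(set(brk)) != len(brk):
            raise ValueError("occasion_breaks must be strictly increasing")

    def inhibitor_at(self, t: float) -> int:
        flag = 0
        for time, value in self.inhibitor_schedule:
            if time <= t:
                flag = value
            else:
                break
        return int(flag)

    def occasion_of(self, t: float) -> int:
        """0-based occasion index containing time ``t``."""
        return bisect.bisect_right(self.occasion_breaks, t)

    @property
    def n_occasions(self) -> int:
        return len(self.occasion_breaks) + 1


@dataclass(frozen=True)
class IndividualParameters:
    """Realized PK parameters of one subject on one occasion."""

    cl: float   #: clearance (L/h)
    v1: float   #: central volume (L)
    q: float    #: intercompartmental clearance (L/h)
    v2: float   #: peripheral volume (L)

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class PKState:
    """Amounts in the two compartments (µg) at clock time ``t`` (h)."""

    a1: float = 0.0
    a2: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("compartment amounts must be non-negative")


def individual_parameters(
    pop: PopulationParameters,
    weight: float,
    inhibitor: int,
    eta_cl: float = 0.0,
    eta_v1: float = 0.0,
    kappa: float = 0.0,
) -> IndividualParameters:
    """Realized CL/V1/Q/V2 after covariates and random effects.

    ``inhibitor`` is the 0/1 CYP3A4/5-inhibitor co-treatment flag for the
    occasion; ``kappa`` is the occasion-level random effect on clearance.
    """
    if not weight > 0:
        raise ValueError("weight must be strictly positive")
    if inhibitor not in (0, 1):
        raise ValueError("inhibitor flag must be 0 or 1")
    wn = weight / pop.ref_weight
    cl = pop.theta_cl * wn ** pop.exp_cl * pop.theta_inh ** inhibitor \
        * np.exp(eta_cl + kappa)
    v1 = pop.theta_v1 * wn ** pop.exp_v * np.exp(eta_v1)
    return IndividualParameters(cl=cl, v1=v1, q=cl * pop.fact, v2=v1 * pop.fact)


def _advance(a1, a2, cl, v1, q, v2, rate, dt):
    """Exact update of the two-compartment amounts over a constant-rate span.

    All arguments broadcast; the 2×2 rate matrix is exponentiated in closed
    form through its (real, distinct) eigenvalues.  Returns ``(a1, a2)``.
    """
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    l1 = 0.5 * (s + disc)
    l2 = 0.5 * (s - disc)
    # steady state under constant input: A1 = R/k10, A2 = A1 k12/k21
    a1ss = rate / k10
    a2ss = a1ss * k12 / k21
    d1 = a1 - a1ss
    d2 = a2 - a2ss
    e1 = np.exp(-l1 * dt)
    e2 = np.exp(-l2 * dt)
    # expm(M t) for M = [[-(k10+k12), k21], [k12, -k21]], eigenvalues -l1, -l2
    m11 = -(k10 + k12)
    m22 = -k21
    inv = 1.0 / (l1 - l2)
    c1 = (e2 * (m11 + l1) - e1 * (m11 + l2)) * inv
    c12 = (e2 - e1) * k21 * inv
    c21 = (e2 - e1) * k12 * inv
    c2 = (e2 * (m22 + l1) - e1 * (m22 + l2)) * inv
    new_a1 = a1ss + c1 * d1 + c12 * d2
    new_a2 = a2ss + c21 * d1 + c2 * d2
    return new_a1, new_a2


def propagate_state(
    state: PKState,
    params: IndividualParameters,
    rate: float,
    dt: float,
) -> PKState:
    """Advance the system by ``dt`` hours under a constant infusion rate."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if dt == 0:
        return PKState(a1=state.a1, a2=state.a2, t=state.t)
    a1, a2 = _advance(state.a1, state.a2, params.cl, params.v1,
                      params.q, params.v2, rate, dt)
    # exact solution can round to tiny negatives near zero
    return PKState(a1=max(float(a1), 0.0), a2=max(float(a2), 0.0),
                   t=state.t + dt)


def simulate_profile(
    subject: SubjectProfile,
    indiv: Union[IndividualParameters, Sequence[IndividualParameters]],
    times: Sequence[float],
) -> np.ndarray:
    """Noise-free (IPRED) concentrations (ng/ml) at the requested times.

    ``indiv`` is either a single parameter set or one per occasion (as
    delimited by ``subject.occasion_breaks``).  Overlapping infusion
    segments superpose (rates add).  Times before the first dose return 0.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    if isinstance(indiv, IndividualParameters):
        per_occ = [indiv] * subject.n_occasions
    else:
        per_occ = list(indiv)
        if len(per_occ) != subject.n_occasions:
            raise ValueError(
                f"expected {subject.n_occasions} parameter sets "
                f"(one per occasion), got {len(per_occ)}")
    if times.size == 0:
        return np.empty(0)

    t_end = float(times[-1])
    knots = {0.0}
    for seg in subject.regimen:
        if seg.start < t_end:
            knots.add(seg.start)
        if seg.end < t_end:
            knots.add(seg.end)
    for b in subject.occasion_breaks:
        if 0.0 < b < t_end:
            knots.add(b)
    knots.update(float(t) for t in times if t >= 0.0)
    grid = sorted(knots)

    conc = {}
    a1 = a2 = 0.0
    for t0, t1 in zip(grid, grid[1:] + [None]):
        p = per_occ[subject.occasion_of(t0)]
        conc[t0] = a1 / p.v1
        if t1 is None:
            break
        rate = sum(s.rate for s in subject.regimen if s.start <= t0 < s.end)
        a1, a2 = _advance(a1, a2, p.cl, p.v1, p.q, p.v2, rate, t1 - t0)
    out = np.array([conc[float(t)] if t >= 0.0 else 0.0 for t in times])
    return np.maximum(out, 0.0)


def apply_residual_error(ipred, sigma_prop: float, rng: np.random.Generator):
    """Observed concentration with proportional error, floored at zero.

    DV = IPRED·(1 + ε) with ε ~ N(0, σ²).  Accepts scalars or arrays.
    """
    ipred = np.asarray(ipred, dtype=float)
    if np.any(ipred < 0):
        raise ValueError("ipred must be non-negative")
    if sigma_prop < 0:
        raise ValueError("sigma_prop must be non-negative")
    eps = rng.normal(0.0, sigma_prop, size=ipred.shape) if sigma_prop > 0 \
        else np.zeros(ipred.shape)
    dv = ipred * (1.0 + eps)
    dv = np.maximum(dv, 0.0)
    return float(dv) if dv.ndim == 0 else dv
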