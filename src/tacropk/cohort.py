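"""Virtual study cohorts with the trial's design and statistical structure.

The generator emulates the clinical protocol the model was built from:
continuous IV infusion in 24-h bags, a starting rate of 1.25 µg/kg/h,
one steady-state trough drawn 15 min before each next bag, titration of
the rate toward the 7–10 ng/ml window, and CYP3A4/5-inhibitor co-treatment
on ~11.7% of samples.  Subject weights follow a truncated log-normal
centred on the study median (23.9 kg, range 5.5–155.5 kg).

Random draws per subject follow a fixed order for reproducibility:
weight and inhibitor episode in :func:`sample_subjects`; then in
:func:`simulate_trial` η_CL, η_V1, the per-occasion κ vector, and finally
one residual ε per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import COLUMNS, PKEventDataset
from .model import (
    InfusionSegment,
    PopulationParameters,
    SubjectProfile,
    _advance,
    individual_parameters,
)

__all__ = ["CohortDesign", "sample_subjects", "simulate_trial", "generate_cohort"]

#: trough draw time within each 24-h bag (15 min before the next bag)
TROUGH_OFFSET = 0.25


@dataclass(frozen=True)
class CohortDesign:
    """Study-design knobs of the virtual trial (defaults = study conditions)."""

    n_subjects: int = 111
    weight_median: float = 23.9       #: kg
    weight_min: float = 5.5           #: kg
    weight_max: float = 155.5         #: kg
    weight_log_sd: float = 0.7        #: SD of log-weight before truncation
    start_rate_per_kg: float = 1.25   #: µg/kg/h
    target_low: float = 7.0           #: ng/ml
    target_high: float = 10.0         #: ng/ml
    n_days: int = 14
    inhibitor_sample_fraction: float = 0.117
    titrate: bool = True
    titration_cap: float = 0.5        #: max fractional rate change per day
    min_rate_per_kg: float = 0.1      #: µg/kg/h floor
    initial_dosing: str = "per_kg"    #: "per_kg" or "model" (typical-CL based)
    dropout_day: Optional[int] = None  #: geometric censoring after this day (off by default)
    dropout_p: float = 0.15
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (self.weight_min < self.weight_median < self.weight_max):
            raise ValueError("need weight_min < weight_median < weight_max")
        if not self.target_low < self.target_high:
            raise ValueError("need target_low < target_high")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0 <= self.inhibitor_sample_fraction < 1:
            raise ValueError("inhibitor_sample_fraction must be in [0, 1)")
        if self.initial_dosing not in ("per_kg", "model"):
            raise ValueError("initial_dosing must be 'per_kg' or 'model'")

    def replace(self, **changes) -> "CohortDesign":
        return _dc_replace(self, **changes)


def _inhibitor_subject_probability(design: CohortDesign) -> float:
    # Episodes run from a uniform start day through the end of the record,
    # so a flagged subject covers (n_days+1)/(2 n_days) of days in
    # expectation; solve for the subject-level probability that makes the
    # expected fraction of INH=1 samples equal the design fraction.
    expected_cover = (design.n_days + 1) / (2.0 * design.n_days)
    return min(1.0, design.inhibitor_sample_fraction / expected_cover)


def sample_subjects(design: CohortDesign, rng: np.random.Generator) -> list:
    """Draw subject profiles: weights, inhibitor episodes, initial regimen."""
    p_inh = _inhibitor_subject_probability(design)
    mu = math.log(design.weight_median)
    subjects = []
    for i in range(design.n_subjects):
        while True:  # truncation by rejection
            wt = float(np.exp(rng.normal(mu, design.weight_log_sd)))
            if design.weight_min <= wt <= design.weight_max:
                break
        schedule = ((0.0, 0),)
        if p_inh > 0 and rng.random() < p_inh:
            start_day = int(rng.integers(1, design.n_days + 1))
            if start_day == 1:
                schedule = ((0.0, 1),)
            else:
                schedule = ((0.0, 0), (24.0 * (start_day - 1), 1))
        rate0 = design.start_rate_per_kg * wt
        regimen = tuple(InfusionSegment(24.0 * j, 24.0, rate0)
                        for j in range(design.n_days))
        breaks = tuple(24.0 * j for j in range(1, design.n_days))
        subjects.append(SubjectProfile(
            subject_id=i + 1, weight=wt, regimen=regimen,
            inhibitor_schedule=schedule, occasion_breaks=breaks))
    return subjects


def _titrated_rate(rate: float, dv: float, design: CohortDesign,
                   weight: float) -> float:
    """Daily rate adjustment toward the mid-target, mimicking clinical TDM."""
    mid = 0.5 * (design.target_low + design.target_high)
    if design.target_low <= dv <= design.target_high:
        return rate
    factor = mid / max(dv, 1e-6)
    factor = min(max(factor, 1.0 - design.titration_cap),
                 1.0 + design.titration_cap)
    return max(rate * factor, design.min_rate_per_kg * weight)


def simulate_trial(
    subjects: Sequence[SubjectProfile],
    pop: PopulationParameters,
    design: CohortDesign,
    rng: np.random.Generator,
    return_effects: bool = False,
) -> PKEventDataset:
    """Simulate the virtual trial and return the event dataset.

    Each subject starts at the design starting rate (weight-based or
    model-based typical rate), a trough is drawn 15 min before each next
    bag with proportional residual error, and the next bag's rate is
    titrated toward the target window.  With ``return_effects`` the
    realized random effects are returned alongside the dataset
    (subject id → (η_CL, η_V1, κ-vector)).
    """
    if not subjects:
        raise ValueError("subjects must be non-empty")
    rows = []
    effects = {}
    for subj in subjects:
        eta_cl = rng.normal(0.0, pop.omega_cl) if pop.omega_cl > 0 else 0.0
        eta_v1 = rng.normal(0.0, pop.omega_v1) if pop.omega_v1 > 0 else 0.0
        kappas = (rng.normal(0.0, pop.pi_cl, size=design.n_days)
                  if pop.pi_cl > 0 else np.zeros(design.n_days))
        effects[subj.subject_id] = (eta_cl, eta_v1, kappas.copy())
        n_days = design.n_days
        if design.dropout_day is not None:
            extra = rng.geometric(design.dropout_p)
            n_days = min(design.n_days, design.dropout_day + extra - 1)

        if design.initial_dosing == "model":
            inh0 = subj.inhibitor_at(0.0)
            cl_typ = individual_parameters(pop, subj.weight, inh0).cl
            mid = 0.5 * (design.target_low + design.target_high)
            rate = mid * cl_typ
        else:
            rate = design.start_rate_per_kg * subj.weight
        a1 = a2 = 0.0
        for j in range(1, n_days + 1):
            t_dose = 24.0 * (j - 1)
            inh = subj.inhibitor_at(t_dose)
            p = individual_parameters(pop, subj.weight, inh,
                                      eta_cl, eta_v1, kappas[j - 1])
            rows.append((subj.subject_id, t_dose, 1, rate * 24.0, rate,
                         np.nan, 1, subj.weight, inh, j))
            a1, a2 = _advance(a1, a2, p.cl, p.v1, p.q, p.v2, rate,
                              24.0 - TROUGH_OFFSET)
            ipred = a1 / p.v1
            eps = rng.normal(0.0, pop.sigma_prop) if pop.sigma_prop > 0 else 0.0
            dv = max(ipred * (1.0 + eps), 0.0)
            rows.append((subj.subject_id, 24.0 * j - TROUGH_OFFSET, 0,
                         np.nan, np.nan, dv, 0, subj.weight, inh, j))
            a1, a2 = _advance(a1, a2, p.cl, p.v1, p.q, p.v2, rate,
                              TROUGH_OFFSET)
            if design.titrate:
                rate = _titrated_rate(rate, dv, design, subj.weight)
    frame = pd.DataFrame(rows, columns=COLUMNS)
    dataset = PKEventDataset(frame)
    return (dataset, effects) if return_effects else dataset


def generate_cohort(
    design: CohortDesign,
    pop: Optional[PopulationParameters] = None,
    rng: Optional[np.random.Generator] = None,
) -> PKEventDataset:
    """Convenience wrapper: sample subjects and simulate the trial."""
    if pop is None:
        pop = PopulationParameters()
    if rng is None:
        rng = np.random.default_rng(design.seed)
    subjects = sample_subjects(design, rng)
    return simulate_trial(subjects, pop, design, rng)
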