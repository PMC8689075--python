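"""Model-based dosing: typical starting rates and MAP-individualized rates.

At steady state under a continuous infusion the trough equals rate/CL,
so the model-based starting rate for a target trough is simply
target × CL_typical(weight, inhibitor).  After one or more measured
troughs, the subject's random effects are estimated by MAP and the
constant rate whose predicted concentration hits the target at the
forecast horizon is found by bisection (the concentration at any time is
monotone increasing in the rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .data import PKEventDataset
from .estimation import BAG_HOURS, build_panel, map_estimate
from .model import (
    IndividualParameters,
    PopulationParameters,
    _advance,
    individual_parameters,
)

__all__ = ["DoseRecommendation", "initial_rate", "adaptive_rate"]

DEFAULT_TARGET = 8.5  #: ng/ml, midpoint of the 7-10 therapeutic window


@dataclass(frozen=True)
class DoseRecommendation:
    """A recommended continuous-infusion rate and its predicted outcome."""

    rate: float                 #: µg/h
    rate_per_kg: float          #: µg/kg/h
    rate_per_kg_rounded: float  #: µg/kg/h at 0.01 pump granularity
    predicted_trough: float     #: ng/ml at the forecast horizon
    target: Tuple[float, float]  #: (low, high) ng/ml
    basis: str                  #: "typical" or "MAP"


def initial_rate(
    pop: PopulationParameters,
    weight: float,
    inhibitor: int = 0,
    target_trough: float = DEFAULT_TARGET,
    target_window: Tuple[float, float] = (7.0, 10.0),
) -> DoseRecommendation:
    """Model-based starting rate from the typical clearance.

    Uses the steady-state identity trough = rate/CL; no individual
    information beyond weight and inhibitor status is used.
    """
    if not weight > 0:
        raise ValueError("weight must be strictly positive")
    if target_trough < 0:
        raise ValueError("target trough must be non-negative")
    cl = individual_parameters(pop, weight, inhibitor).cl
    rate = target_trough * cl
    per_kg = rate / weight
    return DoseRecommendation(
        rate=rate, rate_per_kg=per_kg,
        rate_per_kg_rounded=round(per_kg, 2),
        predicted_trough=target_trough, target=target_window,
        basis="typical")


def _forecast(panel, params_by_day, future_params: IndividualParameters,
              rate_future: float, horizon: float) -> float:
    """Concentration ``horizon`` hours after the recorded dosing history."""
    a1 = a2 = 0.0
    for j in range(panel.n_days):
        if not panel.day_mask[0, j]:
            break
        p = params_by_day[j]
        a1, a2 = _advance(a1, a2, p.cl, p.v1, p.q, p.v2,
                          panel.rate[0, j], BAG_HOURS)
    p = future_params
    a1, a2 = _advance(a1, a2, p.cl, p.v1, p.q, p.v2, rate_future, horizon)
    return float(a1 / p.v1)


def adaptive_rate(
    subject_data: PKEventDataset,
    pop: PopulationParameters,
    target_trough: float = DEFAULT_TARGET,
    horizon: float = BAG_HOURS,
    target_window: Tuple[float, float] = (7.0, 10.0),
) -> DoseRecommendation:
    """MAP-individualized constant rate hitting the target at the horizon.

    The subject's effects are estimated from the observed troughs, the
    current amounts are propagated through the recorded dosing history,
    and the constant rate applied from the end of the history is solved
    so the predicted concentration ``horizon`` hours later equals the
    target.  κ for the not-yet-observed future occasion is 0 (prior
    mode); the inhibitor status of the last recorded bag carries forward.
    """
    if horizon <= 0:
        raise ValueError("horizon must be after the end of the dosing history")
    panel = build_panel(subject_data)
    if len(panel.ids) != 1:
        raise ValueError("adaptive_rate expects a single-subject dataset")
    if panel.n_obs < 1:
        raise ValueError("at least one observed trough is required")
    eta_cl, eta_v1, kappas = map_estimate(subject_data, pop)
    wt = float(panel.wt[0])
    n_days = int(panel.day_mask[0].sum())
    params_by_day = [
        individual_parameters(pop, wt, int(panel.inh[0, j]),
                              eta_cl, eta_v1, float(kappas[j]))
        for j in range(n_days)]
    future = individual_parameters(pop, wt, int(panel.inh[0, n_days - 1]),
                                   eta_cl, eta_v1, 0.0)

    def conc_at(rate):
        return _forecast(panel, params_by_day, future, rate, horizon)

    lo, hi = 0.0, max(target_trough * future.cl, 1e-6)
    for _ in range(60):
        if conc_at(hi) >= target_trough:
            break
        hi *= 2.0
    else:
        raise RuntimeError("target trough unreachable within rate bracket")
    if conc_at(lo) > target_trough:
        rate = 0.0  # accumulated drug alone exceeds the target at horizon
    else:
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if conc_at(mid) < target_trough:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-9 * max(1.0, hi):
                break
        rate = 0.5 * (lo + hi)
    per_kg = rate / wt
    return DoseRecommendation(
        rate=rate, rate_per_kg=per_kg,
        rate_per_kg_rounded=round(per_kg, 2),
        predicted_trough=conc_at(rate), target=target_window,
        basis="MAP")
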