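"""Run configuration: population parameters, cohort design, estimation settings.

The configuration file is a single YAML document with up to four keys::

    seed: 42
    population:      # any PopulationParameters field, e.g.
      theta_cl: 4.2
      omega_v1: 0.30
    design:          # any CohortDesign field, e.g.
      n_subjects: 111
      n_days: 14
    estimation:      # any EstimationSettings field, e.g.
      maxiter: 4000
      method: quad

Unset fields fall back to the package defaults (the published model and
the study design).  Command-line flags override file values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .cohort import CohortDesign
from .model import PopulationParameters

__all__ = ["EstimationSettings", "RunConfig", "load_config", "save_config",
           "setup_logging"]

logger = logging.getLogger("tacropk")


@dataclass(frozen=True)
class EstimationSettings:
    """Knobs of the population fit and covariate search."""

    maxiter: int = 4000          #: outer Nelder-Mead evaluation budget
    fatol: float = 1e-3          #: outer OFV tolerance
    xatol: float = 1e-4          #: outer parameter tolerance (log scale)
    inner_tol: float = 1e-6      #: inner gradient tolerance
    method: str = "quad"         #: marginal-likelihood approximation
    forward_dofv: float = 3.58   #: forward-inclusion ΔOFV threshold
    backward_dofv: float = 6.63  #: backward-elimination ΔOFV threshold


@dataclass(frozen=True)
class RunConfig:
    population: PopulationParameters = field(default_factory=PopulationParameters)
    design: CohortDesign = field(default_factory=CohortDesign)
    estimation: EstimationSettings = field(default_factory=EstimationSettings)
    seed: Optional[int] = None


def _build(cls, section: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**section)


def load_config(path) -> RunConfig:
    """Read a YAML configuration file (missing sections use defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"configuration root must be a mapping: {path}")
    return RunConfig(
        population=_build(PopulationParameters, raw.get("population", {}) or {}),
        design=_build(CohortDesign, raw.get("design", {}) or {}),
        estimation=_build(EstimationSettings, raw.get("estimation", {}) or {}),
        seed=raw.get("seed"),
    )


def save_config(config: RunConfig, path) -> None:
    doc = {
        "seed": config.seed,
        "population": dataclasses.asdict(config.population),
        "design": dataclasses.asdict(config.design),
        "estimation": dataclasses.asdict(config.estimation),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def setup_logging(log_file=None, verbose: bool = False) -> None:
    """Console (and optional file) logging for the command-line tools."""
    root = logging.getLogger("tacropk")
    root.setLevel(logging.DEBUG)
    root.handlers.clear()
    console = logging.StreamHandler()
    console.setLevel(logging.DEBUG if verbose else logging.INFO)
    console.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    root.addHandler(console)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setLevel(logging.DEBUG)
        fh.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        root.addHandler(fh)
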