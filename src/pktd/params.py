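"""Parameter containers for the oxaliplatin PK-TD model.

Units follow the rat study conventions throughout:

* doses are IV boluses in micrograms per kg body weight (3 mg/kg == 3000 ug/kg),
* plasma concentration is ug/mL, so the central volume ``V`` is in mL/kg,
* PK micro rate constants (``ke``, ``k12``, ``k21``) are per *hour*,
* toxicodynamic rate constants are per *day*; regimen and observation times are
  in days since the first dose.

The hour/day bridge is applied once, at simulation time (rates x 24), so that
the coupled system always integrates on a single day-scale clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterable, Mapping

import yaml

HOURS_PER_DAY = 24.0

__all__ = [
    "DoseEvent",
    "Regimen",
    "PKParams",
    "MacroPK",
    "AcuteTDParams",
    "ChronicTDParams",
    "PopulationModel",
    "StudyDesign",
    "load_preset",
    "available_presets",
    "HOURS_PER_DAY",
]


def _require_positive(obj, names: Iterable[str]) -> None:
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class DoseEvent:
    """A single IV bolus into the central compartment.

    ``time`` is days since the first dose; ``amount`` is ug per kg body weight.
    """

    time: float
    amount: float

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")


@dataclass(frozen=True)
class Regimen:
    """An ordered sequence of bolus dose events plus a simulation horizon (days)."""

    events: tuple[DoseEvent, ...]
    horizon: float

    def __post_init__(self):
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        times = [e.time for e in events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose events must be sorted ascending by time")
        if events and self.horizon < times[-1]:
            raise ValueError(
                f"horizon {self.horizon} d precedes last dose at {times[-1]} d"
            )
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @property
    def dose_times(self) -> tuple[float, ...]:
        return tuple(e.time for e in self.events)

    @property
    def is_placebo(self) -> bool:
        return all(e.amount == 0 for e in self.events)

    @classmethod
    def single_dose(cls, amount_ug_per_kg: float, horizon: float = 1.0) -> "Regimen":
        return cls((DoseEvent(0.0, amount_ug_per_kg),), horizon)

    @classmethod
    def placebo(cls, horizon: float = 28.0) -> "Regimen":
        return cls((), horizon)


@dataclass(frozen=True)
class PKParams:
    """Two-compartment disposition parameters (micro constants, per hour)."""

    V: float      # central volume, mL/kg
    ke: float     # elimination from central, 1/h
    k12: float    # central -> peripheral, 1/h
    k21: float    # peripheral -> central, 1/h

    def __post_init__(self):
        _require_positive(self, ("V", "ke", "k12", "k21"))

    def with_etas(self, etas: Mapping[str, float]) -> "PKParams":
        import math

        return replace(
            self, **{k: getattr(self, k) * math.exp(v) for k, v in etas.items()}
        )


@dataclass(frozen=True)
class MacroPK:
    """Hybrid (macro) constants of the bi-exponential bolus solution.

    Unit-dose concentration is ``cA * exp(-alpha t) + cB * exp(-beta t)`` with
    ``cA``, ``cB`` in kg/mL (so multiplying by a ug/kg dose gives ug/mL);
    ``alpha > beta`` share the time unit of the micro constants they came from.
    """

    alpha: float
    beta: float
    cA: float
    cB: float

    def __post_init__(self):
        if not (self.alpha > self.beta > 0):
            raise ValueError("require alpha > beta > 0")


@dataclass(frozen=True)
class AcuteTDParams:
    """Acute (cold allodynia, acetone test) turnover-model parameters.

    The observable is baseline habituation plus a drug-driven response:
    ``x_acute(t) = Response(t) + x0 * exp(-k_handling * t)`` where Response
    follows an indirect-response equation stimulated by a sigmoid-Emax
    (Hill) function of plasma concentration.
    """

    kin_acute: float            # zero-order production, times/day
    kout_acute: float           # first-order loss, 1/day
    Emax_acute: float           # maximum drug effect, times/day
    EC50_acute: float           # half-maximal concentration, ug/mL
    x0_acute: float = 3.1       # baseline score, fixed in the final model
    k_handling: float = 0.08    # habituation decay, 1/day, fixed
    gamma_acute: float = 6.0    # Hill coefficient, fixed

    def __post_init__(self):
        _require_positive(
            self,
            ("kin_acute", "kout_acute", "EC50_acute",
             "x0_acute", "k_handling", "gamma_acute"),
        )
        if self.Emax_acute < 0:   # 0 = drug effect switched off
            raise ValueError("Emax_acute must be >= 0")
        if self.gamma_acute < 1:
            raise ValueError("gamma_acute must be >= 1")


@dataclass(frozen=True)
class ChronicTDParams:
    """Chronic (mechanical allodynia, von Frey test) transit-chain parameters.

    A five-stage transit compartment chain delays the inhibitory drug effect;
    the loss rate is tied to the baseline by ``kout = kin / x0`` so that the
    drug-free system rests exactly at the control threshold ``x0``.
    """

    kin_chronic: float           # zero-order production, g/day
    Emax_chronic: float          # maximum fractional inhibition (dimensionless)
    EC50_chronic: float          # half-maximal concentration, ug/mL
    x0_chronic: float = 8.0      # baseline threshold, g, fixed
    n_transit: int = 5           # pre-output stages, fixed
    gamma_chronic: float = 4.0   # Hill coefficient, fixed

    def __post_init__(self):
        _require_positive(
            self,
            ("kin_chronic", "EC50_chronic", "x0_chronic", "gamma_chronic"),
        )
        if self.Emax_chronic < 0:   # 0 = drug effect switched off
            raise ValueError("Emax_chronic must be >= 0")
        if self.n_transit < 1:
            raise ValueError("n_transit must be >= 1")

    @property
    def kout_chronic(self) -> float:
        """Derived first-order loss rate (1/day); never a free parameter."""
        return self.kin_chronic / self.x0_chronic

    def with_etas(self, etas: Mapping[str, float]) -> "ChronicTDParams":
        import math

        return replace(
            self, **{k: getattr(self, k) * math.exp(v) for k, v in etas.items()}
        )


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects + between-animal variability + residual error.

    ``omega`` maps parameter names (fields of the fixed-effect containers) to
    inter-individual %CV of an exponential (lognormal) random effect.  The
    acute model carries no random effects.  Residual error is proportional for
    plasma concentration and acetone score, additive (grams) for the von Frey
    threshold.
    """

    pk: PKParams
    acute: AcuteTDParams
    chronic: ChronicTDParams
    omega: Mapping[str, float] = field(default_factory=dict)   # name -> %CV
    sigma_pk_prop: float = 0.0
    sigma_acute_prop: float = 0.0
    sigma_chronic_add: float = 0.0
    omega_parameterization: str = "cv_approx"  # or "lognormal_exact"

    _PK_OMEGA = ("V", "ke", "k12", "k21")
    _CHRONIC_OMEGA = ("kin_chronic", "EC50_chronic")

    def __post_init__(self):
        allowed = set(self._PK_OMEGA) | set(self._CHRONIC_OMEGA)
        for name, cv in self.omega.items():
            if name not in allowed:
                raise ValueError(
                    f"random effect on {name!r} not supported; allowed: {sorted(allowed)}"
                )
            if cv < 0:
                raise ValueError(f"omega[{name!r}] must be >= 0")
        for name in ("sigma_pk_prop", "sigma_acute_prop", "sigma_chronic_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.omega_parameterization not in ("cv_approx", "lognormal_exact"):
            raise ValueError("omega_parameterization must be cv_approx|lognormal_exact")

    def omega_sd(self, name: str) -> float:
        """SD of the log-scale random effect eta for parameter ``name``."""
        import math

        cv = self.omega.get(name, 0.0) / 100.0
        if self.omega_parameterization == "cv_approx":
            return cv
        return math.sqrt(math.log(1.0 + cv * cv))


@dataclass(frozen=True)
class StudyDesign:
    """The rat study layout emulated by the synthetic-cohort generator."""

    pk_n_per_group: int = 5
    pk_doses_mg_per_kg: tuple[float, ...] = (3.0, 5.0, 8.0)
    pk_sample_times_min: tuple[float, ...] = (3, 5, 10, 20, 30, 45, 60, 90, 120)
    td_groups: tuple[float, ...] = (0.0, 3.0, 5.0, 8.0)   # 0 == saline control
    td_n_per_group: tuple[int, ...] = (6, 5, 5, 5)
    td_dose_days: tuple[float, ...] = (0.0, 7.0, 14.0, 21.0)
    td_observation_days: tuple[float, ...] = (2, 4, 7, 9, 11, 14, 16, 18, 21, 23, 25, 28)
    horizon: float = 28.0

    def __post_init__(self):
        t = self.pk_sample_times_min
        if any(x <= 0 for x in t) or list(t) != sorted(t):
            raise ValueError("PK sample times must be positive and sorted")
        if len(self.td_groups) != len(self.td_n_per_group):
            raise ValueError("td_groups and td_n_per_group lengths differ")
        if max(self.td_observation_days) > self.horizon:
            raise ValueError("observation days must lie within the horizon")

    @property
    def pk_sample_times_days(self) -> tuple[float, ...]:
        return tuple(t / 60.0 / HOURS_PER_DAY for t in self.pk_sample_times_min)


# ---------------------------------------------------------------------------
# presets


def _preset_store() -> dict:
    text = resources.files("pktd").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> tuple[str, ...]:
    return tuple(_preset_store().keys())


def load_preset(name: str = "reference") -> PopulationModel:
    """Load a named parameter preset as a :class:`PopulationModel`.

    The ``reference`` preset holds the final population estimates of the rat
    study (fixed effects, %CV omegas, residual errors).
    """
    store = _preset_store()
    if name not in store:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(store)}")
    cfg = store[name]
    return PopulationModel(
        pk=PKParams(**cfg["pk"]),
        acute=AcuteTDParams(**cfg["acute"]),
        chronic=ChronicTDParams(**cfg["chronic"]),
        omega=dict(cfg.get("omega", {})),
        sigma_pk_prop=cfg.get("sigma_pk_prop", 0.0),
        sigma_acute_prop=cfg.get("sigma_acute_prop", 0.0),
        sigma_chronic_add=cfg.get("sigma_chronic_add", 0.0),
    )
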