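"""Dosing-schedule scenario simulations.

Reproduces the model-based what-if experiments: acetone score and von Frey
threshold after placebo or 1-8 mg/kg given weekly for four weeks, and after
5 mg/kg given every one, two or three weeks (washout comparison), all at the
final fixed-effect parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    AcuteTDParams,
    ChronicTDParams,
    DoseEvent,
    PKParams,
    PopulationModel,
    Regimen,
)
from .trajectories import simulate_acute, simulate_chronic

__all__ = [
    "ScenarioSpec",
    "build_regimen",
    "run_scenarios",
    "dose_sweep_scenarios",
    "interval_sweep_scenarios",
    "plot_scenarios",
]

_DEFAULT_ENDPOINTS = ("acetone_score", "vonfrey_threshold")


@dataclass(frozen=True)
class ScenarioSpec:
    """One dosing scenario: per-administration dose and administration days."""

    label: str
    dose_mg_per_kg: float
    dose_days: tuple[float, ...]
    horizon: float = 28.0
    endpoints: tuple[str, ...] = _DEFAULT_ENDPOINTS

    def __post_init__(self):
        if self.dose_mg_per_kg < 0:
            raise ValueError("dose must be >= 0")
        if any(d < 0 or d > self.horizon for d in self.dose_days):
            raise ValueError("dose days must lie within [0, horizon]")
        if len(set(self.dose_days)) != len(self.dose_days):
            raise ValueError(f"duplicate dose days in scenario {self.label!r}")


def build_regimen(spec: ScenarioSpec) -> Regimen:
    """One IV bolus of ``dose * 1000`` ug/kg per dose day (empty for placebo)."""
    if spec.dose_mg_per_kg == 0:
        return Regimen((), spec.horizon)
    events = tuple(
        DoseEvent(day, spec.dose_mg_per_kg * 1000.0)
        for day in sorted(spec.dose_days)
    )
    return Regimen(events, spec.horizon)


def dose_sweep_scenarios(doses=(0, 1, 2, 3, 4, 5, 6, 7, 8),
                         horizon: float = 28.0) -> list[ScenarioSpec]:
    """Placebo + weekly x4 administration of each dose (mg/kg)."""
    return [
        ScenarioSpec(
            label="placebo" if d == 0 else f"{d:g} mg/kg q1w",
            dose_mg_per_kg=float(d),
            dose_days=(0.0, 7.0, 14.0, 21.0),
            horizon=horizon,
        )
        for d in doses
    ]


def interval_sweep_scenarios(dose: float = 5.0,
                             horizon: float = 28.0) -> list[ScenarioSpec]:
    """5 mg/kg weekly vs two-week (days 0, 14) vs three-week (days 0, 21)."""
    return [
        ScenarioSpec(f"{dose:g} mg/kg q1w", dose, (0.0, 7.0, 14.0, 21.0), horizon),
        ScenarioSpec(f"{dose:g} mg/kg q2w", dose, (0.0, 14.0), horizon),
        ScenarioSpec(f"{dose:g} mg/kg q3w", dose, (0.0, 21.0), horizon),
    ]


def run_scenarios(specs, pk: PKParams, acute: AcuteTDParams,
                  chronic: ChronicTDParams, grid=None,
                  clamp_nonnegative: bool = False) -> pd.DataFrame:
    """Deterministic (fixed-effects-only) trajectories, tidy format.

    Returns a DataFrame with columns scenario, endpoint, time_days, value.
    The default grid is 0.05-day spacing over each scenario's horizon, dense
    enough to capture the hours-scale post-dose transient.
    """
    frames = []
    for spec in specs:
        regimen = build_regimen(spec)
        t = (np.asarray(grid, dtype=float) if grid is not None
             else np.arange(0.0, spec.horizon + 1e-9, 0.05))
        for endpoint in spec.endpoints:
            if endpoint == "acetone_score":
                tr = simulate_acute(acute, pk, regimen, t)
            elif endpoint == "vonfrey_threshold":
                tr = simulate_chronic(chronic, pk, regimen, t,
                                      clamp_nonnegative=clamp_nonnegative)
            else:
                raise ValueError(f"unknown scenario endpoint {endpoint!r}")
            frames.append(pd.DataFrame({
                "scenario": spec.label,
                "endpoint": endpoint,
                "time_days": tr.times,
                "value": tr.values,
            }))
    return pd.concat(frames, ignore_index=True)


def run_default_scenarios(pop: PopulationModel, **kwargs) -> pd.DataFrame:
    """Dose sweep plus washout-interval sweep at the preset fixed effects."""
    specs, seen = [], set()
    for spec in dose_sweep_scenarios() + interval_sweep_scenarios():
        if spec.label not in seen:  # 5 mg/kg q1w appears in both sweeps
            specs.append(spec)
            seen.add(spec.label)
    return run_scenarios(specs, pop.pk, pop.acute, pop.chronic, **kwargs)


def plot_scenarios(table: pd.DataFrame, endpoint: str, ax=None):
    """Line plot of one endpoint across scenarios (matplotlib Axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 4))
    sub = table[table["endpoint"] == endpoint]
    for label, g in sub.groupby("scenario", sort=False):
        ax.plot(g["time_days"], g["value"], label=label)
    ylabels = {
        "acetone_score": "paw withdrawal responses (times)",
        "vonfrey_threshold": "paw withdrawal threshold (g)",
    }
    ax.set_xlabel("time (days)")
    ax.set_ylabel(ylabels.get(endpoint, endpoint))
    ax.legend(fontsize=8)
    return ax
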