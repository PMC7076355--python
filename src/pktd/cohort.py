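"""Synthetic rat cohorts with the statistical structure of the source study.

No raw animal data are deposited, so every estimation and evaluation routine
in this package is exercised on virtual cohorts drawn from a
:class:`~pktd.params.PopulationModel`:

* PK arm: 15 rats, 3 dose groups (3/5/8 mg/kg single IV bolus), plasma
  sampled at 3-120 min; exponential inter-individual variability on
  V/ke/k12/k21; proportional residual error.
* TD arm: 21 distinct rats, saline control + 3 weekly-dosed groups over 4
  weeks, acetone score and von Frey threshold observed 3 days/week;
  exponential variability on kin_chronic and EC50_chronic (the acute model
  carries no random effects); proportional (acetone) and additive (von Frey)
  residual error.

Random streams are keyed per arm and per rat through ``SeedSequence``, with
separate children for parameter draws and residual draws, so enlarging one
arm never perturbs the other and the same seed reproduces tables bit for bit.
Negative simulated observations (possible under either error model) are kept
by default; truncating them would bias estimator-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import PopulationModel, Regimen, DoseEvent, StudyDesign
from .trajectories import ENDPOINTS, pk_concentration, simulate_acute, simulate_chronic

__all__ = [
    "ObservationTable",
    "draw_individual",
    "generate_pk_cohort",
    "generate_td_cohort",
    "regimen_for_group",
]

OBS_COLUMNS = ["subject_id", "group", "endpoint", "time_days", "value"]
DOSE_COLUMNS = ["subject_id", "time_days", "amount_ug_per_kg"]

_PK_ARM, _TD_ARM = 0, 1


@dataclass(frozen=True)
class ObservationTable:
    """Long-format multi-endpoint observations plus companion dose events.

    ``observations`` columns: subject_id, group (dose in mg/kg, 0 = control),
    endpoint, time_days, value.  ``doses`` columns: subject_id, time_days,
    amount_ug_per_kg.  The table is the unit of exchange between the
    generator, the estimators and the evaluation toolkit.
    """

    observations: pd.DataFrame
    doses: pd.DataFrame

    def __post_init__(self):
        obs = self.observations.reset_index(drop=True)
        doses = self.doses.reset_index(drop=True)
        for col in OBS_COLUMNS:
            if col not in obs.columns:
                raise ValueError(f"observations missing column {col!r}")
        for col in DOSE_COLUMNS:
            if col not in doses.columns:
                raise ValueError(f"doses missing column {col!r}")
        bad = set(obs["endpoint"]) - set(ENDPOINTS)
        if bad:
            raise ValueError(f"unknown endpoint codes {sorted(bad)}")
        if obs["value"].isna().any() or obs["time_days"].isna().any():
            raise ValueError("missing values are not allowed")
        for (sid, ep), g in obs.groupby(["subject_id", "endpoint"], sort=False):
            t = g["time_days"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValueError(f"unsorted times for subject {sid!r}/{ep}")
        object.__setattr__(self, "observations", obs[OBS_COLUMNS])
        object.__setattr__(self, "doses", doses[DOSE_COLUMNS])

    # -- convenience -------------------------------------------------------

    @property
    def subjects(self) -> tuple:
        return tuple(self.observations["subject_id"].unique())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def endpoint(self, name: str) -> "ObservationTable":
        if name not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {name!r}")
        obs = self.observations[self.observations["endpoint"] == name]
        keep = obs["subject_id"].unique()
        return ObservationTable(obs, self.doses[self.doses["subject_id"].isin(keep)])

    def rows_for(self, subject_id) -> pd.DataFrame:
        return self.observations[self.observations["subject_id"] == subject_id]

    def regimen_for(self, subject_id, horizon: float | None = None) -> Regimen:
        d = self.doses[self.doses["subject_id"] == subject_id]
        d = d[d["amount_ug_per_kg"] > 0].sort_values("time_days")
        events = tuple(
            DoseEvent(t, a) for t, a in zip(d["time_days"], d["amount_ug_per_kg"])
        )
        if horizon is None:
            t_obs = self.rows_for(subject_id)["time_days"]
            horizon = max(
                float(t_obs.max()) if len(t_obs) else 0.0,
                (events[-1].time if events else 0.0),
                1.0,
            )
        return Regimen(events, horizon)

    def group_of(self, subject_id) -> float:
        return float(self.rows_for(subject_id)["group"].iloc[0])

    def resample_subjects(self, subject_ids) -> "ObservationTable":
        """A new table with the given subjects (repeats allowed, relabelled)."""
        obs_parts, dose_parts = [], []
        for k, sid in enumerate(subject_ids):
            o = self.observations[self.observations["subject_id"] == sid].copy()
            d = self.doses[self.doses["subject_id"] == sid].copy()
            new_id = f"BS{k + 1:03d}"
            o["subject_id"] = new_id
            d["subject_id"] = new_id
            obs_parts.append(o)
            dose_parts.append(d)
        return ObservationTable(
            pd.concat(obs_parts, ignore_index=True),
            pd.concat(dose_parts, ignore_index=True)
            if dose_parts
            else self.doses.iloc[:0],
        )

    def equals(self, other: "ObservationTable") -> bool:
        return self.observations.equals(other.observations) and self.doses.equals(
            other.doses
        )


def regimen_for_group(dose_mg_per_kg: float, design: StudyDesign) -> Regimen:
    """Weekly TD-arm regimen for one dose group (empty for the control)."""
    if dose_mg_per_kg == 0:
        return Regimen.placebo(design.horizon)
    events = tuple(
        DoseEvent(day, dose_mg_per_kg * 1000.0) for day in design.td_dose_days
    )
    return Regimen(events, design.horizon)


def _rngs(seed: int, arm: int, index: int):
    """Independent per-rat streams: one for etas, one for residual noise."""
    eta = np.random.default_rng(np.random.SeedSequence([seed, arm, index, 0]))
    res = np.random.default_rng(np.random.SeedSequence([seed, arm, index, 1]))
    return eta, res


def draw_individual(pop: PopulationModel, rng: np.random.Generator,
                    pk: bool = True, chronic: bool = True) -> dict:
    """Draw one animal's parameter sets: ``P_i = theta * exp(eta_i)``.

    Returns ``{"pk": PKParams, "acute": AcuteTDParams, "chronic":
    ChronicTDParams, "etas": {...}}``; parameters without a listed omega are
    copied unchanged.  Draw order is fixed (PK: V, ke, k12, k21; chronic:
    kin_chronic, EC50_chronic) so streams are reproducible.
    """
    etas: dict[str, float] = {}
    pk_i = pop.pk
    if pk:
        for name in PopulationModel._PK_OMEGA:
            etas[name] = rng.normal(0.0, pop.omega_sd(name)) if pop.omega.get(name) else 0.0
        pk_i = pop.pk.with_etas({k: etas[k] for k in PopulationModel._PK_OMEGA})
    chronic_i = pop.chronic
    if chronic:
        for name in PopulationModel._CHRONIC_OMEGA:
            etas[name] = rng.normal(0.0, pop.omega_sd(name)) if pop.omega.get(name) else 0.0
        chronic_i = pop.chronic.with_etas(
            {k: etas[k] for k in PopulationModel._CHRONIC_OMEGA}
        )
    return {"pk": pk_i, "acute": pop.acute, "chronic": chronic_i, "etas": etas}


def generate_pk_cohort(pop: PopulationModel, design: StudyDesign, seed: int,
                       truncate_negative: bool = False) -> ObservationTable:
    """Single-dose PK arm: concentration rows with proportional residual error."""
    times = np.asarray(design.pk_sample_times_days)
    obs_rows, dose_rows = [], []
    index = 0
    for dose in design.pk_doses_mg_per_kg:
        amount = dose * 1000.0
        regimen = Regimen.single_dose(amount, horizon=float(times[-1]))
        for _ in range(design.pk_n_per_group):
            index += 1
            sid = f"PK{index:03d}"
            rng_eta, rng_res = _rngs(seed, _PK_ARM, index)
            indiv = draw_individual(pop, rng_eta, pk=True, chronic=False)
            f = pk_concentration(indiv["pk"], regimen, times).values
            eps = rng_res.normal(0.0, 1.0, size=f.size)
            y = f * (1.0 + pop.sigma_pk_prop * eps)
            if truncate_negative:
                y = np.maximum(y, 0.0)
            dose_rows.append((sid, 0.0, amount))
            obs_rows.extend(
                (sid, dose, "plasma_conc", t, v) for t, v in zip(times, y)
            )
    return ObservationTable(
        pd.DataFrame(obs_rows, columns=OBS_COLUMNS),
        pd.DataFrame(dose_rows, columns=DOSE_COLUMNS),
    )


def generate_td_cohort(pop: PopulationModel, design: StudyDesign, seed: int,
                       pk_iiv_in_td: bool = True,
                       truncate_negative: bool = False) -> ObservationTable:
    """TD arm: acetone-score and von Frey rows over the 4-week schedule.

    ``pk_iiv_in_td`` draws individual PK parameters for the TD animals (more
    realistic; the default).  Recovery experiments switch it off so that the
    estimators' typical-PK assumption matches the generating process.
    """
    times = np.asarray(design.td_observation_days, dtype=float)
    obs_rows, dose_rows = [], []
    index = 0
    for dose, n_rats in zip(design.td_groups, design.td_n_per_group):
        regimen = regimen_for_group(dose, design)
        for _ in range(n_rats):
            index += 1
            sid = f"TD{index:03d}"
            rng_eta, rng_res = _rngs(seed, _TD_ARM, index)
            indiv = draw_individual(pop, rng_eta, pk=pk_iiv_in_td, chronic=True)
            f_ac = simulate_acute(indiv["acute"], indiv["pk"], regimen, times).values
            f_ch = simulate_chronic(indiv["chronic"], indiv["pk"], regimen, times).values
            eps_ac = rng_res.normal(0.0, 1.0, size=times.size)
            eps_ch = rng_res.normal(0.0, 1.0, size=times.size)
            y_ac = f_ac * (1.0 + pop.sigma_acute_prop * eps_ac)
            y_ch = f_ch + pop.sigma_chronic_add * eps_ch
            if truncate_negative:
                y_ac = np.maximum(y_ac, 0.0)
                y_ch = np.maximum(y_ch, 0.0)
            for e in regimen.events:
                dose_rows.append((sid, e.time, e.amount))
            obs_rows.extend(
                (sid, dose, "acetone_score", t, v) for t, v in zip(times, y_ac)
            )
            obs_rows.extend(
                (sid, dose, "vonfrey_threshold", t, v) for t, v in zip(times, y_ch)
            )
    doses = pd.DataFrame(dose_rows, columns=DOSE_COLUMNS)
    if not dose_rows:
        doses = pd.DataFrame({c: [] for c in DOSE_COLUMNS})
    return ObservationTable(pd.DataFrame(obs_rows, columns=OBS_COLUMNS), doses)
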