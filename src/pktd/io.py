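"""Dataset readers/writers and run configuration.

External files use a minimal two-CSV schema (times always in days):

* observations: ``ID,GROUP,ENDPOINT,TIME_DAYS,DV``
* dose events:  ``ID,TIME_DAYS,AMT_UG_PER_KG``

Users exporting from NONMEM-style datasets map ``EVID==0`` rows to the
observation file (``DV`` as is) and ``EVID==1``/``AMT`` rows to the dose
file; ``MDV`` rows are simply dropped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import ObservationTable
from .params import PopulationModel, StudyDesign, load_preset
from .trajectories import ENDPOINTS

__all__ = [
    "read_observations",
    "write_observations",
    "RunConfig",
    "ParseError",
]

_OBS_HEADER = ["ID", "GROUP", "ENDPOINT", "TIME_DAYS", "DV"]
_DOSE_HEADER = ["ID", "TIME_DAYS", "AMT_UG_PER_KG"]


class ParseError(ValueError):
    pass


def _check_header(df: pd.DataFrame, expected, path) -> None:
    if list(df.columns) != expected:
        raise ParseError(
            f"{path}: expected header {','.join(expected)}, got "
            f"{','.join(map(str, df.columns))}"
        )


def read_observations(obs_path, doses_path) -> ObservationTable:
    """Read an observation table and its companion dose-event file.

    Raises :class:`ParseError` naming the offending row (1-based, excluding
    the header) for unknown endpoint codes, non-numeric values or unsorted
    per-animal times.
    """
    obs = pd.read_csv(obs_path, dtype=str).fillna("")
    doses = pd.read_csv(doses_path, dtype=str).fillna("")
    _check_header(obs, _OBS_HEADER, obs_path)
    _check_header(doses, _DOSE_HEADER, doses_path)

    for i, code in enumerate(obs["ENDPOINT"], start=1):
        if code not in ENDPOINTS:
            raise ParseError(
                f"{obs_path}: row {i}: unknown endpoint code {code!r} "
                f"(expected one of {', '.join(ENDPOINTS)})"
            )
    for name, col in (("TIME_DAYS", obs["TIME_DAYS"]), ("DV", obs["DV"])):
        for i, v in enumerate(col, start=1):
            try:
                float(v)
            except ValueError:
                raise ParseError(
                    f"{obs_path}: row {i}: non-numeric {name} value {v!r}"
                ) from None
    out_obs = pd.DataFrame({
        "subject_id": obs["ID"],
        "group": obs["GROUP"].astype(float),
        "endpoint": obs["ENDPOINT"],
        "time_days": obs["TIME_DAYS"].astype(float),
        "value": obs["DV"].astype(float),
    })
    for (sid, ep), g in out_obs.groupby(["subject_id", "endpoint"], sort=False):
        t = g["time_days"].to_numpy()
        if (t[1:] < t[:-1]).any():
            first_bad = int(g.index[1:][t[1:] < t[:-1]][0]) + 1
            raise ParseError(
                f"{obs_path}: row {first_bad}: unsorted times for animal "
                f"{sid!r} / {ep}"
            )
    for name in ("TIME_DAYS", "AMT_UG_PER_KG"):
        for i, v in enumerate(doses[name], start=1):
            try:
                float(v)
            except ValueError:
                raise ParseError(
                    f"{doses_path}: row {i}: non-numeric {name} value {v!r}"
                ) from None
    out_doses = pd.DataFrame({
        "subject_id": doses["ID"],
        "time_days": doses["TIME_DAYS"].astype(float),
        "amount_ug_per_kg": doses["AMT_UG_PER_KG"].astype(float),
    })
    return ObservationTable(out_obs, out_doses)


def write_observations(table: ObservationTable, obs_path, doses_path) -> None:
    """Write the two-file CSV form; ``read_observations`` round-trips it."""
    obs = table.observations.rename(columns={
        "subject_id": "ID", "group": "GROUP", "endpoint": "ENDPOINT",
        "time_days": "TIME_DAYS", "value": "DV",
    })
    doses = table.doses.rename(columns={
        "subject_id": "ID", "time_days": "TIME_DAYS",
        "amount_ug_per_kg": "AMT_UG_PER_KG",
    })
    # %.17g keeps doubles exact, so write -> read is the identity
    obs.to_csv(obs_path, index=False, float_format="%.17g")
    doses.to_csv(doses_path, index=False, float_format="%.17g")


_KNOWN_KEYS = {
    "preset", "seed", "design", "estimator", "evaluation",
}
_DESIGN_KEYS = set(StudyDesign.__dataclass_fields__)
_ESTIMATOR_KEYS = {"pk_method", "n_starts", "init_offset"}
_EVAL_KEYS = {"n_sim", "n_boot", "percentiles", "stratify"}


@dataclass
class RunConfig:
    """Resolved run configuration: preset + design + estimator/eval options.

    Unknown keys in a config file are rejected rather than ignored, so typos
    cannot silently change a run.
    """

    preset: str = "reference"
    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    estimator: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        design_raw = raw.get("design", {})
        bad = set(design_raw) - _DESIGN_KEYS
        if bad:
            raise ValueError(f"unknown design keys: {sorted(bad)}")
        for section, allowed in (("estimator", _ESTIMATOR_KEYS),
                                 ("evaluation", _EVAL_KEYS)):
            bad = set(raw.get(section, {})) - allowed
            if bad:
                raise ValueError(f"unknown {section} keys: {sorted(bad)}")
        design = StudyDesign(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in design_raw.items()
        })
        return cls(
            preset=raw.get("preset", "reference"),
            seed=int(raw.get("seed", 0)),
            design=design,
            estimator=dict(raw.get("estimator", {})),
            evaluation=dict(raw.get("evaluation", {})),
        )

    def population(self) -> PopulationModel:
        return load_preset(self.preset)

    def digest(self) -> str:
        blob = json.dumps(
            {"preset": self.preset, "seed": self.seed,
             "design": asdict(self.design), "estimator": self.estimator,
             "evaluation": self.evaluation},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
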