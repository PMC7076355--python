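"""Model/Results interface over the estimation pipeline.

Each model class wraps one endpoint of the rat oxaliplatin neuropathy study:

* :class:`PlasmaPKModel` -- two-compartment disposition, per-animal data.
* :class:`AcuteNeuropathyModel` -- acetone-test indirect-response model, PK
  fixed at typical values.
* :class:`ChronicNeuropathyModel` -- von Frey transit-chain model, PK fixed.

``fit()`` returns a Results object carrying the estimates, their asymptotic
CV%, -2LL/AIC, residual diagnostics and a ``summary()`` table; simulation,
VPC and bootstrap hang off the results.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import estimation, evaluation
from .cohort import ObservationTable
from .params import AcuteTDParams, ChronicTDParams, PKParams, PopulationModel
from .trajectories import pk_concentration, simulate_acute, simulate_chronic

__all__ = [
    "PlasmaPKModel",
    "AcuteNeuropathyModel",
    "ChronicNeuropathyModel",
    "PKResults",
    "AcuteResults",
    "ChronicResults",
]


def _as_table(data) -> ObservationTable:
    if isinstance(data, ObservationTable):
        return data
    if isinstance(data, tuple) and len(data) == 2:
        return ObservationTable(*data)
    raise TypeError(
        "data must be an ObservationTable or an (observations, doses) pair"
    )


class _ResultsBase:
    """Shared presentation layer for fit results."""

    _title = "fit"

    def __init__(self, model, fit: estimation.FitResult):
        self.model = model
        self.fit = fit

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit.estimates)

    @property
    def cv_percent(self) -> pd.Series:
        return pd.Series(self.fit.se_cv_percent, dtype=float)

    @property
    def minus2ll(self) -> float:
        return self.fit.minus2ll

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def residuals(self) -> pd.DataFrame | None:
        return self.fit.residuals

    def diagnostics(self) -> pd.DataFrame:
        return evaluation.gof_diagnostics(self.fit)

    def summary(self) -> str:
        lines = [
            f"{self._title}",
            "=" * len(self._title),
            f"n_obs: {self.fit.n_obs}   n_params: {self.fit.n_params}   "
            f"-2LL: {self.fit.minus2ll:.2f}   AIC: {self.fit.aic:.2f}",
            f"converged: {self.fit.converged} ({self.fit.message})",
            "",
            f"{'parameter':<22}{'estimate':>12}{'CV%':>9}",
            "-" * 43,
        ]
        for name, value in self.fit.estimates.items():
            cv = self.fit.se_cv_percent.get(name)
            cv_s = f"{cv:9.1f}" if cv is not None and np.isfinite(cv) else "        -"
            lines.append(f"{name:<22}{value:>12.4g}{cv_s}")
        return "\n".join(lines)


class PKResults(_ResultsBase):
    _title = "Population PK fit (two-compartment, IV bolus)"

    @property
    def pk_params(self) -> PKParams:
        e = self.fit.estimates
        return PKParams(V=e["V"], ke=e["ke"], k12=e["k12"], k21=e["k21"])

    def predict(self, regimen, times) -> np.ndarray:
        return pk_concentration(self.pk_params, regimen, times).values

    def population_model(self, base: PopulationModel) -> PopulationModel:
        """The base population model with PK blocks replaced by the estimates."""
        e = self.fit.estimates
        omega = dict(base.omega)
        for k in ("V", "ke", "k12", "k21"):
            if f"omega_{k}" in e:
                omega[k] = e[f"omega_{k}"]
        return replace(base, pk=self.pk_params, omega=omega,
                       sigma_pk_prop=e.get("sigma_prop", base.sigma_pk_prop))

    def vpc(self, pop: PopulationModel, n_sim: int = 1000, seed: int = 0,
            **kwargs) -> evaluation.VPCResult:
        return evaluation.pc_vpc(self.model.data, self.population_model(pop),
                                 n_sim=n_sim, seed=seed,
                                 endpoint="plasma_conc", **kwargs)

    def bootstrap(self, n_boot: int = 1000, seed: int = 0,
                  **kwargs) -> evaluation.BootstrapResult:
        m = self.model

        def handle(tab):
            return estimation.fit_pk_population(tab, m.init, method=m.method,
                                                n_starts=m.n_starts)

        return evaluation.bootstrap(m.data, handle, n_boot=n_boot, seed=seed,
                                    **kwargs)


class PlasmaPKModel:
    """Two-compartment population PK model of plasma oxaliplatin.

    ``data`` is an :class:`ObservationTable` (or ``(observations, doses)``
    DataFrame pair) holding ``plasma_conc`` rows.  ``init`` provides the
    typical-value starting point for all searches.
    """

    def __init__(self, data, init: PKParams, method: str = "its",
                 n_starts: int = 5):
        self.data = _as_table(data).endpoint("plasma_conc")
        self.init = init
        self.method = method
        self.n_starts = n_starts

    @classmethod
    def from_dataframe(cls, observations: pd.DataFrame, doses: pd.DataFrame,
                       init: PKParams, **kwargs) -> "PlasmaPKModel":
        return cls(ObservationTable(observations, doses), init, **kwargs)

    def fit(self, method: str | None = None) -> PKResults:
        res = estimation.fit_pk_population(
            self.data, self.init, method=method or self.method,
            n_starts=self.n_starts,
        )
        return PKResults(self, res)


class AcuteResults(_ResultsBase):
    _title = "Acute neuropathy fit (acetone test, indirect response)"

    @property
    def td_params(self) -> AcuteTDParams:
        e = self.fit.estimates
        return replace(self.model.init,
                       kin_acute=e["kin_acute"], kout_acute=e["kout_acute"],
                       Emax_acute=e["Emax_acute"], EC50_acute=e["EC50_acute"])

    def predict(self, regimen, times) -> np.ndarray:
        return simulate_acute(self.td_params, self.model.pk_fixed, regimen,
                              times).values

    def vpc(self, pop: PopulationModel, n_sim: int = 1000, seed: int = 0,
            **kwargs) -> evaluation.VPCResult:
        e = self.fit.estimates
        pop = replace(pop, acute=self.td_params,
                      sigma_acute_prop=e.get("sigma_prop", pop.sigma_acute_prop))
        return evaluation.pc_vpc(self.model.data, pop, n_sim=n_sim, seed=seed,
                                 endpoint="acetone_score", **kwargs)

    def bootstrap(self, n_boot: int = 1000, seed: int = 0,
                  **kwargs) -> evaluation.BootstrapResult:
        m = self.model

        def handle(tab):
            return estimation.fit_acute_td(tab, m.pk_fixed, m.init,
                                           n_starts=m.n_starts,
                                           compute_cv=False)

        return evaluation.bootstrap(m.data, handle, n_boot=n_boot, seed=seed,
                                    **kwargs)


class AcuteNeuropathyModel:
    """Cold-allodynia (acetone test) toxicodynamics with fixed typical PK."""

    def __init__(self, data, pk_fixed: PKParams, init: AcuteTDParams,
                 n_starts: int = 5):
        self.data = _as_table(data).endpoint("acetone_score")
        self.pk_fixed = pk_fixed
        self.init = init
        self.n_starts = n_starts

    @classmethod
    def from_dataframe(cls, observations, doses, pk_fixed, init, **kwargs):
        return cls(ObservationTable(observations, doses), pk_fixed, init,
                   **kwargs)

    def fit(self, fixed: dict | None = None) -> AcuteResults:
        res = estimation.fit_acute_td(self.data, self.pk_fixed, self.init,
                                      n_starts=self.n_starts, fixed=fixed)
        return AcuteResults(self, res)


class ChronicResults(_ResultsBase):
    _title = "Chronic neuropathy fit (von Frey test, transit chain)"

    @property
    def td_params(self) -> ChronicTDParams:
        e = self.fit.estimates
        return replace(self.model.init,
                       kin_chronic=e["kin_chronic"],
                       Emax_chronic=e["Emax_chronic"],
                       EC50_chronic=e["EC50_chronic"])

    @property
    def etas(self) -> pd.DataFrame:
        return pd.DataFrame(self.fit.etas).T

    def shrinkage(self, omega_cv_percent: dict | None = None) -> pd.Series:
        """Eta shrinkage per random effect, against fitted (or given) omegas.

        Uses the empirical-Bayes deviations (shrunken toward zero where the
        individual data are uninformative) when the fit provides them.
        """
        source = self.fit.extra.get("eb_etas") or self.fit.etas
        out = {}
        for name in ("kin_chronic", "EC50_chronic"):
            omega = (omega_cv_percent or {}).get(
                name, self.fit.estimates.get(f"omega_{name}", 0.0)
            )
            etas = [e[name] for e in source.values()]
            out[name] = evaluation.eta_shrinkage(etas, omega)
        return pd.Series(out)

    def predict(self, regimen, times) -> np.ndarray:
        return simulate_chronic(self.td_params, self.model.pk_fixed, regimen,
                                times).values

    def vpc(self, pop: PopulationModel, n_sim: int = 1000, seed: int = 0,
            **kwargs) -> evaluation.VPCResult:
        e = self.fit.estimates
        omega = dict(pop.omega)
        for k in ("kin_chronic", "EC50_chronic"):
            if f"omega_{k}" in e:
                omega[k] = e[f"omega_{k}"]
        pop = replace(pop, chronic=self.td_params, omega=omega,
                      sigma_chronic_add=e.get("sigma_add",
                                              pop.sigma_chronic_add))
        return evaluation.pc_vpc(self.model.data, pop, n_sim=n_sim, seed=seed,
                                 endpoint="vonfrey_threshold", **kwargs)

    def bootstrap(self, n_boot: int = 1000, seed: int = 0,
                  **kwargs) -> evaluation.BootstrapResult:
        m = self.model

        def handle(tab):
            return estimation.fit_chronic_td(tab, m.pk_fixed, m.init,
                                             n_starts=m.n_starts,
                                             compute_cv=False)

        return evaluation.bootstrap(m.data, handle, n_boot=n_boot, seed=seed,
                                    **kwargs)


class ChronicNeuropathyModel:
    """Mechanical-allodynia (von Frey) toxicodynamics with fixed typical PK."""

    def __init__(self, data, pk_fixed: PKParams, init: ChronicTDParams,
                 n_starts: int = 5):
        self.data = _as_table(data).endpoint("vonfrey_threshold")
        self.pk_fixed = pk_fixed
        self.init = init
        self.n_starts = n_starts

    @classmethod
    def from_dataframe(cls, observations, doses, pk_fixed, init, **kwargs):
        return cls(ObservationTable(observations, doses), pk_fixed, init,
                   **kwargs)

    def fit(self, refit_individuals: bool = True) -> ChronicResults:
        res = estimation.fit_chronic_td(self.data, self.pk_fixed, self.init,
                                        n_starts=self.n_starts,
                                        refit_individuals=refit_individuals)
        return ChronicResults(self, res)
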