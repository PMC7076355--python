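"""Model-qualification toolkit.

Prediction-corrected visual predictive check (pcVPC), stratified
nonparametric bootstrap, goodness-of-fit residual summaries and eta
shrinkage.  All routines are deterministic functions of (data, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ObservationTable, draw_individual
from .estimation import FitResult
from .params import PopulationModel
from .trajectories import pk_concentration, simulate_acute, simulate_chronic

__all__ = [
    "VPCResult",
    "BootstrapResult",
    "pc_vpc",
    "bootstrap",
    "gof_diagnostics",
    "eta_shrinkage",
]

log = logging.getLogger(__name__)

_PROPORTIONAL_ENDPOINTS = {"plasma_conc", "acetone_score"}


@dataclass(frozen=True)
class VPCResult:
    """Observed and simulated percentiles of prediction-corrected values.

    ``table`` has one row per bin and percentile with the observed value, the
    across-replicate median of the simulated percentile and its 95%
    confidence band.
    """

    table: pd.DataFrame
    n_sim: int
    endpoint: str
    n_fallback: int = 0

    def __post_init__(self):
        t = self.table
        bad = t[(t["sim_lo"] > t["sim_median"]) | (t["sim_median"] > t["sim_hi"])]
        if len(bad):
            raise ValueError("simulated percentile bands are not ordered")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots(figsize=(7, 4))
        for stat, style in (("p5", "--"), ("p50", "-"), ("p95", "--")):
            sub = self.table[self.table["stat"] == stat].sort_values("bin_time")
            ax.plot(sub["bin_time"], sub["observed"], "k" + style, lw=1.2)
            ax.plot(sub["bin_time"], sub["sim_median"], "r" + style, lw=1.0)
            ax.fill_between(sub["bin_time"], sub["sim_lo"], sub["sim_hi"],
                            color="0.8", alpha=0.6)
        ax.set_xlabel("time (days)")
        ax.set_ylabel(f"prediction-corrected {self.endpoint}")
        return ax


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate estimates with per-parameter median and percentile interval."""

    replicates: pd.DataFrame
    summary: pd.DataFrame          # parameter, median, lo, hi
    percentiles: tuple[float, float]
    n_boot: int
    n_failed: int

    @property
    def unstable(self) -> bool:
        return self.n_failed > 0.2 * self.n_boot

    def __post_init__(self):
        s = self.summary
        bad = s[(s["lo"] > s["median"]) | (s["median"] > s["hi"])]
        if len(bad):
            raise ValueError("bootstrap interval does not bracket the median")


def _population_predictions(table: ObservationTable, pop: PopulationModel,
                            endpoint: str) -> np.ndarray:
    """Typical-parameter (PRED) value for every observation row."""
    obs = table.observations
    preds = np.empty(len(obs))
    cache: dict = {}
    for sid, rows in obs.groupby("subject_id", sort=False):
        reg = table.regimen_for(sid)
        key = tuple((e.time, e.amount) for e in reg.events)
        t = rows["time_days"].to_numpy()
        ckey = (key, tuple(t))
        if ckey not in cache:
            if endpoint == "plasma_conc":
                cache[ckey] = pk_concentration(pop.pk, reg, t).values
            elif endpoint == "acetone_score":
                cache[ckey] = simulate_acute(pop.acute, pop.pk, reg, t).values
            else:
                cache[ckey] = simulate_chronic(pop.chronic, pop.pk, reg, t).values
        preds[rows.index] = cache[ckey]
    return preds


def _simulate_replicate(table: ObservationTable, pop: PopulationModel,
                        endpoint: str, rng: np.random.Generator) -> np.ndarray:
    """One simulated dataset at the table's design (etas + residual noise)."""
    obs = table.observations
    values = np.empty(len(obs))
    for sid, rows in obs.groupby("subject_id", sort=False):
        reg = table.regimen_for(sid)
        t = rows["time_days"].to_numpy()
        indiv = draw_individual(pop, rng)
        if endpoint == "plasma_conc":
            f = pk_concentration(indiv["pk"], reg, t).values
            y = f * (1.0 + pop.sigma_pk_prop * rng.normal(size=t.size))
        elif endpoint == "acetone_score":
            f = simulate_acute(indiv["acute"], indiv["pk"], reg, t).values
            y = f * (1.0 + pop.sigma_acute_prop * rng.normal(size=t.size))
        else:
            f = simulate_chronic(indiv["chronic"], indiv["pk"], reg, t).values
            y = f + pop.sigma_chronic_add * rng.normal(size=t.size)
        values[rows.index] = y
    return values


def pc_vpc(table: ObservationTable, pop: PopulationModel, n_sim: int = 1000,
           seed: int = 0, endpoint: str = "plasma_conc",
           stratify: str | None = None) -> VPCResult:
    """Prediction-corrected visual predictive check for one endpoint.

    Each observed and simulated value is corrected by the ratio (proportional
    endpoints) or the difference (additive von Frey endpoint) between the
    bin-median population prediction and the record's own population
    prediction, then 5th/50th/95th percentiles are compared per time bin.
    Bins are the nominal observation times pooled across dose groups
    (``stratify="group"`` keeps groups separate, in which case the correction
    is a no-op under a balanced design).
    """
    sub = table.endpoint(endpoint)
    if sub.observations.empty:
        raise ValueError(f"no {endpoint} rows to check")
    obs = sub.observations
    pred = _population_predictions(sub, pop, endpoint)

    if stratify == "group":
        bins = list(zip(obs["group"], obs["time_days"]))
    else:
        bins = list(obs["time_days"])
    bins = pd.Series(bins, index=obs.index)
    bin_median_pred = pred.copy()
    for _, idx in bins.groupby(bins).groups.items():
        bin_median_pred[obs.index.get_indexer(idx)] = np.median(
            pred[obs.index.get_indexer(idx)]
        )

    n_fallback = 0
    if endpoint in _PROPORTIONAL_ENDPOINTS:
        ok = pred > 0
        n_fallback = int((~ok).sum())
        if n_fallback:
            log.warning("%d records with non-positive PRED: no correction applied",
                        n_fallback)
        factor = np.where(ok, bin_median_pred / np.where(ok, pred, 1.0), 1.0)

        def correct(v):
            return v * factor
    else:
        offset = bin_median_pred - pred

        def correct(v):
            return v + offset

    y_corr = correct(obs["value"].to_numpy())

    qs = (5.0, 50.0, 95.0)
    stats = ("p5", "p50", "p95")

    def bin_percentiles(values):
        out = {}
        for b, idx in bins.groupby(bins).groups.items():
            sel = values[obs.index.get_indexer(idx)]
            out[b] = np.percentile(sel, qs)
        return out

    obs_pct = bin_percentiles(y_corr)

    sims = {b: [] for b in obs_pct}
    for rep in range(n_sim):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        y_sim = correct(_simulate_replicate(sub, pop, endpoint, rng))
        for b, p in bin_percentiles(y_sim).items():
            sims[b].append(p)

    rows = []
    for b in obs_pct:
        arr = np.asarray(sims[b])  # n_sim x 3
        for j, stat in enumerate(stats):
            bin_time = b[1] if stratify == "group" else b
            rows.append({
                "bin_time": float(bin_time),
                "group": (b[0] if stratify == "group" else np.nan),
                "stat": stat,
                "observed": float(obs_pct[b][j]),
                "sim_median": float(np.median(arr[:, j])),
                "sim_lo": float(np.percentile(arr[:, j], 2.5)),
                "sim_hi": float(np.percentile(arr[:, j], 97.5)),
            })
    out = pd.DataFrame(rows).sort_values(["bin_time", "stat"]).reset_index(drop=True)
    return VPCResult(table=out, n_sim=n_sim, endpoint=endpoint,
                     n_fallback=n_fallback)


def bootstrap(table: ObservationTable, fit_handle, n_boot: int = 1000,
              stratify_by_group: bool = True, percentiles=(5.0, 95.0),
              seed: int = 0) -> BootstrapResult:
    """Nonparametric bootstrap: resample animals, refit, summarise.

    ``fit_handle(table) -> FitResult`` must succeed on the original table.
    Resampling is with replacement within dose-group strata (preserving
    per-group animal counts); non-converged replicates are counted and
    excluded from the summary.
    """
    base = fit_handle(table)
    if not base.converged:
        raise RuntimeError("fit does not converge on the original table")
    lo_q, hi_q = percentiles
    groups: dict = {}
    for sid in table.subjects:
        groups.setdefault(table.group_of(sid), []).append(sid)

    rows = []
    n_failed = 0
    for rep in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        chosen = []
        if stratify_by_group:
            for g in sorted(groups):
                sids = groups[g]
                chosen.extend(rng.choice(sids, size=len(sids), replace=True))
        else:
            all_sids = list(table.subjects)
            chosen = list(rng.choice(all_sids, size=len(all_sids), replace=True))
        try:
            res = fit_handle(table.resample_subjects(chosen))
        except Exception:
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        rows.append({"replicate": rep,
                     **{k: v for k, v in res.estimates.items()
                        if np.isscalar(v)}})
    replicates = pd.DataFrame(rows)
    summ = []
    for col in replicates.columns:
        if col == "replicate":
            continue
        v = replicates[col].to_numpy(dtype=float)
        summ.append({
            "parameter": col,
            "median": float(np.median(v)),
            "lo": float(np.percentile(v, lo_q)),
            "hi": float(np.percentile(v, hi_q)),
        })
    result = BootstrapResult(
        replicates=replicates, summary=pd.DataFrame(summ),
        percentiles=(lo_q, hi_q), n_boot=n_boot, n_failed=n_failed,
    )
    if result.unstable:
        log.warning("bootstrap flagged unstable: %d/%d replicates failed",
                    n_failed, n_boot)
    return result


def gof_diagnostics(fit: FitResult) -> pd.DataFrame:
    """Summary statistics of the fit's residual diagnostics.

    Returns one row per residual type present in the fit's residual table
    (IWRES, WRES, ...), with mean, SD and n.  Population predictions missing
    (pooled fits without IPRED) simply yield fewer rows, not an error.
    """
    if fit.residuals is None:
        raise ValueError("fit carries no residual table")
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    res = fit.residuals
    rows = []
    for col in res.columns:
        if not ("WRES" in col or col in ("PRED", "IPRED")):
            continue
        v = res[col].to_numpy(dtype=float)
        rows.append({"quantity": col, "mean": float(np.mean(v)),
                     "sd": float(np.std(v, ddof=1)), "n": int(v.size)})
    return pd.DataFrame(rows)


def eta_shrinkage(etas, omega_cv_percent: float) -> float:
    """Eta shrinkage in percent: ``100 * (1 - SD(eta_hat) / omega)``.

    ``etas`` are per-animal log-scale empirical-Bayes deviations; ``omega``
    is the model's inter-individual %CV for that parameter.  Returns NaN
    (not applicable) when omega is zero.
    """
    if omega_cv_percent == 0:
        return float("nan")
    etas = np.asarray(list(etas), dtype=float)
    if etas.size < 2:
        return float("nan")
    return float(100.0 * (1.0 - np.std(etas, ddof=1) / (omega_cv_percent / 100.0)))
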