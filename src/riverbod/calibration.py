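"""Latin-Hypercube calibration against monitored mean-annual concentrations.

Parameter sets are sampled uniformly within the calibration ranges with
a Latin Hypercube scheme; each set drives the full forward model
(emissions -> attenuation -> routing), and the simulated concentrations
at monitored subbasins are scored against observations.  Efficiency
scores (KGE, R2) are computed on log-transformed concentrations;
MAE/RMSE/percent bias on the natural scale.  The behavioral subset is
the intersection of the upper quartiles of KGE and R2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .emissions import SourceData, compute_emissions
from .errors import ValidationError
from .network import Network, VelocityModel
from .params import (
    Constants,
    DEFAULT_CONSTANTS,
    PARAM_NAMES,
    ParameterRanges,
    ParameterSet,
)
from .routing import route_network

#: Concentration floor (mg O2/L) applied before log transforming — half
#: the modal reported detection limit of 0.5 mg O2/L.
LOG_FLOOR_MG_L = 0.25


def lhs_sample(ranges: ParameterRanges, n: int, seed: int) -> list[ParameterSet]:
    """Draw ``n`` parameter sets by Latin Hypercube within ``ranges``.

    Marginals are uniform and stratified: for every parameter the sorted
    samples occupy all ``n`` equiprobable strata.  Deterministic under
    ``seed``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(PARAM_NAMES), seed=seed)
    unit = sampler.random(n)
    scaled = qmc.scale(unit, ranges.lower(), ranges.upper())
    return [ParameterSet.from_array(row) for row in scaled]


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def kge(obs, sim) -> float:
    """Kling-Gupta efficiency (2009 form), <= 1, perfect at 1.

    ``1 - sqrt((r-1)^2 + (alpha-1)^2 + (beta-1)^2)`` with r the Pearson
    correlation, alpha the ratio of standard deviations and beta the
    ratio of means.  Returns NaN for degenerate observations (zero mean
    or zero variance) or constant simulations.
    """
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape or obs.size < 2:
        raise ValidationError("obs and sim must be equal-length series of size >= 2")
    if obs.mean() == 0 or obs.std() == 0:
        return np.nan
    r = _pearson_r(obs, sim)
    if np.isnan(r):
        return np.nan
    alpha = sim.std() / obs.std()
    beta = sim.mean() / obs.mean()
    return float(1.0 - np.sqrt((r - 1) ** 2 + (alpha - 1) ** 2 + (beta - 1) ** 2))


def r_squared(obs, sim) -> float:
    """Coefficient of determination as squared Pearson correlation."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    r = _pearson_r(obs, sim)
    return np.nan if np.isnan(r) else float(r**2)


@dataclass(frozen=True)
class GOFReport:
    """Goodness-of-fit suite for one simulation against observations."""

    kge: float
    r2: float
    mae: float
    rmse: float
    pbias_percent: float
    n_stations: int


def gof_suite(obs_conc, sim_conc, log_floor: float = LOG_FLOOR_MG_L) -> GOFReport:
    """Score simulated vs observed concentrations.

    KGE and R2 are computed on natural-log concentrations floored at
    ``log_floor``; MAE, RMSE and percent bias on the natural scale.
    """
    obs = np.asarray(obs_conc, dtype=float)
    sim = np.asarray(sim_conc, dtype=float)
    if obs.size == 0 or obs.shape != sim.shape:
        raise ValidationError("empty or mismatched observation pairing")
    log_obs = np.log(np.maximum(obs, log_floor))
    log_sim = np.log(np.maximum(sim, log_floor))
    err = sim - obs
    return GOFReport(
        kge=kge(log_obs, log_sim) if obs.size >= 2 else np.nan,
        r2=r_squared(log_obs, log_sim) if obs.size >= 2 else np.nan,
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        pbias_percent=float(100.0 * err.sum() / obs.sum()) if obs.sum() != 0 else np.nan,
        n_stations=int(obs.size),
    )


GOF_COLUMNS = ("kge", "r2", "mae", "rmse", "pbias_percent")


@dataclass
class CalibrationRun:
    """Result of an LHS calibration: samples, scores and behavioral flags."""

    params: pd.DataFrame  # n x 10, columns PARAM_NAMES
    gof: pd.DataFrame  # n x GOF_COLUMNS
    behavioral: np.ndarray  # boolean, length n
    seed: int
    best_index: int  # max-KGE member of the behavioral subset

    @property
    def best_parameters(self) -> ParameterSet:
        return ParameterSet.from_array(self.params.iloc[self.best_index].values)

    def behavioral_envelope(self) -> pd.DataFrame:
        """Per-parameter [min, max] over the behavioral subset."""
        sub = self.params.loc[self.behavioral]
        return pd.DataFrame({"lower": sub.min(), "upper": sub.max()})

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat([self.params, self.gof], axis=1)
        out["behavioral"] = self.behavioral
        return out


def simulate_concentrations(
    net: Network,
    data: SourceData,
    p: ParameterSet,
    c: Constants = DEFAULT_CONSTANTS,
    velocity_model: VelocityModel | None = None,
) -> pd.Series:
    """Forward model: mean-annual concentration (mg O2/L) per subbasin."""
    em = compute_emissions(net, data, p, c)
    fluxes = route_network(net, em, p, c, velocity_model=velocity_model)
    return pd.Series(
        {sid: fx.concentration_mg_l for sid, fx in fluxes.items()}, name="sim_conc"
    )


def behavioral_mask(kge_values: np.ndarray, r2_values: np.ndarray) -> np.ndarray:
    """Upper-quartile intersection rule with inclusive (>= Q3) membership."""
    kge_values = np.asarray(kge_values, dtype=float)
    r2_values = np.asarray(r2_values, dtype=float)
    valid = ~(np.isnan(kge_values) | np.isnan(r2_values))
    if not valid.any():
        raise ValidationError("no valid scores to select behavioral sets from")
    q_kge = np.nanquantile(kge_values, 0.75)
    q_r2 = np.nanquantile(r2_values, 0.75)
    return valid & (kge_values >= q_kge) & (r2_values >= q_r2)


def run_calibration(
    net: Network,
    data: SourceData,
    observations: pd.DataFrame,
    ranges: ParameterRanges | None = None,
    n: int = 1500,
    seed: int = 42,
    c: Constants = DEFAULT_CONSTANTS,
    velocity_model: VelocityModel | None = None,
) -> CalibrationRun:
    """Sample, run and score ``n`` parameter sets; flag the behavioral ones.

    ``observations`` needs columns ``subbasin_id`` and ``mean_conc_mg_l``;
    stations whose subbasin is not in the network, or whose simulated
    concentration is undefined (zero discharge), raise/are dropped
    respectively.  The recommended set (``best_index``) is the max-KGE
    member of the behavioral subset — advisory only; the shipped
    calibrated defaults remain the canonical parameters.
    """
    ranges = ranges or ParameterRanges()
    if "subbasin_id" not in observations or "mean_conc_mg_l" not in observations:
        raise ValidationError(
            "observations need 'subbasin_id' and 'mean_conc_mg_l' columns"
        )
    station_ids = observations["subbasin_id"].astype(str).tolist()
    unknown = sorted(set(station_ids) - set(net.ids))
    if unknown:
        raise ValidationError(f"observation subbasin(s) not in network: {unknown[:5]}")
    if not station_ids:
        raise ValidationError("no observation stations resolvable")
    obs_conc = observations["mean_conc_mg_l"].to_numpy(dtype=float)

    samples = lhs_sample(ranges, n, seed)
    gof_rows = []
    for p in samples:
        sim = simulate_concentrations(net, data, p, c, velocity_model)
        sim_at_stations = sim.loc[station_ids].to_numpy()
        ok = ~np.isnan(sim_at_stations)
        rep = gof_suite(obs_conc[ok], sim_at_stations[ok])
        gof_rows.append(
            [rep.kge, rep.r2, rep.mae, rep.rmse, rep.pbias_percent]
        )

    params_frame = pd.DataFrame(
        [p.as_array() for p in samples], columns=list(PARAM_NAMES)
    )
    gof_frame = pd.DataFrame(gof_rows, columns=list(GOF_COLUMNS))
    mask = behavioral_mask(gof_frame["kge"].values, gof_frame["r2"].values)
    kge_masked = np.where(mask, gof_frame["kge"].values, -np.inf)
    best = int(np.argmax(kge_masked))
    return CalibrationRun(
        params=params_frame, gof=gof_frame, behavioral=mask, seed=seed, best_index=best
    )


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson matrix over parameters and scores with significance flags."""

    corr: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame  # two-sided P < alpha
    alpha: float
    n_sets: int


def parameter_correlations(run: CalibrationRun, alpha: float = 0.05) -> CorrelationReport:
    """Pearson correlations among behavioral parameters, KGE and R2.

    Constant columns yield NaN entries (flagged non-significant) rather
    than raising.
    """
    sub = run.to_frame().loc[run.behavioral, list(PARAM_NAMES) + ["kge", "r2"]]
    if len(sub) < 3:
        raise ValidationError("need at least 3 behavioral sets for correlations")
    cols = list(sub.columns)
    k = len(cols)
    corr = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x, y = sub[cols[i]].values, sub[cols[j]].values
            if i == j:
                corr[i, j], pval[i, j] = 1.0, 0.0
                continue
            if x.std() == 0 or y.std() == 0:
                continue
            r, pv = stats.pearsonr(x, y)
            corr[i, j] = corr[j, i] = r
            pval[i, j] = pval[j, i] = pv
    corr_df = pd.DataFrame(corr, index=cols, columns=cols)
    pval_df = pd.DataFrame(pval, index=cols, columns=cols)
    return CorrelationReport(
        corr=corr_df,
        pvalues=pval_df,
        significant=pval_df < alpha,
        alpha=alpha,
        n_sets=len(sub),
    )
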