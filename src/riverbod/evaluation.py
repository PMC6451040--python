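"""Water-quality evaluation: BOD conversions, classes, and accuracy.

Concentrations are binned into five ordered quality classes (High to
Bad) at 2.5 / 5 / 10 / 15 mg O2/L; boundary values fall in the worse
class.  Classification skill against observations is summarized with a
confusion matrix (producer/user/overall accuracy, gross over- and
under-prediction rates) and a threshold-tolerant agreement score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import Network
from .params import Constants, DEFAULT_CONSTANTS
from .routing import ReachFlux


class QualityClass(enum.IntEnum):
    """Ordered water-quality classes; smaller is better."""

    HIGH = 0
    GOOD = 1
    MODERATE = 2
    POOR = 3
    BAD = 4


#: Upper class boundaries (mg O2/L); a boundary belongs to the worse class.
CLASS_THRESHOLDS: tuple[float, ...] = (2.5, 5.0, 10.0, 15.0)


def bod7_to_bod5(x, c: Constants = DEFAULT_CONSTANTS):
    """Convert BOD7 to BOD5 equivalents (same units, concentration or load)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("BOD values must be non-negative")
    out = arr / c.bod7_to_bod5_divisor
    return float(out) if out.ndim == 0 else out


def classify(conc_mg_l: float) -> QualityClass | None:
    """Quality class of a concentration; None for undefined (NaN) values."""
    if conc_mg_l is None or np.isnan(conc_mg_l):
        return None
    if conc_mg_l < 0:
        raise ValidationError("concentration must be non-negative")
    return QualityClass(int(np.searchsorted(CLASS_THRESHOLDS, conc_mg_l, side="right")))


def classify_series(conc) -> np.ndarray:
    """Vectorized :func:`classify`; NaN concentrations map to -1."""
    arr = np.asarray(conc, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValidationError("concentrations must be non-negative")
    out = np.searchsorted(CLASS_THRESHOLDS, arr, side="right")
    return np.where(np.isnan(arr), -1, out).astype(int)


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 class-agreement counts and the derived accuracy statistics.

    Rows are predicted classes, columns observed classes (the printed
    layout).  User accuracy is the diagonal share of each predicted row;
    producer accuracy the diagonal share of each observed column.
    Gross errors count pairs two or more classes apart: over-prediction
    means predicted worse than observed, under-prediction the reverse.
    """

    counts: np.ndarray  # [predicted, observed]
    user_accuracy_pct: np.ndarray
    producer_accuracy_pct: np.ndarray
    overall_accuracy_pct: float
    overprediction_pct: float
    underprediction_pct: float
    n: int


def confusion(obs_classes, pred_classes) -> ConfusionMatrix:
    """Build the confusion matrix from paired class sequences."""
    obs = np.asarray([int(v) for v in obs_classes])
    pred = np.asarray([int(v) for v in pred_classes])
    if obs.shape != pred.shape:
        raise ValidationError("obs and pred class sequences differ in length")
    if obs.size == 0:
        raise ValidationError("empty class pairing")
    k = len(QualityClass)
    if np.any((obs < 0) | (obs >= k)) or np.any((pred < 0) | (pred >= k)):
        raise ValidationError("class values out of range")
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (pred, obs), 1)
    total = counts.sum()
    diag = np.diag(counts).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        user = np.where(counts.sum(axis=1) > 0, 100.0 * diag / counts.sum(axis=1), np.nan)
        producer = np.where(
            counts.sum(axis=0) > 0, 100.0 * diag / counts.sum(axis=0), np.nan
        )
    return ConfusionMatrix(
        counts=counts,
        user_accuracy_pct=user,
        producer_accuracy_pct=producer,
        overall_accuracy_pct=float(100.0 * diag.sum() / total),
        overprediction_pct=float(100.0 * np.sum(pred - obs >= 2) / total),
        underprediction_pct=float(100.0 * np.sum(obs - pred >= 2) / total),
        n=int(total),
    )


def tolerant_accuracy(obs_conc, pred_conc, tol: float = 0.5) -> float:
    """Class agreement (%) allowing a +/- ``tol`` mg/L shift of predictions.

    A pair agrees when the classes match outright, or when moving the
    predicted concentration by at most ``tol`` can land it in the
    observed class — equivalently, when the prediction falls within the
    observed class interval widened by ``tol`` on both sides.  At
    ``tol=0`` this reduces to plain classification accuracy.
    """
    obs = np.asarray(obs_conc, dtype=float)
    pred = np.asarray(pred_conc, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValidationError("empty or mismatched concentration pairing")
    if tol < 0:
        raise ValidationError("tol must be non-negative")
    obs_cls = classify_series(obs)
    lo_cls = classify_series(np.maximum(pred - tol, 0.0))
    hi_cls = classify_series(pred + tol)
    agree = (lo_cls <= obs_cls) & (obs_cls <= hi_cls)
    return float(100.0 * agree.mean())


def summarize(series) -> dict[str, float]:
    """Order statistics of a flux series: 5th/90th/95th percentile, mean, max.

    Percentiles use linear interpolation between order statistics.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty series")
    return {
        "p5": float(np.percentile(arr, 5)),
        "mean": float(arr.mean()),
        "p90": float(np.percentile(arr, 90)),
        "p95": float(np.percentile(arr, 95)),
        "max": float(arr.max()),
    }


@dataclass(frozen=True)
class QualityShareReport:
    """Length-weighted share of the network per quality outcome."""

    failing_pct: float  # share of classified length above the failing threshold
    class_shares_pct: dict[str, float]  # sums to 100 over classified length
    unclassified_length_km: float
    total_length_km: float


def network_quality_share(
    fluxes: dict[str, ReachFlux], net: Network, failing_threshold: float = 5.0
) -> QualityShareReport:
    """Share of total reach length failing good quality, and per class.

    Weighted by reach length; reaches with undefined concentration are
    reported separately and excluded from the share denominators.
    """
    lengths, concs = [], []
    for sid, fx in fluxes.items():
        lengths.append(net[sid].reach_length_km)
        concs.append(fx.concentration_mg_l)
    lengths = np.asarray(lengths, dtype=float)
    concs = np.asarray(concs, dtype=float)
    defined = ~np.isnan(concs)
    classified_len = float(lengths[defined].sum())
    total_len = float(lengths.sum())
    if classified_len == 0:
        raise ValidationError("no classified reach length in the network")
    failing = float(lengths[defined & (concs > failing_threshold)].sum())
    cls = classify_series(concs)
    shares = {
        qc.name.lower(): float(
            100.0 * lengths[defined & (cls == int(qc))].sum() / classified_len
        )
        for qc in QualityClass
    }
    return QualityShareReport(
        failing_pct=100.0 * failing / classified_len,
        class_shares_pct=shares,
        unclassified_length_km=total_len - classified_len,
        total_length_km=total_len,
    )


@dataclass(frozen=True)
class Observation:
    """One monitoring-station record (mean annual, BOD5 equivalents)."""

    station_id: str
    subbasin_id: str
    mean_conc_mg_l: float
    n_samples_per_year: int
    variant: str = "BOD5"
    load_t_y: float | None = None
    conversion_flagged: bool = False

    def __post_init__(self) -> None:
        if self.mean_conc_mg_l < 0:
            raise ValidationError("mean_conc_mg_l must be non-negative")
        if self.variant not in ("BOD5", "BOD7"):
            raise ValidationError(f"unknown BOD variant {self.variant!r}")


def conc_to_load(conc_mg_l, discharge_m3s, c: Constants = DEFAULT_CONSTANTS):
    """Annual load (t/y) of a mean concentration in a mean discharge."""
    return np.asarray(conc_mg_l, dtype=float) * c.flow_volume_factor * np.asarray(
        discharge_m3s, dtype=float
    )


def load_concentration_convert(
    obs: Observation, discharge_m3s: float, c: Constants = DEFAULT_CONSTANTS
) -> Observation:
    """Complete an observation with its load (or concentration) counterpart.

    With a positive discharge the missing quantity is filled from
    ``load = conc * 31.5576 * Q`` (and its inverse).  Non-positive
    discharge flags the record instead of raising — small, probably
    erroneous streamflows must not crash evaluation.
    """
    from dataclasses import replace

    if discharge_m3s <= 0:
        return replace(obs, conversion_flagged=True)
    if obs.load_t_y is None:
        load = float(conc_to_load(obs.mean_conc_mg_l, discharge_m3s, c))
        return replace(obs, load_t_y=load)
    conc = obs.load_t_y / (c.flow_volume_factor * discharge_m3s)
    return replace(obs, mean_conc_mg_l=float(conc))


def specific_load(load_t_y, upstream_area_km2):
    """Specific load (t/km2/y) of an annual load over its drainage area."""
    area = np.asarray(upstream_area_km2, dtype=float)
    if np.any(area <= 0):
        raise ValidationError("upstream area must be positive")
    out = np.asarray(load_t_y, dtype=float) / area
    return float(out) if out.ndim == 0 else out


def read_observations_csv(
    path, c: Constants = DEFAULT_CONSTANTS, min_samples_exclusive: int = 6
) -> pd.DataFrame:
    """Load the observation CSV, convert BOD7 records, filter small samples.

    Only records with more than ``min_samples_exclusive`` measurements
    per year are retained (smaller samples are unreliable).  BOD7
    concentrations and loads are converted to BOD5 equivalents.
    """
    df = pd.read_csv(path, dtype={"station_id": str, "subbasin_id": str})
    required = {"station_id", "subbasin_id", "mean_conc_mg_l", "n_samples"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"observations CSV lacks column(s): {sorted(missing)}")
    df = df[df["n_samples"] > min_samples_exclusive].copy()
    if "variant" in df.columns:
        is7 = df["variant"] == "BOD7"
        df.loc[is7, "mean_conc_mg_l"] = bod7_to_bod5(
            df.loc[is7, "mean_conc_mg_l"].values, c
        )
        if "load_t_y" in df.columns:
            has_load = is7 & df["load_t_y"].notna()
            df.loc[has_load, "load_t_y"] = bod7_to_bod5(
                df.loc[has_load, "load_t_y"].values, c
            )
        df["variant"] = "BOD5"
    return df.reset_index(drop=True)
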