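"""Calibratable parameters, fixed constants, and calibration ranges.

The model has ten calibratable parameters (treatment efficiencies, pathway
delays, decay rate, urban event-mean concentration, natural-area export
coefficient, and the industrial BOD/TOC ratio) plus a handful of fixed
physical constants.  :class:`ParameterSet` defaults to the calibrated
values; :data:`DEFAULT_RANGES` holds the literature-based sampling ranges
used for Latin Hypercube calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .errors import ValidationError

#: Canonical parameter ordering used for sampling matrices and reports.
PARAM_NAMES: tuple[str, ...] = (
    "eff1",
    "eff2",
    "eff3",
    "eff_sd",
    "dd_days",
    "lvst_days",
    "k20",
    "emc_u",
    "e_nat",
    "bod_toc",
)

#: Literature-based initial calibration ranges, one ``(lower, upper)`` pair
#: per parameter in :data:`PARAM_NAMES` order.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "eff1": (0.35, 0.75),
    "eff2": (0.80, 0.95),
    "eff3": (0.92, 0.98),
    "eff_sd": (0.35, 0.40),
    "dd_days": (4.0, 8.0),
    "lvst_days": (4.0, 8.0),
    "k20": (0.35, 0.60),
    "emc_u": (1.0, 21.0),
    "e_nat": (0.0, 0.5),
    "bod_toc": (0.2, 2.2),
}

_EFFICIENCIES = ("eff1", "eff2", "eff3", "eff_sd")


@dataclass(frozen=True)
class ParameterSet:
    """The ten calibratable model parameters.

    Defaults are the calibrated values.  Efficiencies are removal
    fractions in [0, 1]; ``dd_days``/``lvst_days`` are pathway delays in
    days added to the basin time lag; ``k20`` is the first-order decay
    rate at 20 degC (1/day); ``emc_u`` the urban wash-off event-mean
    concentration (mg O2/L); ``e_nat`` the natural-area export
    coefficient (t/km2/y); ``bod_toc`` the industrial BOD/TOC ratio.
    """

    eff1: float = 0.50
    eff2: float = 0.94
    eff3: float = 0.96
    eff_sd: float = 0.40
    dd_days: float = 7.0
    lvst_days: float = 7.0
    k20: float = 0.56
    emc_u: float = 11.0
    e_nat: float = 0.16
    bod_toc: float = 0.75

    def __post_init__(self) -> None:
        for name in _EFFICIENCIES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.dd_days < 0 or self.lvst_days < 0:
            raise ValidationError("pathway delays must be non-negative")
        if self.k20 <= 0:
            raise ValidationError(f"k20={self.k20} must be positive")
        if self.emc_u < 0 or self.e_nat < 0:
            raise ValidationError("emc_u and e_nat must be non-negative")
        if self.bod_toc <= 0:
            raise ValidationError(f"bod_toc={self.bod_toc} must be positive")

    def as_array(self) -> np.ndarray:
        """Parameter values as a 1-D array in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ParameterSet":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValidationError(
                f"expected {len(PARAM_NAMES)} values, got shape {values.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def replace(self, **changes: float) -> "ParameterSet":
        return replace(self, **changes)


#: The calibrated parameter set shipped as the canonical default.
CALIBRATED = ParameterSet()


@dataclass(frozen=True)
class Constants:
    """Fixed model constants, overridable but defaulting to printed values."""

    bod_per_pe_g_day: float = 60.0
    pe_per_inhabitant: float = 1.23
    sewer_loss_fraction: float = 0.10
    bod_per_lu_g_day: float = 400.0
    intensive_threshold_lu_km2: float = 25.0
    sewer_time_days: float = 4.0 / 24.0
    year_days: float = 365.25
    bod7_to_bod5_divisor: float = 1.16

    def __post_init__(self) -> None:
        if not 0.0 <= self.sewer_loss_fraction < 1.0:
            raise ValidationError("sewer_loss_fraction must lie in [0, 1)")
        for f in fields(self):
            if f.name == "sewer_loss_fraction":
                continue
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"{f.name} must be positive")

    @property
    def pe_load_t_y(self) -> float:
        """Raw BOD load of one person equivalent (t/y)."""
        return self.bod_per_pe_g_day * self.year_days / 1e6

    @property
    def lu_load_t_y(self) -> float:
        """Raw BOD load of one livestock unit (t/y)."""
        return self.bod_per_lu_g_day * self.year_days / 1e6

    @property
    def flow_volume_factor(self) -> float:
        """t/y carried by 1 m3/s at 1 mg/L: 3600*24*year_days/1e6."""
        return 3600.0 * 24.0 * self.year_days / 1e6


DEFAULT_CONSTANTS = Constants()


@dataclass(frozen=True)
class ParameterRanges:
    """Sampling bounds per parameter, defaulting to :data:`DEFAULT_RANGES`."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.bounds)
        if missing:
            raise ValidationError(f"missing range(s) for: {sorted(missing)}")
        unknown = set(self.bounds) - set(PARAM_NAMES)
        if unknown:
            raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValidationError(f"{name}: lower {lo} must be < upper {hi}")

    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in PARAM_NAMES])

    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in PARAM_NAMES])


DEFAULT_PARAMETER_RANGES = ParameterRanges()
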