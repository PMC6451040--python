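"""Per-subbasin BOD emissions (t/y) by source category.

Six categories are distinguished.  Point sources enter the main reach
directly: treated/untreated sewered domestic waste, industrial
discharges, and intensive-livestock waste (treated at secondary level).
Diffuse sources are attenuated by basin retention before reaching the
reach, each on its own pathway: disconnected domestic waste (septic
tanks and individual systems), extensive livestock, urban wash-off, and
natural-area export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import Network
from .params import Constants, DEFAULT_CONSTANTS, ParameterSet

POINT_CATEGORIES: tuple[str, ...] = (
    "domestic_point",
    "industrial",
    "livestock_intensive",
)
DIFFUSE_CATEGORIES: tuple[str, ...] = (
    "domestic_diffuse",
    "livestock_extensive",
    "urban_washoff",
    "natural",
)
CATEGORIES: tuple[str, ...] = POINT_CATEGORIES + DIFFUSE_CATEGORIES

#: Treatment levels of sewered domestic waste, worst to best.
TREATMENT_LEVELS: tuple[str, ...] = ("none", "primary", "secondary", "tertiary")

DEMOGRAPHICS_COLUMNS = (
    "pe_untreated",
    "pe_primary",
    "pe_secondary",
    "pe_tertiary",
    "pe_ias",
    "pe_sd",
)
LIVESTOCK_COLUMNS = ("lu_cattle", "lu_sheep_goat", "lu_pig", "lu_chicken")


def pathway_delay_days(category: str, p: ParameterSet, c: Constants) -> float:
    """Extra travel time (days) added to the basin time lag per pathway."""
    if category == "domestic_diffuse":
        return p.dd_days
    if category == "livestock_extensive":
        return p.lvst_days
    if category == "urban_washoff":
        return c.sewer_time_days
    if category == "natural":
        return 0.0
    raise ValidationError(f"unknown diffuse category {category!r}")


@dataclass(frozen=True)
class EmissionSet:
    """Per-subbasin BOD loads (t/y) at the point of environmental release.

    ``point`` and ``diffuse`` are dataframes indexed by subbasin id with
    one column per category; diffuse columns are implicitly tagged with
    their pathway (see :func:`pathway_delay_days`).
    """

    point: pd.DataFrame
    diffuse: pd.DataFrame

    def __post_init__(self) -> None:
        if tuple(self.point.columns) != POINT_CATEGORIES:
            raise ValidationError(f"point columns must be {POINT_CATEGORIES}")
        if tuple(self.diffuse.columns) != DIFFUSE_CATEGORIES:
            raise ValidationError(f"diffuse columns must be {DIFFUSE_CATEGORIES}")
        if not self.point.index.equals(self.diffuse.index):
            raise ValidationError("point and diffuse ids differ")
        if (self.point.values < 0).any() or (self.diffuse.values < 0).any():
            raise ValidationError("emission loads must be non-negative")

    @property
    def ids(self) -> list[str]:
        return list(self.point.index)

    def total_t_y(self) -> float:
        return float(self.point.values.sum() + self.diffuse.values.sum())

    def by_category(self) -> pd.Series:
        return pd.concat([self.point.sum(), self.diffuse.sum()])


def population_to_pe(inhabitants, c: Constants = DEFAULT_CONSTANTS):
    """Convert resident inhabitants to person equivalents (PE)."""
    x = np.asarray(inhabitants, dtype=float)
    if np.any(x < 0):
        raise ValidationError("inhabitants must be non-negative")
    out = c.pe_per_inhabitant * x
    return float(out) if np.isscalar(inhabitants) else out


def allocate_treatment_levels(
    populations: pd.Series,
    areas_km2: pd.Series,
    national_shares: dict[str, float],
    c: Constants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Distribute national treatment-level shares over subbasins by density.

    Subbasins are ranked by population density (descending); the best
    levels are filled greedily down the ranking until each national
    share — expressed in PE — is exhausted.  The subbasin straddling a
    quota boundary is split between the adjacent levels.  Equal-density
    tie groups are split proportionally, so a uniform-density region
    receives the national shares everywhere.

    Returns a dataframe indexed like ``populations`` with one PE column
    per level in :data:`TREATMENT_LEVELS`.
    """
    unknown = set(national_shares) - set(TREATMENT_LEVELS)
    if unknown:
        raise ValidationError(f"unknown treatment level(s): {sorted(unknown)}")
    total_share = sum(national_shares.values())
    if abs(total_share - 1.0) > 1e-9:
        raise ValidationError(f"national shares sum to {total_share}, expected 1")
    if np.any(populations.values < 0):
        raise ValidationError("populations must be non-negative")
    populations = populations.astype(float)
    areas = areas_km2.reindex(populations.index).astype(float)
    if areas.isna().any() or (areas <= 0).any():
        raise ValidationError("every subbasin needs a positive area")

    pe = populations * c.pe_per_inhabitant
    total_pe = float(pe.sum())
    result = pd.DataFrame(
        0.0, index=populations.index, columns=list(TREATMENT_LEVELS)
    )
    if total_pe == 0:
        return result

    # remaining PE quota per level, filled best-first
    quota = {lvl: national_shares.get(lvl, 0.0) * total_pe for lvl in TREATMENT_LEVELS}
    level_stack = [lvl for lvl in reversed(TREATMENT_LEVELS) if quota[lvl] > 0]

    density = pe / areas
    ranked = sorted(
        populations.index, key=lambda i: (-density.loc[i], str(i))
    )
    # group exact-density ties so they can be split proportionally
    groups: list[list] = []
    for sid in ranked:
        if groups and density.loc[groups[-1][0]] == density.loc[sid]:
            groups[-1].append(sid)
        else:
            groups.append([sid])

    li = 0
    for group in groups:
        remaining = {sid: float(pe.loc[sid]) for sid in group}
        while any(v > 1e-12 for v in remaining.values()) and li < len(level_stack):
            lvl = level_stack[li]
            group_left = sum(remaining.values())
            take = min(quota[lvl], group_left)
            for sid, left in remaining.items():
                share = take * left / group_left
                result.loc[sid, lvl] += share
                remaining[sid] = left - share
            quota[lvl] -= take
            if quota[lvl] <= 1e-12:
                li += 1
    return result


def _pe_raw_load(pe, c: Constants):
    """Raw (pre-treatment) BOD load of a PE count, t/y."""
    return np.asarray(pe, dtype=float) * c.pe_load_t_y


def domestic_point_emissions(
    demographics: pd.DataFrame,
    p: ParameterSet,
    c: Constants = DEFAULT_CONSTANTS,
) -> pd.Series:
    """Point-source domestic BOD per subbasin (t/y).

    Sewered waste per treatment level is reduced by sewerage losses
    (default 10%) and by the level's removal efficiency (zero for
    connected-untreated waste).
    """
    eff = {"none": 0.0, "primary": p.eff1, "secondary": p.eff2, "tertiary": p.eff3}
    cols = {"none": "pe_untreated", "primary": "pe_primary",
            "secondary": "pe_secondary", "tertiary": "pe_tertiary"}
    out = np.zeros(len(demographics))
    for level, col in cols.items():
        if col not in demographics:
            continue
        raw = _pe_raw_load(demographics[col].values, c)
        out += raw * (1.0 - c.sewer_loss_fraction) * (1.0 - eff[level])
    return pd.Series(out, index=demographics.index, name="domestic_point")


def domestic_diffuse_emissions(
    demographics: pd.DataFrame,
    p: ParameterSet,
    c: Constants = DEFAULT_CONSTANTS,
) -> pd.Series:
    """Disconnected domestic BOD per subbasin (t/y), delayed-domestic path.

    Scattered dwellings drain through septic tanks (``eff_sd``);
    individual appropriate systems are treated as primary (``eff1``).
    No sewerage loss applies — these loads never enter a sewer.
    """
    out = np.zeros(len(demographics))
    if "pe_sd" in demographics:
        out += _pe_raw_load(demographics["pe_sd"].values, c) * (1.0 - p.eff_sd)
    if "pe_ias" in demographics:
        out += _pe_raw_load(demographics["pe_ias"].values, c) * (1.0 - p.eff1)
    return pd.Series(out, index=demographics.index, name="domestic_diffuse")


def industrial_emissions(toc_t_y, p: ParameterSet):
    """Industrial BOD from TOC point emissions: BOD = TOC * bod/toc."""
    toc = np.asarray(toc_t_y, dtype=float)
    if np.any(toc < 0):
        raise ValidationError("TOC emissions must be non-negative")
    out = toc * p.bod_toc
    if isinstance(toc_t_y, pd.Series):
        return pd.Series(out, index=toc_t_y.index, name="industrial")
    return float(out) if np.isscalar(toc_t_y) else out


def livestock_emissions(
    livestock: pd.DataFrame,
    areas_km2: pd.Series,
    p: ParameterSet,
    c: Constants = DEFAULT_CONSTANTS,
    combined_ruminant_density: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """Split livestock BOD into intensive (point) and extensive (diffuse).

    Pig and chicken units are always intensive.  Cattle and sheep/goat
    units are intensive where their density exceeds the threshold
    (default 25 LU/km2) — by default judged on the combined ruminant
    density; set ``combined_ruminant_density=False`` for a per-type
    test.  Intensive waste is treated at secondary level and enters the
    reach as a point source; extensive waste is released raw on the
    delayed livestock pathway.
    """
    areas = areas_km2.reindex(livestock.index).astype(float)
    if areas.isna().any() or (areas <= 0).any():
        raise ValidationError("every subbasin needs a positive area")
    lu = {
        col: livestock[col].values.astype(float) if col in livestock else 0.0
        for col in LIVESTOCK_COLUMNS
    }
    for col, v in lu.items():
        if np.any(np.asarray(v) < 0):
            raise ValidationError(f"{col} must be non-negative")

    always_intensive = lu["lu_pig"] + lu["lu_chicken"]
    cattle, sheep = lu["lu_cattle"], lu["lu_sheep_goat"]
    if combined_ruminant_density:
        dense = (cattle + sheep) / areas.values > c.intensive_threshold_lu_km2
        intensive_ruminant = np.where(dense, cattle + sheep, 0.0)
    else:
        cattle_dense = cattle / areas.values > c.intensive_threshold_lu_km2
        sheep_dense = sheep / areas.values > c.intensive_threshold_lu_km2
        intensive_ruminant = np.where(cattle_dense, cattle, 0.0) + np.where(
            sheep_dense, sheep, 0.0
        )
    extensive_ruminant = cattle + sheep - intensive_ruminant

    intensive = (always_intensive + intensive_ruminant) * c.lu_load_t_y * (1.0 - p.eff2)
    extensive = extensive_ruminant * c.lu_load_t_y
    idx = livestock.index
    return (
        pd.Series(intensive, index=idx, name="livestock_intensive"),
        pd.Series(extensive, index=idx, name="livestock_extensive"),
    )


def urban_washoff(urban_runoff_m3s, p: ParameterSet, c: Constants = DEFAULT_CONSTANTS):
    """Urban wash-off BOD (t/y) from mean annual urban runoff (m3/s)."""
    r = np.asarray(urban_runoff_m3s, dtype=float)
    if np.any(r < 0):
        raise ValidationError("urban runoff must be non-negative")
    out = p.emc_u * r * c.flow_volume_factor
    if isinstance(urban_runoff_m3s, pd.Series):
        return pd.Series(out, index=urban_runoff_m3s.index, name="urban_washoff")
    return float(out) if np.isscalar(urban_runoff_m3s) else out


def natural_emissions(natural_area_km2, p: ParameterSet):
    """Natural-area BOD export (t/y): export coefficient times area."""
    a = np.asarray(natural_area_km2, dtype=float)
    if np.any(a < 0):
        raise ValidationError("natural area must be non-negative")
    out = p.e_nat * a
    if isinstance(natural_area_km2, pd.Series):
        return pd.Series(out, index=natural_area_km2.index, name="natural")
    return float(out) if np.isscalar(natural_area_km2) else out


@dataclass(frozen=True)
class SourceData:
    """Raw per-subbasin source drivers, each indexed by subbasin id.

    Any table may be None (that source is absent).  ``demographics``
    needs the PE columns in :data:`DEMOGRAPHICS_COLUMNS`, ``livestock``
    the LU columns in :data:`LIVESTOCK_COLUMNS`, ``industrial_toc`` a
    single ``toc_t_y`` column or Series.
    """

    demographics: pd.DataFrame | None = None
    livestock: pd.DataFrame | None = None
    industrial_toc: pd.Series | None = None


def _check_ids(name: str, index: pd.Index, net: Network) -> None:
    unknown = [i for i in index if i not in net]
    if unknown:
        raise ValidationError(f"{name} table references unknown subbasin(s): {unknown[:5]}")


def compute_emissions(
    net: Network,
    data: SourceData,
    p: ParameterSet,
    c: Constants = DEFAULT_CONSTANTS,
    sewer_loss_reemit: bool = False,
) -> EmissionSet:
    """Assemble the full :class:`EmissionSet` over a network.

    Missing subbasins in a driver table contribute zero.  With
    ``sewer_loss_reemit``, the sewerage-loss fraction of connected
    domestic waste re-enters the system untreated on the delayed
    domestic pathway instead of being removed.
    """
    ids = pd.Index(net.topo_order, name="id")
    point = pd.DataFrame(0.0, index=ids, columns=list(POINT_CATEGORIES))
    diffuse = pd.DataFrame(0.0, index=ids, columns=list(DIFFUSE_CATEGORIES))

    areas = pd.Series({sid: net[sid].area_km2 for sid in ids})
    urban_runoff = pd.Series({sid: net[sid].urban_runoff_m3s for sid in ids})
    natural_area = pd.Series({sid: net[sid].natural_area_km2 for sid in ids})

    if data.demographics is not None:
        demo = data.demographics
        _check_ids("demographics", demo.index, net)
        demo = demo.reindex(ids, fill_value=0.0)
        point["domestic_point"] = domestic_point_emissions(demo, p, c)
        diffuse["domestic_diffuse"] = domestic_diffuse_emissions(demo, p, c)
        if sewer_loss_reemit:
            connected_cols = ["pe_untreated", "pe_primary", "pe_secondary", "pe_tertiary"]
            connected = demo[[col for col in connected_cols if col in demo]].sum(axis=1)
            diffuse["domestic_diffuse"] += (
                _pe_raw_load(connected.values, c) * c.sewer_loss_fraction
            )

    if data.industrial_toc is not None:
        toc = data.industrial_toc
        _check_ids("industrial", toc.index, net)
        point["industrial"] = industrial_emissions(toc, p).reindex(ids, fill_value=0.0)

    if data.livestock is not None:
        lv = data.livestock
        _check_ids("livestock", lv.index, net)
        lv = lv.reindex(ids, fill_value=0.0)
        intensive, extensive = livestock_emissions(lv, areas, p, c)
        point["livestock_intensive"] = intensive
        diffuse["livestock_extensive"] = extensive

    diffuse["urban_washoff"] = urban_washoff(urban_runoff, p, c)
    diffuse["natural"] = natural_emissions(natural_area, p)
    return EmissionSet(point=point, diffuse=diffuse)


def read_demographics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str}).set_index("id")
    return df


def read_livestock_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str}).set_index("id")


def read_industrial_csv(path) -> pd.Series:
    df = pd.read_csv(path, dtype={"id": str}).set_index("id")
    # several facilities may share a subbasin
    return df.groupby(level=0)["toc_t_y"].sum()
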