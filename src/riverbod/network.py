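"""Semi-distributed river network: subbasins, topology, and travel times.

Each subbasin comprises one main reach and the land draining into it.
Reaches are linked from upstream to the outlet; the downstream graph must
be a forest (each subbasin has at most one downstream neighbour, no
cycles).  Subbasins draining directly to the sea carry the reserved
sentinel :data:`SEA` as their ``downstream_id``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ReferenceError_, TopologyError, ValidationError

#: Reserved downstream sentinel marking a sea outlet.
SEA = "sea"

#: Coefficients of the basin time-lag power law T_B = 0.43 * A^0.418 (hours).
TIME_LAG_COEF = 0.43
TIME_LAG_EXP = 0.418


@dataclass(frozen=True)
class Subbasin:
    """One subbasin: a main reach plus the land that drains into it.

    ``reach_travel_time_days`` (if given) always wins over a velocity;
    otherwise ``velocity_ms`` or a :class:`VelocityModel` is needed to
    obtain the reach travel time.
    """

    id: str
    downstream_id: str = SEA
    area_km2: float = 1.0
    natural_area_km2: float = 0.0
    urban_runoff_m3s: float = 0.0
    reach_length_km: float = 0.0
    discharge_m3s: float = 0.0
    water_temp_C: float = 20.0
    reach_travel_time_days: float | None = None
    velocity_ms: float | None = None

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValidationError(f"subbasin {self.id}: area_km2 must be > 0")
        if not 0.0 <= self.natural_area_km2 <= self.area_km2:
            raise ValidationError(
                f"subbasin {self.id}: natural_area_km2 must lie in [0, area_km2]"
            )
        if self.discharge_m3s < 0:
            raise ValidationError(f"subbasin {self.id}: discharge_m3s must be >= 0")
        if self.reach_length_km < 0:
            raise ValidationError(f"subbasin {self.id}: reach_length_km must be >= 0")
        if self.urban_runoff_m3s < 0:
            raise ValidationError(f"subbasin {self.id}: urban_runoff_m3s must be >= 0")
        if self.reach_travel_time_days is not None and self.reach_travel_time_days < 0:
            raise ValidationError(
                f"subbasin {self.id}: reach_travel_time_days must be >= 0"
            )
        if self.velocity_ms is not None and self.velocity_ms <= 0:
            raise ValidationError(f"subbasin {self.id}: velocity_ms must be > 0")

    @property
    def is_outlet(self) -> bool:
        return self.downstream_id == SEA


@dataclass(frozen=True)
class VelocityModel:
    """Power-law velocity from discharge, v = a * Q^b (m/s from m3/s).

    The default coefficients are pragmatic placeholders — they are NOT
    taken from any calibrated hydraulic relationship and should be
    overridden for real applications.  A precomputed reach travel time
    on a subbasin always takes precedence over this model.
    """

    a: float = 0.30
    b: float = 0.20

    def velocity(self, discharge_m3s: float) -> float:
        if discharge_m3s <= 0:
            raise ConfigurationError(
                "velocity model needs discharge_m3s > 0 to estimate velocity"
            )
        return self.a * discharge_m3s**self.b


class Network:
    """Validated river network over a set of :class:`Subbasin` objects.

    Exposes the cached topological order (headwaters first), outlet ids,
    and upstream/downstream lookups.  Construction fails on cycles,
    dangling downstream references, and duplicate ids.
    """

    def __init__(self, subbasins: Iterable[Subbasin]):
        self.subbasins: dict[str, Subbasin] = {}
        for sb in subbasins:
            if sb.id in self.subbasins:
                raise ValidationError(f"duplicate subbasin id {sb.id!r}")
            if sb.id == SEA:
                raise ValidationError(f"subbasin id {SEA!r} is reserved")
            self.subbasins[sb.id] = sb
        if not self.subbasins:
            raise ValidationError("network needs at least one subbasin")

        for sb in self.subbasins.values():
            if not sb.is_outlet and sb.downstream_id not in self.subbasins:
                raise ReferenceError_(
                    f"subbasin {sb.id!r} drains to unknown id {sb.downstream_id!r}"
                )

        g = nx.DiGraph()
        g.add_nodes_from(self.subbasins)
        g.add_edges_from(
            (sb.id, sb.downstream_id)
            for sb in self.subbasins.values()
            if not sb.is_outlet
        )
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise TopologyError(
                f"downstream graph contains a cycle through {cycle[0][0]!r}"
            )
        self._graph = g
        # ties broken by id for a deterministic order
        self.topo_order: list[str] = list(
            nx.lexicographical_topological_sort(g)
        )
        self.outlets: list[str] = [
            sb.id for sb in self.subbasins.values() if sb.is_outlet
        ]
        self._upstream: dict[str, list[str]] = {sid: [] for sid in self.subbasins}
        for sb in self.subbasins.values():
            if not sb.is_outlet:
                self._upstream[sb.downstream_id].append(sb.id)

    def __len__(self) -> int:
        return len(self.subbasins)

    def __iter__(self) -> Iterator[Subbasin]:
        return iter(self.subbasins.values())

    def __contains__(self, sid: str) -> bool:
        return sid in self.subbasins

    def __getitem__(self, sid: str) -> Subbasin:
        return self.subbasins[sid]

    def upstream(self, sid: str) -> list[str]:
        """Ids of subbasins draining directly into ``sid``."""
        return list(self._upstream[sid])

    def downstream(self, sid: str) -> str:
        """Downstream id of ``sid`` (:data:`SEA` for outlets)."""
        return self.subbasins[sid].downstream_id

    @property
    def ids(self) -> list[str]:
        return list(self.subbasins)


_SUBBASIN_COLUMNS = {
    "area_km2",
    "natural_area_km2",
    "urban_runoff_m3s",
    "reach_length_km",
    "discharge_m3s",
    "water_temp_C",
    "reach_travel_time_days",
    "velocity_ms",
}


def build_network(table: pd.DataFrame | Iterable[Mapping]) -> Network:
    """Build a validated :class:`Network` from tabular subbasin records.

    Accepts a dataframe or an iterable of mappings with the
    :class:`Subbasin` fields.  Empty/NaN ``downstream_id`` values are
    read as sea outlets.
    """
    if isinstance(table, pd.DataFrame):
        records = table.to_dict(orient="records")
    else:
        records = [dict(r) for r in table]
    subbasins = []
    for rec in records:
        if "id" not in rec:
            raise ValidationError("subbasin record lacks an 'id' field")
        kwargs: dict = {"id": str(rec["id"])}
        down = rec.get("downstream_id", SEA)
        if down is None or (isinstance(down, float) and np.isnan(down)) or down == "":
            down = SEA
        kwargs["downstream_id"] = str(down)
        for col in _SUBBASIN_COLUMNS:
            if col in rec and rec[col] is not None:
                val = rec[col]
                if isinstance(val, str) and val.strip() == "":
                    continue
                val = float(val)
                if np.isnan(val):
                    continue
                kwargs[col] = val
        subbasins.append(Subbasin(**kwargs))
    return Network(subbasins)


def read_subbasins_csv(path) -> Network:
    """Read the subbasin attribute CSV (UTF-8, header row) into a Network."""
    return build_network(pd.read_csv(path, dtype={"id": str, "downstream_id": str}))


def network_to_frame(net: Network) -> pd.DataFrame:
    """Inverse of :func:`build_network` for writing the subbasin CSV."""
    rows = []
    for sid in net.topo_order:
        sb = net[sid]
        rows.append(
            {
                "id": sb.id,
                "downstream_id": "" if sb.is_outlet else sb.downstream_id,
                "area_km2": sb.area_km2,
                "natural_area_km2": sb.natural_area_km2,
                "urban_runoff_m3s": sb.urban_runoff_m3s,
                "reach_length_km": sb.reach_length_km,
                "discharge_m3s": sb.discharge_m3s,
                "water_temp_C": sb.water_temp_C,
                "reach_travel_time_days": sb.reach_travel_time_days,
                "velocity_ms": sb.velocity_ms,
            }
        )
    return pd.DataFrame(rows)


def shreve_order(net: Network) -> dict[str, int]:
    """Shreve magnitude: headwaters are 1, junctions sum upstream orders."""
    order: dict[str, int] = {}
    for sid in net.topo_order:
        ups = net.upstream(sid)
        order[sid] = 1 if not ups else sum(order[u] for u in ups)
    return order


def basin_time_lag(area_km2):
    """Subbasin time lag (hours) from drainage area (km2).

    Empirical power law ``0.43 * A^0.418``; callers convert to days
    before using it as a travel time.  Accepts scalars or arrays.
    """
    area = np.asarray(area_km2, dtype=float)
    if np.any(area <= 0):
        raise ValidationError("area_km2 must be positive")
    out = TIME_LAG_COEF * area**TIME_LAG_EXP
    return float(out) if np.isscalar(area_km2) else out


def reach_travel_time(sb: Subbasin, velocity_model: VelocityModel | None = None) -> float:
    """Reach travel time in days from length and velocity.

    Resolution order: precomputed ``reach_travel_time_days`` wins; then
    ``velocity_ms``; then the optional power-law ``velocity_model``.
    A zero-length reach has zero travel time regardless.
    """
    if sb.reach_travel_time_days is not None:
        return sb.reach_travel_time_days
    if sb.reach_length_km == 0:
        return 0.0
    if sb.velocity_ms is not None:
        velocity = sb.velocity_ms
    elif velocity_model is not None:
        velocity = velocity_model.velocity(sb.discharge_m3s)
    else:
        raise ConfigurationError(
            f"subbasin {sb.id!r}: no reach_travel_time_days, velocity_ms, "
            "or velocity model available"
        )
    return sb.reach_length_km * 1000.0 / velocity / 86400.0
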