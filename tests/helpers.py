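"""Shared test utilities: random network builders and brute-force oracles.

The oracles here deliberately avoid the package's routing code paths:
they recompute everything from the printed formulas with plain ``math``
so that routed results are checked against an independent derivation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from riverbod.emissions import DIFFUSE_CATEGORIES, POINT_CATEGORIES, EmissionSet
from riverbod.network import Network, Subbasin
from riverbod.params import Constants, ParameterSet


def random_network(rng: np.random.Generator, n: int, n_outlets: int = 1) -> Network:
    """Random tree network with random physical attributes."""
    n_outlets = min(n_outlets, n)
    subbasins = []
    for i in range(n):
        down = "sea" if i < n_outlets else f"n{int(rng.integers(0, i))}"
        subbasins.append(
            Subbasin(
                id=f"n{i}",
                downstream_id=down,
                area_km2=float(rng.uniform(0.5, 20.0)),
                natural_area_km2=0.0,
                urban_runoff_m3s=float(rng.uniform(0.0, 0.5)),
                reach_length_km=float(rng.uniform(0.0, 20.0)),
                discharge_m3s=float(rng.uniform(0.1, 50.0)),
                water_temp_C=float(rng.uniform(5.0, 25.0)),
                reach_travel_time_days=float(rng.uniform(0.0, 0.5)),
            )
        )
    # fix natural areas within [0, area]
    fixed = [
        Subbasin(
            **{
                **sb.__dict__,
                "natural_area_km2": float(rng.uniform(0.0, sb.area_km2)),
            }
        )
        for sb in subbasins
    ]
    return Network(fixed)


def random_emissions(rng: np.random.Generator, net: Network) -> EmissionSet:
    """Random non-negative loads in every category, some zeros."""
    ids = pd.Index(net.topo_order, name="id")
    point = pd.DataFrame(
        rng.uniform(0.0, 50.0, size=(len(ids), len(POINT_CATEGORIES)))
        * (rng.random((len(ids), len(POINT_CATEGORIES))) > 0.3),
        index=ids,
        columns=list(POINT_CATEGORIES),
    )
    diffuse = pd.DataFrame(
        rng.uniform(0.0, 50.0, size=(len(ids), len(DIFFUSE_CATEGORIES)))
        * (rng.random((len(ids), len(DIFFUSE_CATEGORIES))) > 0.3),
        index=ids,
        columns=list(DIFFUSE_CATEGORIES),
    )
    return EmissionSet(point=point, diffuse=diffuse)


def _pathway_delay(cat: str, p: ParameterSet, c: Constants) -> float:
    return {
        "domestic_diffuse": p.dd_days,
        "livestock_extensive": p.lvst_days,
        "urban_washoff": c.sewer_time_days,
        "natural": 0.0,
    }[cat]


def brute_force_outlet_loads(
    net: Network, em: EmissionSet, p: ParameterSet, c: Constants
) -> dict[str, dict[str, float]]:
    """Independent path-product enumeration of loads delivered to sea.

    For every (subbasin, category) pair: the diffuse load is first
    decayed over the basin time lag plus its pathway delay, then every
    load is multiplied by exp(-k*TT) for each reach on the path from its
    subbasin to the outlet.  All factors are recomputed with ``math``.
    """
    reach_factor = {}
    k_t = {}
    for sid in net.ids:
        sb = net[sid]
        k = p.k20 * 1.047 ** (sb.water_temp_C - 20.0)
        k_t[sid] = k
        tt_r = sb.reach_travel_time_days
        assert tt_r is not None, "oracle expects precomputed reach travel times"
        reach_factor[sid] = math.exp(-k * tt_r)

    totals: dict[str, dict[str, float]] = {
        out: {cat: 0.0 for cat in POINT_CATEGORIES + DIFFUSE_CATEGORIES}
        for out in net.outlets
    }
    for sid in net.ids:
        t_b_days = 0.43 * net[sid].area_km2**0.418 / 24.0
        path = [sid]
        while not net[path[-1]].is_outlet:
            path.append(net.downstream(path[-1]))
        transport = math.prod(reach_factor[r] for r in path)
        outlet = path[-1]
        for cat in POINT_CATEGORIES:
            totals[outlet][cat] += float(em.point.at[sid, cat]) * transport
        for cat in DIFFUSE_CATEGORIES:
            basin = math.exp(-k_t[sid] * (t_b_days + _pathway_delay(cat, p, c)))
            totals[outlet][cat] += float(em.diffuse.at[sid, cat]) * basin * transport
    return totals


def count_upstream_leaves(net: Network, sid: str) -> int:
    """Brute-force Shreve magnitude: number of headwater leaves above sid."""
    ups = net.upstream(sid)
    if not ups:
        return 1
    return sum(count_upstream_leaves(net, u) for u in ups)
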