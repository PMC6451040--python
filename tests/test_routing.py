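import math

import numpy as np
import pandas as pd
import pytest

from riverbod import (
    CALIBRATED,
    Network,
    ParameterSet,
    Subbasin,
    attenuate,
    basin_attenuation,
    concentration,
    decay_rate,
    fluxes_to_frame,
    route_network,
    sea_loads,
)
from riverbod.emissions import DIFFUSE_CATEGORIES, POINT_CATEGORIES, EmissionSet
from riverbod.errors import ValidationError

from helpers import brute_force_outlet_loads, random_emissions, random_network


def emission_frame(net, point=None, diffuse=None):
    ids = pd.Index(net.topo_order, name="id")
    pt = pd.DataFrame(0.0, index=ids, columns=list(POINT_CATEGORIES))
    df = pd.DataFrame(0.0, index=ids, columns=list(DIFFUSE_CATEGORIES))
    for (sid, cat), v in (point or {}).items():
        pt.loc[sid, cat] = v
    for (sid, cat), v in (diffuse or {}).items():
        df.loc[sid, cat] = v
    return EmissionSet(point=pt, diffuse=df)


class TestDecayRate:
    def test_identity_at_20C(self):
        assert decay_rate(0.56, 20.0) == 0.56
        assert decay_rate(0.35, 20.0) == 0.35

    def test_cooling_slows_decay(self):
        assert decay_rate(0.56, 10.0) == pytest.approx(0.3538, abs=5e-4)

    def test_nonpositive_k20_rejected(self):
        with pytest.raises(ValidationError):
            decay_rate(0.0, 20.0)


class TestAttenuate:
    def test_retention_endpoints(self):
        # seven-day delay at the low/high temperature-adjusted rates
        assert attenuate(100.0, 0.29, 7.0) == pytest.approx(13.1336, abs=1e-3)
        assert attenuate(100.0, 0.49, 7.0) == pytest.approx(3.2387, abs=1e-3)

    def test_zero_travel_time(self):
        assert attenuate(42.0, 0.56, 0.0) == 42.0

    def test_composition(self):
        a = attenuate(attenuate(100.0, 0.4, 1.5), 0.4, 2.5)
        assert a == pytest.approx(attenuate(100.0, 0.4, 4.0), rel=1e-12)


class TestBasinAttenuation:
    def test_natural_pathway_uses_time_lag_only(self, params):
        # area chosen so T_B = 0.04 days exactly; temp drives k_T = 0.35
        area = (0.04 * 24.0 / 0.43) ** (1.0 / 0.418)
        temp = 20.0 + math.log(0.35 / params.k20) / math.log(1.047)
        net = Network([Subbasin(id="a", area_km2=area, water_temp_C=temp,
                                natural_area_km2=area / 2, reach_travel_time_days=0.0)])
        em = emission_frame(net, diffuse={("a", "natural"): 1.0})
        out = basin_attenuation(em, net, params)
        assert out.loc["a", "natural"] == pytest.approx(math.exp(-0.35 * 0.04), rel=1e-6)

    def test_domestic_diffuse_seven_day_delay(self, params):
        # tiny basin (T_B ~ 0) at k_T = 0.35: about 8.6% delivered
        temp = 20.0 + math.log(0.35 / params.k20) / math.log(1.047)
        net = Network([Subbasin(id="a", area_km2=1e-6, water_temp_C=temp,
                                reach_travel_time_days=0.0)])
        em = emission_frame(net, diffuse={("a", "domestic_diffuse"): 100.0})
        out = basin_attenuation(em, net, params)
        assert out.loc["a", "domestic_diffuse"] == pytest.approx(8.6294, abs=2e-2)

    def test_zero_loads_deliver_zero(self, params, chain3):
        em = emission_frame(chain3)
        out = basin_attenuation(em, chain3, params)
        assert (out.values == 0.0).all()

    def test_urban_four_hour_delay_shorter_than_domestic(self, params, chain3):
        em = emission_frame(
            chain3,
            diffuse={("a", "urban_washoff"): 10.0, ("a", "domestic_diffuse"): 10.0},
        )
        out = basin_attenuation(em, chain3, params)
        assert out.loc["a", "urban_washoff"] > out.loc["a", "domestic_diffuse"]


class TestConcentration:
    def test_definitional_constant(self):
        assert concentration(31.5576, 1.0) == pytest.approx(1.0)

    def test_inverse_of_urban_washoff_example(self):
        assert concentration(347.1336, 1.0) == pytest.approx(11.0)

    def test_zero_load(self):
        assert concentration(0.0, 1.0) == 0.0

    def test_zero_discharge_flagged_not_raised(self):
        assert np.isnan(concentration(10.0, 0.0))


class TestRouteNetwork:
    def test_single_point_source_no_reach_decay(self, params):
        net = Network([Subbasin(id="a", reach_travel_time_days=0.0, discharge_m3s=1.0)])
        em = emission_frame(net, point={("a", "industrial"): 10.0})
        fluxes = route_network(net, em, params)
        assert fluxes["a"].outflux_t_y == pytest.approx(10.0)
        assert fluxes["a"].influx_t_y == 0.0

    def test_chain_with_half_life_reaches(self):
        # two reaches, each with k*TT = ln 2: an 8 t/y source at the head
        # of the first arrives at the outlet as 8 * 0.25 = 2 t/y
        p = CALIBRATED
        tt = math.log(2.0) / p.k20
        net = Network(
            [
                Subbasin(id="up", downstream_id="down", reach_travel_time_days=tt,
                         water_temp_C=20.0),
                Subbasin(id="down", reach_travel_time_days=tt, water_temp_C=20.0),
            ]
        )
        em = emission_frame(net, point={("up", "industrial"): 8.0})
        fluxes = route_network(net, em, p)
        assert fluxes["up"].outflux_t_y == pytest.approx(4.0)
        assert fluxes["down"].outflux_t_y == pytest.approx(2.0)

    def test_zero_emissions_zero_fluxes(self, params, chain3):
        em = emission_frame(chain3)
        fluxes = route_network(chain3, em, params)
        for fx in fluxes.values():
            assert fx.outflux_t_y == 0.0
            assert fx.influx_t_y == 0.0

    def test_id_mismatch_rejected(self, params, chain3):
        other = Network([Subbasin(id="zz", reach_travel_time_days=0.0)])
        em = emission_frame(other)
        with pytest.raises(ValidationError, match="ids"):
            route_network(chain3, em, params)

    def test_outflux_never_exceeds_head_load(self, params, rng):
        net = random_network(rng, 30)
        em = random_emissions(rng, net)
        fluxes = route_network(net, em, params)
        for fx in fluxes.values():
            head = fx.influx_t_y + fx.local_point_t_y + fx.local_diffuse_t_y
            assert fx.outflux_t_y <= head + 1e-12
            assert fx.outflux_t_y >= 0.0

    def test_by_source_sums_to_outflux(self, params, rng):
        net = random_network(rng, 40)
        em = random_emissions(rng, net)
        for fx in route_network(net, em, params).values():
            assert sum(fx.by_source.values()) == pytest.approx(
                fx.outflux_t_y, rel=1e-9, abs=1e-12
            )

    def test_half_entry_decays_local_loads_less(self, params):
        net = Network([Subbasin(id="a", reach_travel_time_days=1.0, water_temp_C=20.0)])
        em = emission_frame(net, point={("a", "industrial"): 10.0})
        full = route_network(net, em, params, local_entry="head")["a"].outflux_t_y
        half = route_network(net, em, params, local_entry="half")["a"].outflux_t_y
        assert half == pytest.approx(10.0 * math.exp(-params.k20 / 2.0))
        assert half > full

    def test_matches_brute_force_oracle(self, params, constants, rng):
        for _ in range(25):
            net = random_network(rng, int(rng.integers(2, 21)),
                                 n_outlets=int(rng.integers(1, 3)))
            em = random_emissions(rng, net)
            fluxes = route_network(net, em, params, constants)
            oracle = brute_force_outlet_loads(net, em, params, constants)
            for out_id, by_cat in oracle.items():
                for cat, expected in by_cat.items():
                    assert fluxes[out_id].by_source[cat] == pytest.approx(
                        expected, rel=1e-9, abs=1e-12
                    )

    def test_routing_linearity_over_categories(self, params, rng):
        # routing each category alone and summing equals routing together
        net = random_network(rng, 25)
        em = random_emissions(rng, net)
        together = route_network(net, em, params)
        summed = {sid: 0.0 for sid in net.ids}
        for cat in POINT_CATEGORIES + DIFFUSE_CATEGORIES:
            pt = em.point.copy() * 0.0
            df = em.diffuse.copy() * 0.0
            if cat in POINT_CATEGORIES:
                pt[cat] = em.point[cat]
            else:
                df[cat] = em.diffuse[cat]
            single = route_network(net, EmissionSet(point=pt, diffuse=df), params)
            for sid in net.ids:
                summed[sid] += single[sid].outflux_t_y
        for sid in net.ids:
            assert summed[sid] == pytest.approx(
                together[sid].outflux_t_y, rel=1e-9, abs=1e-12
            )


class TestSeaLoads:
    def test_single_outlet_total(self, params, chain3):
        em = emission_frame(chain3, point={("a", "industrial"): 5.0})
        fluxes = route_network(chain3, em, params)
        report = sea_loads(chain3, fluxes)
        assert report.total_t_y == pytest.approx(fluxes["c"].outflux_t_y)

    def test_single_source_category(self, params, chain3):
        em = emission_frame(chain3, diffuse={("b", "natural"): 5.0})
        report = sea_loads(chain3, route_network(chain3, em, params))
        assert report.by_source["natural"] == pytest.approx(report.total_t_y)
        for cat, v in report.by_source.items():
            if cat != "natural":
                assert v == 0.0

    def test_coastal_flag_on_shreve_one_outlet(self, params):
        net = Network(
            [
                Subbasin(id="h1", downstream_id="big", reach_travel_time_days=0.0),
                Subbasin(id="h2", downstream_id="big", reach_travel_time_days=0.0),
                Subbasin(id="big", reach_travel_time_days=0.0),  # Shreve order 2
                Subbasin(id="tiny", reach_travel_time_days=0.0),  # headwater to sea
            ]
        )
        em = emission_frame(net, point={("tiny", "industrial"): 1.0,
                                        ("h1", "industrial"): 1.0})
        report = sea_loads(net, route_network(net, em, params))
        assert bool(report.per_outlet.loc["tiny", "coastal"]) is True
        assert bool(report.per_outlet.loc["big", "coastal"]) is False
        assert report.coastal_total_t_y == pytest.approx(1.0)

    def test_source_shares_sum_to_100(self, params, rng):
        net = random_network(rng, 30, n_outlets=3)
        em = random_emissions(rng, net)
        report = sea_loads(net, route_network(net, em, params))
        assert sum(report.source_shares_pct.values()) == pytest.approx(100.0)


class TestMassMonotonicity:
    """Sea delivery responds monotonically to each parameter."""

    def _sea_total(self, net, em_builder, p):
        from riverbod import compute_emissions

        em = em_builder(p)
        return sea_loads(net, route_network(net, em, p)).total_t_y

    def test_monotone_in_parameters(self, rng):
        from riverbod import SourceData, compute_emissions

        net = random_network(rng, 40, n_outlets=2)
        ids = pd.Index(net.topo_order, name="id")
        demo = pd.DataFrame(
            rng.uniform(0, 500, size=(len(ids), 6)),
            index=ids,
            columns=["pe_untreated", "pe_primary", "pe_secondary", "pe_tertiary",
                     "pe_ias", "pe_sd"],
        )
        lv = pd.DataFrame(
            rng.uniform(0, 100, size=(len(ids), 4)),
            index=ids,
            columns=["lu_cattle", "lu_sheep_goat", "lu_pig", "lu_chicken"],
        )
        toc = pd.Series(rng.uniform(0, 50, len(ids)), index=ids, name="toc_t_y")
        data = SourceData(demographics=demo, livestock=lv, industrial_toc=toc)

        def builder(p):
            return compute_emissions(net, data, p)

        base = CALIBRATED.replace(eff1=0.5, eff2=0.9, eff3=0.95, eff_sd=0.38)
        t0 = self._sea_total(net, builder, base)
        decreasing = {"k20": 0.59, "dd_days": 8.0, "lvst_days": 8.0, "eff1": 0.7,
                      "eff2": 0.95, "eff3": 0.97, "eff_sd": 0.40}
        for name, worse in decreasing.items():
            t1 = self._sea_total(net, builder, base.replace(**{name: worse}))
            assert t1 <= t0 + 1e-9, name
        increasing = {"emc_u": 20.0, "e_nat": 0.5, "bod_toc": 2.0}
        for name, more in increasing.items():
            t1 = self._sea_total(net, builder, base.replace(**{name: more}))
            assert t1 >= t0 - 1e-9, name


def test_fluxes_to_frame_roundtrip(params, chain3):
    em = emission_frame(chain3, point={("a", "industrial"): 5.0})
    fluxes = route_network(chain3, em, params)
    frame = fluxes_to_frame(fluxes)
    assert set(frame.index) == {"a", "b", "c"}
    assert frame.loc["c", "outflux_t_y"] == pytest.approx(fluxes["c"].outflux_t_y)
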