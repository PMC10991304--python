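"""Accounting chain: units, mass conservation, linearity, missing-data rules."""

import dataclasses
import math

import pytest
from hypothesis import given, settings, strategies as st

import strawinv as si
from strawinv.inventory import CityRecord, DisposalShares, mass_balance_ok
from strawinv.regions import UnknownProvinceError
from strawinv.yield_model import StrawYieldModel


def ok_city(city_id="c1", province="Henan", year=2011, area=100.0, grain=5000.0,
            straw=4000.0):
    return CityRecord(city_id, province, si.region_of_province(province), year,
                      area, grain, straw_yield_per_ha=straw)


FLAT = {r: StrawYieldModel(r, a=4000.0, b=0.0, n_obs=10, r_squared=1.0,
                           residual_sd=0.0) for r in si.Region}


class TestRegionOfProvince:
    @pytest.mark.parametrize("province,region", [
        ("Henan", si.Region.CC), ("Xinjiang", si.Region.NC),
        ("Sichuan", si.Region.SC), ("Beijing", si.Region.CC),
    ])
    def test_listed_provinces_map_to_their_zone(self, province, region):
        assert si.region_of_province(province) == region

    @pytest.mark.parametrize("province", ["Hunan", "Tianjin", "Inner Mongolia", ""])
    def test_unlisted_provinces_are_refused(self, province):
        with pytest.raises(UnknownProvinceError):
            si.region_of_province(province)

    def test_zone_province_lists_are_disjoint(self):
        from strawinv.regions import REGION_PROVINCES
        all_provinces = [p for provs in REGION_PROVINCES.values() for p in provs]
        assert len(all_provinces) == len(set(all_provinces)) == 18


class TestTotalStrawYield:
    def test_unit_chain_kg_per_ha_times_1000ha(self):
        # 4000 kg/ha over 100*1000 ha = 4e8 kg = 4e5 t = 40 in 1e4 t
        assert si.total_straw_yield(ok_city(area=100.0, straw=4000.0)) == pytest.approx(40.0)

    def test_small_magnitudes(self):
        assert si.total_straw_yield(ok_city(area=10.0, straw=1.0)) == pytest.approx(0.001)

    def test_zero_district_yields_zero(self):
        rec = CityRecord("z", "Hebei", "CC", 2012, 0.0, None, status="zero")
        assert si.total_straw_yield(rec) == 0.0

    def test_missing_propagates(self):
        rec = CityRecord("m", "Hebei", "CC", 2012, None, None, status="missing")
        assert si.total_straw_yield(rec) is None


class TestPartitionDisposal:
    def test_hand_arithmetic(self):
        assert si.partition_disposal(40.0, DisposalShares(0.5, 0.3, 0.2)) == \
            pytest.approx((20.0, 12.0, 8.0))

    def test_all_recycled(self):
        assert si.partition_disposal(40.0, DisposalShares(1.0, 0.0, 0.0)) == \
            (40.0, 0.0, 0.0)

    def test_zero_total(self):
        assert si.partition_disposal(0.0, DisposalShares(0.5, 0.3, 0.2)) == \
            (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("shares", [(0.5, 0.3, 0.3), (-0.1, 0.6, 0.5), (1.1, 0.0, -0.1)])
    def test_invalid_shares_rejected(self, shares):
        with pytest.raises(ValueError):
            DisposalShares(*shares)

    @given(total=st.floats(0, 1e6), recycle=st.floats(0, 1), burn=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_mass_conservation(self, total, recycle, burn):
        scale = recycle + burn + 1.0  # leave room for a positive remove share
        shares = DisposalShares(recycle / scale, burn / scale, 1 - (recycle + burn) / scale)
        parts = si.partition_disposal(total, shares)
        assert sum(parts) == pytest.approx(total, rel=1e-9, abs=1e-9)


class TestNutrientSupply:
    def test_table_fractions_at_100_tons(self):
        # 100 t recycled+burned in NC: N 0.49 t, P 0.032 t, K 1.801 t
        out = si.nutrient_supply(0.005, 0.005, "NC", si.TABLE1_NUTRIENTS)
        assert out["N"] == pytest.approx(0.49)
        assert out["P"] == pytest.approx(0.032)
        assert out["K"] == pytest.approx(1.801)

    def test_cc_per_thousand_tons(self):
        out = si.nutrient_supply(0.1, 0.0, "CC", si.TABLE1_NUTRIENTS)
        assert out["N"] == pytest.approx(5.2)

    def test_zero_masses(self):
        out = si.nutrient_supply(0.0, 0.0, "SC", si.TABLE1_NUTRIENTS)
        assert out == {"N": 0.0, "P": 0.0, "K": 0.0}

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            si.nutrient_supply(1.0, 1.0, "EC", si.TABLE1_NUTRIENTS)

    def test_prose_variant_scales_p_and_k_tenfold(self):
        base = si.nutrient_supply(0.005, 0.005, "NC", si.TABLE1_NUTRIENTS)
        alt = si.nutrient_supply(0.005, 0.005, "NC", si.EQ3TEXT_NUTRIENTS)
        assert alt["N"] == pytest.approx(base["N"])
        assert alt["P"] == pytest.approx(10 * base["P"])
        assert alt["K"] == pytest.approx(10 * base["K"])


class TestBurningEmissions:
    def test_national_straw_mass_arithmetic(self):
        out = si.burning_emissions(15.94e6, si.DEFAULT_EMISSION_FACTORS)
        assert out["CO2"] == pytest.approx(23.27e6, rel=5e-4)

    def test_gram_per_kg_is_kg_per_ton(self):
        out = si.burning_emissions(1000.0, si.DEFAULT_EMISSION_FACTORS)
        assert out["NOx"] == pytest.approx(3.3)

    def test_zero_burned(self):
        out = si.burning_emissions(0.0, si.DEFAULT_EMISSION_FACTORS)
        assert all(v == 0.0 for v in out.values())

    @given(burned=st.floats(1e-6, 1e9))
    @settings(max_examples=50, deadline=None)
    def test_emission_ratios_are_exact_ef_ratios(self, burned):
        out = si.burning_emissions(burned, si.DEFAULT_EMISSION_FACTORS)
        assert out["CH4"] / out["CO2"] == pytest.approx(3.4 / 1460, rel=1e-12)
        assert out["NOx"] / out["SO2"] == pytest.approx(3.3 / 0.85, rel=1e-12)


class TestRunInventory:
    def test_single_city_matches_hand_composed_chain(self, even_shares):
        rec = ok_city(area=100.0, grain=5000.0, straw=None)
        results = si.run_inventory([rec], even_shares, si.TABLE1_NUTRIENTS,
                                   si.DEFAULT_EMISSION_FACTORS, models=FLAT)
        r = results[0]
        total = si.total_straw_yield(dataclasses.replace(rec, straw_yield_per_ha=4000.0))
        recycled, burned, removed = si.partition_disposal(total, even_shares)
        assert r.total_straw == pytest.approx(total)
        assert (r.recycled, r.burned, r.removed) == pytest.approx((recycled, burned, removed))
        assert r.nutrient_supply == pytest.approx(
            si.nutrient_supply(recycled, burned, "CC", si.TABLE1_NUTRIENTS))
        assert r.emissions == pytest.approx(
            si.burning_emissions(burned * 1e4, si.DEFAULT_EMISSION_FACTORS))

    def test_mass_balance_holds_for_every_record(self, small_cities, noiseless_models,
                                                 even_shares):
        results = si.run_inventory(small_cities, even_shares, si.TABLE1_NUTRIENTS,
                                   si.DEFAULT_EMISSION_FACTORS, models=noiseless_models)
        assert all(mass_balance_ok(r) for r in results)

    def test_area_scaling_scales_every_output_linearly(self, even_shares):
        recs = [ok_city(city_id=f"c{i}", area=50.0 + 10 * i) for i in range(4)]
        scaled = [dataclasses.replace(r, area=r.area * 3.0) for r in recs]
        base = si.run_inventory(recs, even_shares, si.TABLE1_NUTRIENTS,
                                si.DEFAULT_EMISSION_FACTORS)
        tripled = si.run_inventory(scaled, even_shares, si.TABLE1_NUTRIENTS,
                                   si.DEFAULT_EMISSION_FACTORS)
        for b, t in zip(base, tripled):
            assert t.total_straw == pytest.approx(3 * b.total_straw, rel=1e-12)
            for n in si.NUTRIENTS:
                assert t.nutrient_supply[n] == pytest.approx(3 * b.nutrient_supply[n],
                                                             rel=1e-12)
            for p in si.POLLUTANTS:
                assert t.emissions[p] == pytest.approx(3 * b.emissions[p], rel=1e-12)

    def test_no_burning_means_no_emissions_but_recycled_nutrients(self):
        rec = ok_city()
        results = si.run_inventory([rec], DisposalShares(0.7, 0.0, 0.3),
                                   si.TABLE1_NUTRIENTS, si.DEFAULT_EMISSION_FACTORS)
        r = results[0]
        assert all(v == 0.0 for v in r.emissions.values())
        assert r.nutrient_supply == pytest.approx(
            si.nutrient_supply(r.recycled, 0.0, "CC", si.TABLE1_NUTRIENTS))

    def test_missing_and_zero_statuses_propagate(self, even_shares):
        recs = [
            ok_city(city_id="ok"),
            CityRecord("zz", "Hebei", "CC", 2011, 0.0, None, status="zero"),
            CityRecord("mm", "Hebei", "CC", 2012, None, None, status="missing"),
        ]
        results = {r.city_id: r for r in si.run_inventory(
            recs, even_shares, si.TABLE1_NUTRIENTS, si.DEFAULT_EMISSION_FACTORS)}
        assert results["zz"].total_straw == 0.0
        assert all(v == 0.0 for v in results["zz"].emissions.values())
        assert results["mm"].total_straw is None
        assert all(v is None for v in results["mm"].emissions.values())

    def test_all_missing_gives_empty_aggregate(self, even_shares):
        recs = [CityRecord(f"m{i}", "Hebei", "CC", 2011 + i, None, None,
                           status="missing") for i in range(3)]
        results = si.run_inventory(recs, even_shares, si.TABLE1_NUTRIENTS,
                                   si.DEFAULT_EMISSION_FACTORS)
        assert si.aggregate(results).empty

    def test_duplicate_city_year_rejected(self, even_shares):
        recs = [ok_city(), ok_city()]
        with pytest.raises(ValueError, match="duplicate"):
            si.run_inventory(recs, even_shares, si.TABLE1_NUTRIENTS,
                             si.DEFAULT_EMISSION_FACTORS)

    def test_missing_model_lists_offending_cities(self, even_shares):
        rec = ok_city(straw=None)
        with pytest.raises(ValueError, match="c1"):
            si.run_inventory([rec], even_shares, si.TABLE1_NUTRIENTS,
                             si.DEFAULT_EMISSION_FACTORS, models={})

    def test_share_precedence_city_over_region_over_global(self):
        rec = ok_city()
        by_city = {"c1": DisposalShares(1.0, 0.0, 0.0),
                   si.Region.CC: DisposalShares(0.0, 1.0, 0.0),
                   "global": DisposalShares(0.0, 0.0, 1.0)}
        r = si.run_inventory([rec], by_city, si.TABLE1_NUTRIENTS,
                             si.DEFAULT_EMISSION_FACTORS)[0]
        assert r.recycled == pytest.approx(r.total_straw)
        by_region = {si.Region.CC: DisposalShares(0.0, 1.0, 0.0),
                     "global": DisposalShares(0.0, 0.0, 1.0)}
        r = si.run_inventory([rec], by_region, si.TABLE1_NUTRIENTS,
                             si.DEFAULT_EMISSION_FACTORS)[0]
        assert r.burned == pytest.approx(r.total_straw)
        r = si.run_inventory([rec], {"global": DisposalShares(0.0, 0.0, 1.0)},
                             si.TABLE1_NUTRIENTS, si.DEFAULT_EMISSION_FACTORS)[0]
        assert r.removed == pytest.approx(r.total_straw)

    def test_unresolvable_shares_rejected(self):
        with pytest.raises(KeyError, match="c1"):
            si.run_inventory([ok_city()], {"othercity": DisposalShares(1, 0, 0)},
                             si.TABLE1_NUTRIENTS, si.DEFAULT_EMISSION_FACTORS)


class TestAggregation:
    def test_national_equals_sum_of_regions_equals_sum_of_cities(
            self, small_cities, noiseless_models, even_shares):
        results = si.run_inventory(small_cities, even_shares, si.TABLE1_NUTRIENTS,
                                   si.DEFAULT_EMISSION_FACTORS, models=noiseless_models)
        national = si.aggregate(results, by="national")
        regional = si.aggregate(results, by="region")
        by_city = sum(r.total_straw for r in results if r.status != "missing")
        assert national["total_straw_1e4t"].iloc[0] == pytest.approx(
            regional["total_straw_1e4t"].sum(), rel=1e-12)
        assert national["total_straw_1e4t"].iloc[0] == pytest.approx(by_city, rel=1e-12)
        assert national["CO2_t"].iloc[0] == pytest.approx(
            regional["CO2_t"].sum(), rel=1e-12)

    def test_unknown_level_rejected(self, even_shares):
        results = si.run_inventory([ok_city()], even_shares, si.TABLE1_NUTRIENTS,
                                   si.DEFAULT_EMISSION_FACTORS)
        with pytest.raises(ValueError):
            si.aggregate(results, by="continent")
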