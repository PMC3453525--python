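"""Overhead pools, annuity factors, apportionment rates and conservation."""

import numpy as np
import pytest

from spmcost.model import CareLevelRecipe
from spmcost.overheads import (
    OverheadPools,
    OverheadRates,
    SpmWorkload,
    annualise_capital,
    build_pools,
    compute_overhead_rates,
    overhead_for_recipe,
)

from conftest import make_district, make_facility, make_service


class TestAnnualiseCapital:
    def test_zero_discount_is_straight_line(self):
        assert annualise_capital(100.0, 10, 0.0) == pytest.approx(10.0)

    def test_single_year_annuity(self):
        assert annualise_capital(100.0, 1, 0.03) == pytest.approx(103.0)

    def test_matches_present_value_oracle(self):
        # independent oracle: the annual payment whose discounted sum is the cost
        for life, r in [(10, 0.03), (20, 0.05), (5, 0.10), (30, 0.01)]:
            oracle = 100.0 / sum((1.0 + r) ** -t for t in range(1, life + 1))
            assert annualise_capital(100.0, life, r) == pytest.approx(oracle, rel=1e-12)

    def test_zero_life_rejected(self):
        with pytest.raises(ValueError, match="life_years"):
            annualise_capital(100.0, 0, 0.03)


def _hospital_district(pool=100_000.0, non_spm_bed_days=0.0, non_spm_opd=0.0,
                       centre_pool=0.0, centre_visits=0.0):
    return make_district(facilities=[
        make_facility("H1", "district_hospital", annual_operating_cost=pool,
                      non_spm_bed_days=non_spm_bed_days,
                      non_spm_outpatient_visits=non_spm_opd),
        make_facility("P1", "health_centre_nobeds", annual_operating_cost=centre_pool,
                      non_spm_outpatient_visits=centre_visits,
                      catchment_population=100_000),
    ])


class TestComputeRates:
    def test_hospital_split_arithmetic(self):
        district = _hospital_district(pool=100_000.0)
        pools = build_pools(district, [])
        work = SpmWorkload(primary_visits=0.0, outpatient_visits=6_000.0, bed_days=7_000.0)
        rates = compute_overhead_rates(district, pools, work, hospital_inpatient_weight=0.7)
        assert rates.per_bed_day == pytest.approx(10.0)
        assert rates.per_outpatient_visit == pytest.approx(5.0)

    def test_zero_pools_give_zero_rates(self):
        district = _hospital_district(pool=0.0)
        pools = build_pools(district, [])
        rates = compute_overhead_rates(district, pools, SpmWorkload())
        assert rates.per_bed_day == rates.per_outpatient_visit == rates.per_primary_visit == 0.0

    def test_positive_pool_with_zero_workload_errors(self):
        district = _hospital_district(pool=1000.0)
        pools = build_pools(district, [])
        with pytest.raises(ValueError, match="zero total"):
            compute_overhead_rates(district, pools, SpmWorkload())

    def test_more_shared_workload_strictly_lowers_rates(self):
        # economies of scope: non-package activity spreads the fixed pools
        rng = np.random.default_rng(3)
        for _ in range(20):
            bed, opd, visits = rng.uniform(1_000, 50_000, 3)
            base = _hospital_district(pool=500_000.0, non_spm_bed_days=bed,
                                      non_spm_opd=opd, centre_pool=80_000.0,
                                      centre_visits=visits)
            more = _hospital_district(pool=500_000.0, non_spm_bed_days=2 * bed,
                                      non_spm_opd=2 * opd, centre_pool=80_000.0,
                                      centre_visits=2 * visits)
            work = SpmWorkload(primary_visits=500.0, outpatient_visits=500.0, bed_days=500.0)
            r0 = compute_overhead_rates(base, build_pools(base, []), work)
            r1 = compute_overhead_rates(more, build_pools(more, []), work)
            assert r1.per_bed_day < r0.per_bed_day
            assert r1.per_outpatient_visit < r0.per_outpatient_visit
            assert r1.per_primary_visit < r0.per_primary_visit

    def test_pool_conservation(self):
        # apportioned rate x total stream workload recovers each pool
        district = make_district(facilities=[
            make_facility("H1", "district_hospital", annual_operating_cost=700_000.0,
                          annualised_capital=120_000.0, indirect_staff_cost=80_000.0,
                          non_spm_bed_days=20_000.0, non_spm_outpatient_visits=50_000.0),
            make_facility("P1", "health_centre_beds", annual_operating_cost=90_000.0,
                          non_spm_bed_days=400.0, non_spm_outpatient_visits=20_000.0,
                          catchment_population=60_000),
            make_facility("P2", "health_centre_nobeds", annual_operating_cost=70_000.0,
                          non_spm_outpatient_visits=15_000.0, catchment_population=40_000),
        ])
        work = SpmWorkload(primary_visits=8_000.0, outpatient_visits=3_000.0, bed_days=2_500.0)
        pools = build_pools(district, [])
        eq = 2.0
        rates = compute_overhead_rates(district, pools, work, centre_bed_day_equivalent=eq)
        hospital_pool = 900_000.0
        centre_pool = 160_000.0
        recovered_hosp = (rates.per_bed_day * (work.bed_days + 20_000.0)
                          + rates.per_outpatient_visit * (work.outpatient_visits + 50_000.0))
        recovered_centre = rates.per_primary_visit * (
            work.primary_visits + 20_000.0 + 15_000.0 + eq * 400.0
        )
        assert recovered_hosp == pytest.approx(hospital_pool, rel=1e-6)
        assert recovered_centre == pytest.approx(centre_pool, rel=1e-6)

    def test_rates_homogeneous_degree_zero(self):
        base = _hospital_district(pool=400_000.0, non_spm_bed_days=10_000.0,
                                  non_spm_opd=30_000.0, centre_pool=90_000.0,
                                  centre_visits=25_000.0)
        scaled = _hospital_district(pool=3 * 400_000.0, non_spm_bed_days=3 * 10_000.0,
                                    non_spm_opd=3 * 30_000.0, centre_pool=3 * 90_000.0,
                                    centre_visits=3 * 25_000.0)
        work = SpmWorkload(primary_visits=1_000.0, outpatient_visits=1_000.0, bed_days=1_000.0)
        work3 = SpmWorkload(primary_visits=3_000.0, outpatient_visits=3_000.0, bed_days=3_000.0)
        r0 = compute_overhead_rates(base, build_pools(base, []), work)
        r1 = compute_overhead_rates(scaled, build_pools(scaled, []), work3)
        assert r1.per_bed_day == pytest.approx(r0.per_bed_day, rel=1e-12)
        assert r1.per_outpatient_visit == pytest.approx(r0.per_outpatient_visit, rel=1e-12)
        assert r1.per_primary_visit == pytest.approx(r0.per_primary_visit, rel=1e-12)

    def test_sparsity_raises_rates(self):
        # an extra facility (larger pools, same workload) raises every rate:
        # the mechanism by which sparse districts cost more per episode
        base = _hospital_district(pool=400_000.0, non_spm_bed_days=10_000.0,
                                  non_spm_opd=30_000.0, centre_pool=90_000.0,
                                  centre_visits=25_000.0)
        denser_network = make_district(facilities=[
            *base.facilities[:1],
            make_facility("P1", "health_centre_nobeds", annual_operating_cost=90_000.0,
                          non_spm_outpatient_visits=12_500.0, catchment_population=50_000),
            make_facility("P2", "health_centre_nobeds", annual_operating_cost=90_000.0,
                          non_spm_outpatient_visits=12_500.0, catchment_population=50_000),
        ])
        work = SpmWorkload(primary_visits=1_000.0, outpatient_visits=1_000.0, bed_days=1_000.0)
        r0 = compute_overhead_rates(base, build_pools(base, []), work)
        r1 = compute_overhead_rates(denser_network, build_pools(denser_network, []), work)
        assert r1.per_primary_visit > r0.per_primary_visit

    def test_programme_and_admin_per_capita(self):
        district = _hospital_district(pool=0.0)
        svc = make_service("dengue_ctrl", programme_overhead_per_capita=0.4)
        pools = build_pools(district, [svc])
        assert pools.programme_pool["dengue_ctrl"] == pytest.approx(0.4 * district.population)
        rates = compute_overhead_rates(district, pools, SpmWorkload())
        assert rates.per_capita_programme["dengue_ctrl"] == pytest.approx(0.4)


class TestOverheadForRecipe:
    RATES = OverheadRates(per_bed_day=25.0, per_outpatient_visit=8.0, per_primary_visit=5.0)

    def test_primary_visit_rate(self):
        recipe = CareLevelRecipe(level="primary")
        assert overhead_for_recipe(recipe, self.RATES) == pytest.approx(5.0)

    def test_bed_days_scale_inpatient_overhead(self):
        recipe = CareLevelRecipe(level="hospital_inpatient", inpatient_days=4.0)
        assert overhead_for_recipe(recipe, self.RATES) == pytest.approx(100.0)

    def test_admission_visit_flag(self):
        recipe = CareLevelRecipe(level="hospital_inpatient", inpatient_days=4.0)
        got = overhead_for_recipe(recipe, self.RATES, admission_includes_visit=True)
        assert got == pytest.approx(108.0)

    def test_random_recipes_match_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            level = rng.choice(["primary", "hospital_outpatient", "hospital_inpatient"])
            days = float(rng.uniform(0, 10)) if level == "hospital_inpatient" else 0.0
            recipe = CareLevelRecipe(level=level, inpatient_days=days)
            oracle = {"primary": 5.0, "hospital_outpatient": 8.0,
                      "hospital_inpatient": days * 25.0}[level]
            assert overhead_for_recipe(recipe, self.RATES) == pytest.approx(oracle)


class TestPoolValidation:
    def test_negative_pool_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            OverheadPools(facility_pool={"H1": -1.0}, programme_pool={})
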