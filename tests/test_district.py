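"""Service loads, district totals, per-capita budgets, age/sex allocation."""

import numpy as np
import pytest

from spmcost.config import RunConfig
from spmcost.district import age_sex_allocation, cost_district, service_load, spm_workload
from spmcost.model import AGE_BANDS, CareLevelRecipe, ResourceItem
from spmcost.synth import GeneratorConfig, generate_catalogue, generate_district

from conftest import make_district, make_facility, make_service, uniform_age_sex


class TestServiceLoad:
    def test_zero_coverage_treats_nobody(self):
        svc = make_service(incidence_key="diarrhoea", coverage_target=0.0)
        load = service_load(svc, make_district())
        assert load.treated_count == 0.0

    def test_chain_arithmetic(self):
        district = make_district(population=100_000, rates={"diarrhoea": 0.025})
        svc = make_service(incidence_key="diarrhoea", facility_need=1.0,
                           coverage_target=0.9, referral_fraction=0.2,
                           admission_fraction=0.5)
        load = service_load(svc, district)
        assert load.treated_count == pytest.approx(2_250.0)
        assert load.referred_count == pytest.approx(450.0)
        assert load.admitted_count == pytest.approx(225.0)

    def test_random_chains_match_stepwise_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            d, n, cov, pi, m, sigma = rng.uniform(0, 1, 6)
            district = make_district(population=50_000, rates={"malaria": float(d)})
            svc = make_service(incidence_key="malaria", facility_need=float(n),
                               coverage_target=float(cov), referral_fraction=float(pi),
                               admission_fraction=float(m),
                               self_referral_fraction=float(sigma))
            load = service_load(svc, district)
            target = 50_000 * 1.0
            case = target * d
            treated = case * n * cov
            referred = treated * ((1 - sigma) * pi + sigma)
            admitted = referred * m
            assert load.case_count == pytest.approx(case, rel=1e-12)
            assert load.treated_count == pytest.approx(treated, rel=1e-12)
            assert load.referred_count == pytest.approx(referred, rel=1e-12)
            assert load.admitted_count == pytest.approx(admitted, rel=1e-12)
            chain = (load.target_count, load.case_count, load.treated_count,
                     load.referred_count, load.admitted_count)
            assert all(hi >= lo - 1e-9 for hi, lo in zip(chain, chain[1:]))

    def test_missing_driver_names_service_and_driver(self):
        svc = make_service("tb_care", incidence_key="tuberculosis")
        with pytest.raises(KeyError, match="tb_care.*tuberculosis"):
            service_load(svc, make_district(rates={"malaria": 0.1}))

    def test_utilisation_mode_uses_observed_fraction(self):
        district = make_district(rates={"diarrhoea": 0.1})
        svc = make_service(incidence_key="diarrhoea", coverage_target=0.9,
                           utilisation_fraction=0.45)
        need = service_load(svc, district, mode="need")
        util = service_load(svc, district, mode="utilisation")
        assert util.treated_count == pytest.approx(need.treated_count / 2)


def _flat_cost_district(population=100_000, rate=0.0125):
    """Zero-overhead district: one co-located pair, no fixed pools."""
    return make_district(population=population, rates={"diarrhoea": rate},
                         facilities=[
                             make_facility("H1", "district_hospital"),
                             make_facility("P1", "health_centre_nobeds",
                                           catchment_population=population),
                         ])


def _priced_service(price=20.0, **kw):
    recipes = {
        "primary": CareLevelRecipe(level="primary", items=[
            ResourceItem(name="kit", unit_price=price, quantity=1.0, use_probability=1.0)]),
        "hospital_outpatient": CareLevelRecipe(level="hospital_outpatient"),
        "hospital_inpatient": CareLevelRecipe(level="hospital_inpatient"),
    }
    return make_service(incidence_key="diarrhoea", coverage_target=0.8,
                        recipes=recipes, **kw)


class TestCostDistrict:
    def test_single_service_arithmetic(self):
        # treated 1,000 episodes at 20 each -> 20,000; per-capita 0.2
        district = _flat_cost_district()
        report = cost_district(district, [_priced_service()])
        assert report.total_cost == pytest.approx(20_000.0)
        assert report.per_capita == pytest.approx(0.2)

    def test_empty_catalogue_costs_population_overheads_only(self):
        district = _flat_cost_district()
        report = cost_district(district, [])
        assert report.total_cost == 0.0
        admin_district = district.model_copy(update={"dho_admin_cost": 5_000.0})
        report = cost_district(admin_district, [])
        assert report.total_cost == pytest.approx(5_000.0)

    def test_additivity_is_exact(self):
        district = generate_district(GeneratorConfig(seed=4))
        catalogue = generate_catalogue(4)
        report = cost_district(district, catalogue)
        assert report.total_cost == float(report.per_service["total_cost"].sum()) + report.admin_overhead

    def test_per_capita_invariant_under_population_scaling(self):
        def scaled(factor):
            facs = [
                make_facility("H1", "district_hospital",
                              annual_operating_cost=500_000.0 * factor,
                              non_spm_bed_days=20_000.0 * factor,
                              non_spm_outpatient_visits=50_000.0 * factor),
                make_facility("P1", "health_centre_nobeds", 3.0, 4.0,
                              annual_operating_cost=80_000.0 * factor,
                              non_spm_outpatient_visits=30_000.0 * factor,
                              catchment_population=100_000 * factor),
            ]
            return make_district(population=100_000 * factor, facilities=facs,
                                 rates={"diarrhoea": 0.1},
                                 dho_admin_cost=300_000.0 * factor)

        svc = _priced_service(referral_fraction=0.2, admission_fraction=0.5,
                              inpatient_days=0.0)
        small = cost_district(scaled(1), [svc])
        big = cost_district(scaled(2), [svc])
        assert big.per_capita == pytest.approx(small.per_capita, abs=1e-9)

    def test_per_capita_monotone_in_coverage(self):
        district = generate_district(GeneratorConfig(seed=6))
        catalogue = generate_catalogue(6)
        base = cost_district(district, catalogue).per_capita
        raised = [
            s.model_copy(update={"coverage_target": min(1.0, s.coverage_target + 0.05)})
            for s in catalogue
        ]
        assert cost_district(district, raised).per_capita >= base

    @pytest.mark.parametrize("seed", [1, 8, 21])
    def test_utilisation_cost_never_exceeds_need_cost(self, seed):
        district = generate_district(GeneratorConfig(seed=seed))
        catalogue = generate_catalogue(seed)
        need = cost_district(district, catalogue, config=RunConfig(mode="need"))
        util = cost_district(district, catalogue, config=RunConfig(mode="utilisation"))
        assert util.per_capita <= need.per_capita

    @pytest.mark.parametrize("seed", [1, 8, 21])
    def test_bottom_heavy_pyramid_costs_more_than_aging(self, seed):
        catalogue = generate_catalogue(seed)
        young = generate_district(GeneratorConfig(seed=seed, pyramid_shape="bottom_heavy"))
        old = generate_district(GeneratorConfig(seed=seed, pyramid_shape="aging"))
        assert (cost_district(young, catalogue).per_capita
                > cost_district(old, catalogue).per_capita)

    def test_workload_aggregation_matches_loads(self):
        district = generate_district(GeneratorConfig(seed=7))
        catalogue = generate_catalogue(7)
        loads = {s.id: service_load(s, district) for s in catalogue}
        work = spm_workload(catalogue, loads)
        oracle_beds = sum(
            loads[s.id].admitted_count * s.recipes["hospital_inpatient"].inpatient_days
            for s in catalogue)
        assert work.bed_days == pytest.approx(oracle_beds, rel=1e-12)
        assert work.primary_visits <= sum(l.treated_count for l in loads.values())


class TestAgeSexAllocation:
    def test_maternal_catalogue_all_female(self):
        district = make_district()
        svc = make_service("anc", attribution="maternal")
        shares = age_sex_allocation({"anc": 1000.0}, [svc], district)
        assert shares["female"].sum() == pytest.approx(1.0)
        assert shares["male"].sum() == pytest.approx(0.0)
        assert shares.loc["0-4", "female"] == 0.0  # maternal care goes to 15-49

    def test_sex_neutral_service_splits_evenly(self):
        district = make_district(age_sex=uniform_age_sex())
        svc = make_service("tb", attribution="population")
        shares = age_sex_allocation({"tb": 500.0}, [svc], district)
        assert shares["female"].sum() == pytest.approx(0.5)
        assert shares["male"].sum() == pytest.approx(0.5)

    def test_mixed_catalogue_matches_per_service_oracle(self):
        district = generate_district(GeneratorConfig(seed=12))
        catalogue = generate_catalogue(12)
        report = cost_district(district, catalogue)
        costs = dict(zip(report.per_service["service"], report.per_service["total_cost"]))
        from spmcost.district import _attribution_weights
        oracle = np.zeros((len(AGE_BANDS), 2))
        for s in catalogue:
            oracle += costs[s.id] * _attribution_weights(s, district).to_numpy()
        pop_grid = np.array([[district.age_sex.female[b], district.age_sex.male[b]]
                             for b in AGE_BANDS])
        oracle += report.admin_overhead * pop_grid
        oracle /= oracle.sum()
        assert np.allclose(report.age_sex_shares.to_numpy(), oracle, atol=1e-12)
        assert report.age_sex_shares.to_numpy().sum() == pytest.approx(1.0, abs=1e-9)

    def test_child_attribution_targets_under_fives(self):
        district = make_district()
        svc = make_service("imm", attribution="child")
        shares = age_sex_allocation({"imm": 100.0}, [svc], district)
        assert shares.loc["0-4"].sum() == pytest.approx(1.0)
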