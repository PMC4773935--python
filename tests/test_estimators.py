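import numpy as np
import pandas as pd
import pytest

from incidest.estimators import (
    DataAvailability,
    FrequencyTable,
    _merged_ratios,
    build_frequency_table,
    compute_mi_ratios,
    method_2,
    method_3,
    method_5,
    method_6,
    method_7,
    method_8,
    method_9,
    select_method,
)
from incidest.sites import FEMALE, MALE, N_AGE_GROUPS
from incidest.tables import (
    EventTable,
    RateTable,
    SurvivalTable,
    ValidationError,
    pooled_rates,
)

from conftest import constant_rate_events, make_events, make_population, uniform_population


# -------------------------------------------------------------------- method 2


def test_method_2_identity_with_stationary_population():
    years = list(range(2003, 2008))
    ev = constant_rate_events("no", years, MALE, "Lung", 40.0)
    pop = uniform_population(["no"], years + [2010])
    est = method_2(ev, pop)
    # stationary population: estimate equals the window's average annual count
    avg = ev.subset(years=(2003, 2007)).total() / 5
    assert est.cases(MALE, "Lung") == pytest.approx(avg, rel=1e-12)


def test_method_2_matches_brute_force():
    rng = np.random.default_rng(12)
    years = list(range(2003, 2008))
    rows = [("no", y, MALE, "Lung", a, float(rng.integers(0, 50)))
            for y in years for a in range(N_AGE_GROUPS)]
    ev = make_events(rows)
    pop = make_population(
        [("no", y, s, a, float(rng.integers(50_000, 150_000)))
         for y in years + [2010] for s in (MALE, FEMALE) for a in range(N_AGE_GROUPS)]
    )
    est = method_2(ev, pop)
    brute = 0.0
    p = pop.data.set_index(["year", "sex", "age_group"])["person_years"]
    for a in range(N_AGE_GROUPS):
        cases = sum(c for (_, y, s, _, aa, c) in ev.data.itertuples(index=False) if aa == a)
        py = sum(p[(y, MALE, a)] for y in years)
        brute += cases / py * p[(2010, MALE, a)]
    assert est.cases(MALE, "Lung") == pytest.approx(brute, rel=1e-12)


# ------------------------------------------------------------------ M:I ratios


def _single_age_tables(deaths, cases, dataset="west"):
    inc = make_events([(dataset, 2005, MALE, "Lung", 9, cases)])
    mort = make_events([(dataset, 2005, MALE, "Lung", 9, deaths)], "mortality")
    return inc, mort


def test_mi_ratio_simple_division():
    inc, mort = _single_age_tables(40.0, 100.0)
    mi = compute_mi_ratios(inc, mort, proxy_datasets=["west"])
    assert mi.data.set_index("age_group")["ratio"][9] == pytest.approx(0.40)


def test_mi_neighbour_pooling_recorded_in_provenance():
    """A site below the annual-deaths threshold pools neighbour data."""
    inc, mort = _single_age_tables(13.0 * 5, 300.0)
    nb_inc = make_events([("nb", 2005, MALE, "Lung", 9, 500.0)])
    nb_mort = make_events([("nb", 2005, MALE, "Lung", 9, 100.0)], "mortality")
    inc = EventTable("incidence", pd.concat([inc.data, nb_inc.data], ignore_index=True))
    mort = EventTable("mortality", pd.concat([mort.data, nb_mort.data], ignore_index=True))
    national_mort = make_events([("no", y, MALE, "Lung", 9, 13.0) for y in range(2003, 2008)],
                                "mortality")
    mi = compute_mi_ratios(
        inc, mort, proxy_datasets=["west"], neighbour_datasets=["nb"],
        national_mortality=national_mort, pooling_threshold=100.0,
    )
    assert mi.provenance[(MALE, "Lung")] == ("west", "nb")
    assert mi.data.set_index("age_group")["ratio"][9] == pytest.approx((65 + 100) / (300 + 500))


def test_mi_zero_incidence_age_merges_downward():
    """An age with deaths but no cases takes the combined younger cell's ratio."""
    inc = make_events([("west", 2005, MALE, "Lung", 8, 50.0)])
    mort = make_events(
        [("west", 2005, MALE, "Lung", 8, 10.0), ("west", 2005, MALE, "Lung", 9, 2.0)],
        "mortality",
    )
    mi = compute_mi_ratios(inc, mort, proxy_datasets=["west"])
    ratios = mi.data.set_index("age_group")["ratio"]
    # ages 9+ carry no cases, so they join age 8's cell and the whole
    # merged stratum shares the combined (10+2)/50 ratio
    assert ratios[9] == pytest.approx((10 + 2) / 50)
    assert ratios[8] == pytest.approx((10 + 2) / 50)


def test_mi_all_zero_incidence_rejected():
    inc = make_events([("west", 2005, MALE, "Lung", 9, 0.0)])
    mort = make_events([("west", 2005, MALE, "Lung", 9, 3.0)], "mortality")
    with pytest.raises(ValidationError, match="Lung"):
        compute_mi_ratios(inc, mort, proxy_datasets=["west"])


def test_merged_ratios_borrow_older_cell_for_zero_death_ages():
    inc = np.zeros(N_AGE_GROUPS)
    mort = np.zeros(N_AGE_GROUPS)
    inc[2], inc[10] = 100.0, 20.0
    mort[10] = 5.0
    ratios = _merged_ratios(inc, mort)
    assert ratios[2] == pytest.approx(0.25)  # borrowed from the older cell
    assert ratios[10] == pytest.approx(0.25)


# ---------------------------------------------------------------- methods 3-5


def _national_setup(rate=30.0, fatality=0.5):
    """National incidence/mortality with exact proportional deaths."""
    years = list(range(2003, 2008))
    inc = constant_rate_events("no", years, MALE, "Lung", rate)
    mort = constant_rate_events("no", years, MALE, "Lung", rate * fatality, kind="mortality")
    pop = uniform_population(["no"], years + [2010])
    return inc, mort, pop


def test_method_3_self_consistency_recovers_national_incidence():
    """M:I from the same national data inverts back to national incidence."""
    inc, mort, pop = _national_setup()
    mi = compute_mi_ratios(inc, mort, proxy_datasets=["no"])
    mort_rates = pooled_rates(mort, pop, datasets=["no"], years=(2003, 2007))
    est = method_3(mort_rates, mi, pop)
    truth = 30.0 * 1.0 * N_AGE_GROUPS  # rate x 1e5 PY per age band
    assert est.cases(MALE, "Lung") == pytest.approx(truth, rel=1e-9)


def test_method_3_divides_rates_by_ratio():
    rates = RateTable(pd.DataFrame(
        {"sex": [MALE], "site": ["Lung"], "age_group": [9], "rate": [10.0]}))
    mi_inc = make_events([("no", 2005, MALE, "Lung", 9, 100.0)])
    mi_mort = make_events([("no", 2005, MALE, "Lung", 9, 50.0)], "mortality")
    mi = compute_mi_ratios(mi_inc, mi_mort, proxy_datasets=["no"])
    pop = uniform_population(["no"], [2010])
    est = method_3(rates, mi, pop)
    assert est.detail["cases"].sum() == pytest.approx(20.0)  # rate 20 on 1e5 PY


def test_method_3_zero_ratio_with_mortality_errors():
    rates = RateTable(pd.DataFrame(
        {"sex": [MALE], "site": ["Lung"], "age_group": [9], "rate": [10.0]}))
    mi_inc = make_events([("no", 2005, MALE, "Lung", 9, 100.0)])
    mi_mort = make_events([("no", 2005, MALE, "Lung", 9, 0.0)], "mortality")
    mi = compute_mi_ratios(mi_inc, mi_mort, proxy_datasets=["no"])
    pop = uniform_population(["no"], [2010])
    with pytest.raises(ValidationError, match="zero M:I"):
        method_3(rates, mi, pop)


def test_method_5_inverts_survival_link_exactly():
    """Mortality generated as I(1-S) is inverted back to I per stratum."""
    incidence_rate, survival = 30.0, 0.5
    rates = RateTable(pd.DataFrame(
        {"sex": MALE, "site": "Lung", "age_group": range(N_AGE_GROUPS),
         "rate": incidence_rate * (1 - survival)}))
    surv = SurvivalTable(pd.DataFrame(
        [{"sex": MALE, "site": "Lung", "survival_5yr": survival}]))
    pop = uniform_population(["no"], [2010])
    est = method_5(rates, surv, pop)
    assert est.cases(MALE, "Lung") == pytest.approx(incidence_rate * N_AGE_GROUPS, rel=1e-12)


def test_method_5_s_zero_returns_mortality():
    rates = RateTable(pd.DataFrame(
        {"sex": [MALE], "site": ["Lung"], "age_group": [9], "rate": [10.0]}))
    surv = SurvivalTable(pd.DataFrame([{"sex": MALE, "site": "Lung", "survival_5yr": 0.0}]))
    est = method_5(rates, surv, uniform_population(["no"], [2010]))
    assert est.cases(MALE, "Lung") == pytest.approx(10.0)


def test_method_5_caps_survival_near_one():
    rates = RateTable(pd.DataFrame(
        {"sex": [MALE], "site": ["Lung"], "age_group": [9], "rate": [1.0]}))
    surv = SurvivalTable(pd.DataFrame([{"sex": MALE, "site": "Lung", "survival_5yr": 0.999}]))
    with pytest.warns(UserWarning, match="capped"):
        est = method_5(rates, surv, uniform_population(["no"], [2010]))
    assert est.cases(MALE, "Lung") == pytest.approx(1.0 / (1 - 0.99))


# ---------------------------------------------------------------- methods 6-9


def test_method_6_whole_country_proxy_equals_method_2():
    years = list(range(2003, 2008))
    ev = constant_rate_events("no", years, MALE, "Lung", 33.0)
    pop = uniform_population(["no"], years + [2010])
    m6 = method_6(ev, pop, pop, regions=["no"])
    m2 = method_2(ev, pop)
    assert m6.cases(MALE, "Lung") == pytest.approx(m2.cases(MALE, "Lung"), rel=1e-12)


def test_method_7_scaled_proxy_rates_scale_estimate():
    years = list(range(2003, 2008))
    base = constant_rate_events("reg", years, MALE, "Lung", 20.0)
    scaled = constant_rate_events("reg", years, MALE, "Lung", 30.0)
    rpop = uniform_population(["reg"], years)
    npop = uniform_population(["no"], [2010])
    e1 = method_7(base, rpop, npop, regions=["reg"])
    e2 = method_7(scaled, rpop, npop, regions=["reg"])
    assert e2.cases(MALE, "Lung") == pytest.approx(1.5 * e1.cases(MALE, "Lung"), rel=1e-12)


def test_method_9_neighbours_identical_to_nation_recover_truth():
    years = [2009, 2010, 2011]
    nb = constant_rate_events("nb", years, MALE, "Lung", 25.0)
    nb_pop = uniform_population(["nb"], years)
    npop = uniform_population(["no"], [2010])
    est = method_9(nb, nb_pop, npop, neighbours=["nb"])
    assert est.cases(MALE, "Lung") == pytest.approx(25.0 * N_AGE_GROUPS, rel=1e-12)


def test_method_9_pools_by_person_years():
    """Pooled rate is the person-year-weighted average of country rates."""
    years = [2009]
    inc = make_events([("a", 2009, MALE, "Lung", 9, 10.0), ("b", 2009, MALE, "Lung", 9, 90.0)])
    nb_pop = make_population(
        [("a", 2009, MALE, 9, 100_000.0), ("b", 2009, MALE, 9, 300_000.0)])
    npop = make_population([("no", 2010, MALE, 9, 200_000.0)])
    est = method_9(inc, nb_pop, npop, neighbours=["a", "b"], window=(2009, 2009))
    pooled_rate = 1e5 * 100 / 400_000  # 25 per 1e5, not mean(10, 30) = 20
    assert est.cases(MALE, "Lung") == pytest.approx(pooled_rate * 2.0)


# -------------------------------------------------------- frequency / method 8


def test_frequency_table_proportions():
    ev = make_events(
        [("nb", 2010, MALE, "Lung", 9, 30.0), ("nb", 2010, MALE, "Stomach", 9, 70.0)])
    freq = build_frequency_table(ev, datasets=["nb"], window=(2009, 2011))
    got = freq.data.set_index("site")["proportion"]
    assert got["Lung"] == pytest.approx(0.3)
    assert got["Stomach"] == pytest.approx(0.7)


def test_frequency_proportions_sum_to_one_on_random_input():
    rng = np.random.default_rng(3)
    sites = ["Lung", "Stomach", "Pancreas", "Bladder"]
    rows = [("nb", 2010, s, site, 9, float(rng.integers(1, 99)))
            for s in (MALE, FEMALE) for site in sites]
    freq = build_frequency_table(make_events(rows), datasets=["nb"], window=(2009, 2011))
    sums = freq.data.groupby("sex")["proportion"].sum()
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)


def test_method_8_partition_conserves_all_sites_total():
    rng = np.random.default_rng(4)
    all_rates = RateTable(pd.DataFrame(
        {"sex": MALE, "site": "all", "age_group": range(N_AGE_GROUPS),
         "rate": rng.uniform(10, 80, N_AGE_GROUPS)}))
    freq = FrequencyTable(pd.DataFrame(
        {"sex": MALE, "site": ["Lung", "Stomach", "Bladder"],
         "proportion": [0.5, 0.3, 0.2]}))
    pop = uniform_population(["no"], [2010])
    est = method_8(all_rates, freq, pop)
    all_total = float(all_rates.data["rate"].sum())  # 1e5 PY per stratum
    assert est.data["cases"].sum() == pytest.approx(all_total, rel=1e-12)
    assert est.cases(MALE, "Lung") == pytest.approx(0.5 * all_total, rel=1e-12)


def test_method_8_single_site_reduces_to_rate_transport():
    all_rates = RateTable(pd.DataFrame(
        {"sex": [MALE], "site": ["all"], "age_group": [9], "rate": [50.0]}))
    freq = FrequencyTable(pd.DataFrame(
        {"sex": [MALE], "site": ["Lung"], "proportion": [1.0]}))
    est = method_8(all_rates, freq, uniform_population(["no"], [2010]))
    assert est.cases(MALE, "Lung") == pytest.approx(50.0)


def test_method_8_missing_sex_in_frequencies_rejected():
    all_rates = RateTable(pd.DataFrame(
        {"sex": [MALE, FEMALE], "site": "all", "age_group": 9, "rate": 50.0}))
    freq = FrequencyTable(pd.DataFrame(
        {"sex": [MALE], "site": ["Lung"], "proportion": [1.0]}))
    with pytest.raises(ValidationError, match="female"):
        method_8(all_rates, freq, uniform_population(["no"], [2010]))


# ------------------------------------------------------------ method selection


@pytest.mark.parametrize(
    "availability,expected",
    [
        (DataAvailability(national_incidence_history=True, national_mortality=True), "1"),
        (DataAvailability(recent_national_incidence=True, neighbour_data=True), "2"),
        (DataAvailability(national_mortality=True, regional_registries=True,
                          regional_registry_count=3), "3"),
        (DataAvailability(national_mortality=True, neighbour_data=True), "4"),
        (DataAvailability(national_mortality=True, survival=True), "5"),
        (DataAvailability(regional_registries=True, regional_registry_count=1), "6"),
        (DataAvailability(regional_registries=True, regional_registry_count=4), "7"),
        (DataAvailability(neighbour_data=True, frequency_data=True), "8"),
        (DataAvailability(neighbour_data=True), "9"),
    ],
)
def test_selection_priority_order(availability, expected):
    assert select_method(availability) == expected


def test_selection_with_nothing_available_errors():
    with pytest.raises(ValidationError):
        select_method(DataAvailability())
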