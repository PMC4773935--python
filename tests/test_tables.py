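import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from incidest import io as iio
from incidest.comparison import round_half_away
from incidest.sites import FEMALE, MALE
from incidest.tables import (
    EstimateTable,
    ValidationError,
    apply_rates,
    compute_rates,
    gold_standard,
    group_sites,
    pooled_rates,
    reallocate_unspecified_uterus,
)

from conftest import make_events, make_population, uniform_population


# ---------------------------------------------------------------------- reader


def test_reader_builds_validated_table(tmp_path):
    path = tmp_path / "ev.csv"
    path.write_text(
        "dataset,year,sex,site,age_group,count\n"
        "no,2010,male,C18,5,1\n"
        "no,2010,male,C18,6,2\n"
        "no,2010,female,C50,8,3\n"
    )
    ev = iio.read_registry_table(path, "incidence")
    assert len(ev.data) == 3
    assert ev.total() == 6
    assert set(ev.data["site"]) == {"Colon-rectum", "Breast"}


def test_reader_rejects_sex_site_conflict(tmp_path):
    path = tmp_path / "ev.csv"
    path.write_text("dataset,year,sex,site,age_group,count\nno,2010,male,C53,8,1\n")
    with pytest.raises(ValidationError, match="C53|Cervix"):
        iio.read_registry_table(path, "incidence")


def test_reader_sums_duplicate_strata_with_warning(tmp_path):
    path = tmp_path / "ev.csv"
    path.write_text(
        "dataset,year,sex,site,age_group,count\n"
        "no,2010,male,C18,5,3\n"
        "no,2011,male,C18,5,1\n"
        "no,2010,male,C18,5,4\n"
    )
    with pytest.warns(UserWarning, match="duplicate"):
        ev = iio.read_registry_table(path, "incidence")
    dup = ev.data[(ev.data["year"] == 2010)]
    assert float(dup["count"].iloc[0]) == 7.0


def test_reader_requires_columns_and_rejects_negative(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text("dataset,year,sex,age_group,count\nno,2010,male,5,1\n")
    with pytest.raises(iio.FormatError, match="site"):
        iio.read_registry_table(bad, "incidence")
    neg = tmp_path / "neg.csv"
    neg.write_text("dataset,year,sex,site,age_group,count\nno,2010,male,C18,5,-1\n")
    with pytest.raises(ValidationError, match="row 2"):
        iio.read_registry_table(neg, "incidence")


def test_reader_collapses_19_band_age_axis(tmp_path):
    path = tmp_path / "ev.csv"
    path.write_text(
        "dataset,year,sex,site,age_group,count\n"
        "no,2010,male,C18,85-89,2\n"
        "no,2010,male,C18,90+,3\n"
    )
    with pytest.warns(UserWarning, match="19-band"):
        ev = iio.read_registry_table(path, "incidence")
    assert list(ev.data["age_group"]) == [17]
    assert float(ev.data["count"].iloc[0]) == 5.0


# ----------------------------------------------------------------- group_sites


def test_group_sites_sums_codes_into_groups():
    ev = make_events(
        [("no", 2010, "male", "C18", 10, 5),
         ("no", 2010, "male", "C19", 10, 2),
         ("no", 2010, "male", "C20", 10, 3)]
    )
    out = group_sites(ev)
    assert len(out.data) == 1
    assert out.data["site"].iloc[0] == "Colon-rectum"
    assert out.total() == 10


def test_group_sites_idempotent_on_grouped_input():
    ev = make_events([("no", 2010, "male", "Colon-rectum", 10, 7)])
    out = group_sites(ev)
    pd.testing.assert_frame_equal(out.data, ev.data)


def test_group_sites_matches_brute_force_on_random_codes():
    rng = np.random.default_rng(7)
    codes = [f"C{n:02d}" for n in rng.choice(97, size=50)]
    codes = [c for c in codes if c not in ("C44", "C50", "C53", "C54", "C55", "C56", "C61", "C62")]
    rows = [("no", 2010, "male", c, int(rng.integers(0, 18)), float(rng.integers(1, 9)))
            for c in codes]
    ev = make_events(rows)
    out = group_sites(ev)
    from incidest.sites import group_for

    brute: dict[tuple, float] = {}
    for _, r in ev.data.iterrows():
        key = (group_for(r["site"]).name, r["age_group"])
        brute[key] = brute.get(key, 0.0) + r["count"]
    got = out.data.set_index(["site", "age_group"])["count"].to_dict()
    assert got == pytest.approx(brute)
    assert out.total() == pytest.approx(ev.total())


# ----------------------------------------------------------------- C55 rule


def _uterus_events(rows):
    return make_events([("no", 2010, FEMALE, site, age, n) for site, age, n in rows])


def test_c55_split_proportional_within_cell():
    ev = _uterus_events(
        [("Cervix uteri", 10, 30), ("Corpus uteri", 10, 70), ("Uterus unspecified", 10, 10)]
    )
    out = reallocate_unspecified_uterus(ev).data.set_index("site")["count"]
    assert out["Cervix uteri"] == pytest.approx(33.0)
    assert out["Corpus uteri"] == pytest.approx(77.0)
    assert "Uterus unspecified" not in out.index


def test_c55_falls_back_to_dataset_level_proportions():
    ev = make_events(
        [("no", 2009, FEMALE, "Cervix uteri", 8, 25),
         ("no", 2009, FEMALE, "Corpus uteri", 8, 75),
         ("no", 2010, FEMALE, "Uterus unspecified", 10, 4)]
    )
    out = reallocate_unspecified_uterus(ev).data
    cell = out[out["year"] == 2010].set_index("site")["count"]
    assert cell["Cervix uteri"] == pytest.approx(1.0)
    assert cell["Corpus uteri"] == pytest.approx(3.0)


def test_c55_splits_half_half_when_no_information():
    ev = _uterus_events([("Uterus unspecified", 9, 6)])
    with pytest.warns(UserWarning, match="50/50"):
        out = reallocate_unspecified_uterus(ev).data.set_index("site")["count"]
    assert out["Cervix uteri"] == pytest.approx(3.0)
    assert out["Corpus uteri"] == pytest.approx(3.0)


def test_c55_noop_without_c55():
    ev = _uterus_events([("Cervix uteri", 9, 5), ("Corpus uteri", 9, 6)])
    out = reallocate_unspecified_uterus(ev)
    pd.testing.assert_frame_equal(
        out.data.sort_values("site").reset_index(drop=True),
        ev.data.sort_values("site").reset_index(drop=True),
    )


def test_c55_in_male_stratum_rejected():
    with pytest.raises(ValidationError):
        make_events([("no", 2010, MALE, "Uterus unspecified", 9, 1)])


@settings(deadline=None, max_examples=25)
@given(
    cervix=st.integers(0, 50),
    corpus=st.integers(0, 50),
    c55=st.integers(0, 20),
    other_cells=st.lists(
        st.tuples(st.integers(2005, 2008), st.integers(0, 17), st.integers(0, 9)),
        max_size=4,
    ),
)
def test_c55_conserves_total_uterine_count(cervix, corpus, c55, other_cells):
    """Reallocation never creates or destroys uterine cases."""
    rows = [("no", 2010, FEMALE, "Cervix uteri", 9, cervix),
            ("no", 2010, FEMALE, "Corpus uteri", 9, corpus),
            ("no", 2010, FEMALE, "Uterus unspecified", 9, c55)]
    rows += [("no", y, FEMALE, "Uterus unspecified", a, n) for y, a, n in other_cells]
    ev = make_events(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = reallocate_unspecified_uterus(ev)
    assert out.total() == pytest.approx(ev.total())
    assert "Uterus unspecified" not in set(out.data["site"])


# ------------------------------------------------------------- rates transport


def test_compute_rates_basic_and_zero():
    ev = make_events([("no", 2010, MALE, "Lung", 9, 50), ("no", 2010, MALE, "Lung", 10, 0)])
    pop = uniform_population(["no"], [2010])
    rates = compute_rates(ev, pop).data.set_index("age_group")["rate"]
    assert rates[9] == pytest.approx(50.0)
    assert rates[10] == 0.0


def test_compute_rates_requires_person_years_for_cases():
    ev = make_events([("no", 2010, MALE, "Lung", 9, 50)])
    pop = uniform_population(["no"], [2011])
    with pytest.raises(ValidationError, match="Lung"):
        compute_rates(ev, pop)


def test_compute_rates_matches_elementwise_division():
    rng = np.random.default_rng(5)
    rows = [("no", 2010, MALE, "Lung", a, float(rng.integers(0, 40))) for a in range(18)]
    ev = make_events(rows)
    pop = make_population(
        [("no", 2010, s, a, float(rng.integers(10_000, 90_000)))
         for s in (MALE, FEMALE) for a in range(18)]
    )
    rates = compute_rates(ev, pop)
    merged = rates.data.merge(ev.data).merge(pop.data)
    np.testing.assert_allclose(
        merged["rate"], 1e5 * merged["count"] / merged["person_years"], rtol=1e-12
    )


def test_rate_round_trip_identity():
    """apply_rates(compute_rates(E, P), P) == E with full population coverage."""
    rng = np.random.default_rng(6)
    rows = [("no", y, s, "Lung", a, float(rng.integers(0, 30)))
            for y in (2009, 2010) for s in (MALE, FEMALE) for a in range(18)]
    ev = make_events(rows)
    pop = make_population(
        [("no", y, s, a, float(rng.integers(10_000, 90_000)))
         for y in (2009, 2010) for s in (MALE, FEMALE) for a in range(18)]
    )
    back = apply_rates(compute_rates(ev, pop), pop)
    merged = ev.data.merge(back.data, on=["dataset", "year", "sex", "site", "age_group"])
    np.testing.assert_allclose(merged["count_x"], merged["count_y"], rtol=1e-12)


def test_apply_rates_linearity_in_population():
    ev = make_events([("no", 2010, MALE, "Lung", 9, 50)])
    pop = uniform_population(["no"], [2010])
    doubled = make_population(pop.data.assign(person_years=pop.data["person_years"] * 2))
    rates = compute_rates(ev, pop)
    a = apply_rates(rates, pop).total()
    b = apply_rates(rates, doubled).total()
    assert b == pytest.approx(2 * a, rel=1e-12)


def test_pooled_rates_person_year_weighting():
    # two datasets with different denominators: pooled rate is the
    # count-sum over person-year-sum, not the mean of rates
    ev = make_events(
        [("a", 2010, MALE, "Lung", 9, 10), ("b", 2010, MALE, "Lung", 9, 90)]
    )
    pop = make_population(
        [("a", 2010, MALE, 9, 100_000.0), ("b", 2010, MALE, 9, 300_000.0)]
    )
    rt = pooled_rates(ev, pop, datasets=["a", "b"], years=(2010, 2010))
    assert rt.data["rate"].iloc[0] == pytest.approx(1e5 * 100 / 400_000)


# --------------------------------------------------------------- gold standard


def test_gold_standard_is_three_year_mean():
    rows = [("no", y, MALE, "Lung", 9, n) for y, n in [(2009, 300), (2010, 324), (2011, 348)]]
    obs = gold_standard(make_events(rows))
    assert obs.cases(MALE, "Lung") == pytest.approx(324.0)


def test_gold_standard_requires_every_year():
    rows = [("no", y, MALE, "Lung", 9, 1) for y in (2009, 2011)]
    with pytest.raises(ValidationError, match="2010"):
        gold_standard(make_events(rows))


def test_gold_standard_linearity():
    rng = np.random.default_rng(8)
    rows1 = [("no", y, MALE, "Lung", a, float(rng.integers(0, 20)))
             for y in (2009, 2010, 2011) for a in range(18)]
    rows2 = [("no", y, MALE, "Lung", a, float(rng.integers(0, 20)))
             for y in (2009, 2010, 2011) for a in range(18)]
    e1, e2 = make_events(rows1), make_events(rows2)
    combo = make_events(
        [(d, y, s, site, a, 2 * c) for d, y, s, site, a, c in e1.data.itertuples(index=False)]
        + list(e2.data.itertuples(index=False))
    )
    lhs = gold_standard(combo).cases(MALE, "Lung")
    rhs = 2 * gold_standard(e1).cases(MALE, "Lung") + gold_standard(e2).cases(MALE, "Lung")
    assert lhs == pytest.approx(rhs, rel=1e-12)


# ---------------------------------------------------------------- round trips


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_event_table_round_trip(tmp_path, seed):
    rng = np.random.default_rng(seed)
    rows = [("no", 2000 + int(rng.integers(0, 10)), MALE, "Lung", int(a), float(rng.integers(0, 50)))
            for a in rng.choice(18, size=10, replace=False)]
    ev = make_events(rows)
    path = tmp_path / "ev.csv"
    iio.write_event_table(ev, path)
    back = iio.read_registry_table(path, "incidence")
    lhs = ev.data.sort_values(["year", "age_group"]).reset_index(drop=True)
    rhs = back.data.sort_values(["year", "age_group"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(lhs, rhs, check_dtype=False)


def test_estimate_table_round_trip(tmp_path):
    detail = pd.DataFrame(
        {"sex": [MALE] * 3, "site": ["Lung"] * 3, "age_group": [8, 9, 10],
         "cases": [10.5, 20.25, 30.0]}
    )
    est = EstimateTable.from_detail("2", 2010, detail)
    path = tmp_path / "est.csv"
    iio.write_estimate_table(est, path)
    back = iio.read_estimate_table(path)
    assert back.method == "2" and back.target_year == 2010
    assert back.cases(MALE, "Lung") == pytest.approx(60.75)


def test_estimate_detail_must_aggregate_exactly():
    detail = pd.DataFrame(
        {"sex": [MALE], "site": ["Lung"], "age_group": [9], "cases": [10.0]}
    )
    data = pd.DataFrame({"sex": [MALE], "site": ["Lung"], "cases": [11.0]})
    with pytest.raises(ValidationError, match="aggregate"):
        EstimateTable("2", 2010, data, detail)


def test_round_half_away_from_zero():
    assert round_half_away(0.5) == 1.0
    assert round_half_away(-0.5) == -1.0
    assert round_half_away(2.5) == 3.0
    assert round_half_away(19.35, 1) == pytest.approx(19.4)
    assert round_half_away(-13.25, 1) == pytest.approx(-13.3)
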