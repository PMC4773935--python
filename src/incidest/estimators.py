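"""National incidence estimators beyond trend projection (methods 2-9).

All of these are variations on two primitives: *rate transport* (apply
age-sex-site rates from a proxy pool to the target country-year's
person-years) and *mortality inversion* (divide projected national
mortality rates by a case-fatality proxy, either a mortality:incidence
ratio from a regional/neighbour pool or ``1 - S`` from 5-year relative
survival, the relation M = I(1-S)).

Method numbering follows the standard estimation framework:

2. recent national rates applied to the target population;
3. national mortality x M:I ratios from regional registries;
4. national mortality x M:I ratios from neighbouring countries;
5. national mortality / (1 - S) with 5-year relative survival S;
6. rates from one regional registry (or region set) transported nationally;
7. rates from another (capital-style) regional registry;
8. all-sites neighbour rates partitioned by site-frequency proportions;
9. pooled site-specific neighbour rates transported nationally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sites import N_AGE_GROUPS
from .tables import (
    PER,
    EstimateTable,
    EventTable,
    PopulationTable,
    RateTable,
    SurvivalTable,
    ValidationError,
    pooled_rates,
)
from .projection import apply_rates_to_target

DEFAULT_REFERENCE_PERIOD = (2003, 2007)
DEFAULT_NEIGHBOUR_PERIOD = (2009, 2011)
#: Sites with fewer average annual national deaths than this pool
#: neighbouring countries into their M:I ratios.
DEFAULT_POOLING_THRESHOLD = 100.0
#: Cap on survival used in the M/(1-S) inversion, preventing blow-up
#: when S is at or above 1.
DEFAULT_S_CAP = 0.99


def _transport(method, rates, population, dataset, target_year) -> EstimateTable:
    detail = apply_rates_to_target(rates, population, dataset, target_year)
    return EstimateTable.from_detail(method, target_year, detail)


def method_2(
    incidence: EventTable,
    population: PopulationTable,
    target_year: int = 2010,
    reference_period: tuple[int, int] = DEFAULT_REFERENCE_PERIOD,
) -> EstimateTable:
    """Most recent recorded national rates applied to the target population."""
    dataset = population.data["dataset"].iloc[0]
    rates = pooled_rates(incidence, population, datasets=None, years=reference_period)
    return _transport("2", rates, population, dataset, target_year)


@dataclass
class MIRatioTable:
    """Mortality:incidence ratios per (sex, site, age_group).

    Age groups whose pooled incidence was zero are merged downward (into
    the adjacent younger group, repeatedly) before the ratio is taken, so
    each stored ratio is finite; the age_group column then maps every
    original band to its merged cell's ratio. ``provenance`` records which
    datasets were pooled per (sex, site).
    """

    data: pd.DataFrame  # columns: sex, site, age_group, ratio
    provenance: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data, columns=["sex", "site", "age_group", "ratio"]).copy()
        df["ratio"] = df["ratio"].astype(float)
        if not np.isfinite(df["ratio"]).all() or (df["ratio"] < 0).any():
            raise ValidationError("M:I ratios must be finite and non-negative")
        self.data = df.reset_index(drop=True)


def _merged_ratios(inc_by_age: np.ndarray, mort_by_age: np.ndarray) -> np.ndarray:
    """Per-age ratios with sparse ages merged into adjacent younger groups.

    Zero-incidence ages merge into the adjacent younger group (repeatedly)
    until every cell's denominator is positive. Whenever the site has any
    pooled deaths at all, cells left with a zero ratio then borrow the
    ratio of the nearest death-bearing cell (older preferred) - without
    pooling their cases into it, which would dilute that cell's case
    fatality - so every stored ratio is finite and positive wherever an
    inversion can need to divide by it.
    """
    ratios = np.zeros(N_AGE_GROUPS)
    # walk upward keeping a running cell; a zero-incidence age joins the
    # cell below it (deaths and cases both accumulate)
    cell_inc, cell_mort, members = 0.0, 0.0, []
    cells: list[tuple[list[int], float, float]] = []
    for a in range(N_AGE_GROUPS):
        members.append(a)
        cell_inc += inc_by_age[a]
        cell_mort += mort_by_age[a]
        if inc_by_age[a] > 0:
            cells.append((list(members), cell_inc, cell_mort))
            cell_inc, cell_mort, members = 0.0, 0.0, []
    if members:
        # trailing ages with no incidence merge into the last closed cell
        if not cells:
            raise ValidationError("site has zero pooled incidence at all ages")
        prev_members, prev_inc, prev_mort = cells[-1]
        cells[-1] = (prev_members + members, prev_inc + cell_inc, prev_mort + cell_mort)
    cell_ratios = [mort / inc for _, inc, mort in cells]
    if mort_by_age.sum() > 0:
        for i, r in enumerate(cell_ratios):
            if r == 0.0:
                donors = [j for j in range(i + 1, len(cells)) if cell_ratios[j] > 0]
                donors = donors or [j for j in range(i - 1, -1, -1) if cell_ratios[j] > 0]
                cell_ratios[i] = cell_ratios[donors[0]]
    for (members, _, _), r in zip(cells, cell_ratios):
        for a in members:
            ratios[a] = r
    return ratios


def compute_mi_ratios(
    incidence: EventTable,
    mortality: EventTable,
    *,
    proxy_datasets,
    neighbour_datasets=(),
    national_mortality: EventTable | None = None,
    pooling_threshold: float = DEFAULT_POOLING_THRESHOLD,
    reference_period: tuple[int, int] = DEFAULT_REFERENCE_PERIOD,
) -> MIRatioTable:
    """Pool deaths over cases into age-specific M:I ratios.

    Ratios are pooled over ``proxy_datasets`` for the reference period.
    For sites whose national average annual deaths (from
    ``national_mortality``) fall below ``pooling_threshold``, the
    neighbour datasets are added to the pool before the ratio is taken.
    Age groups with zero pooled incidence are merged downward until the
    denominator is positive; a site with zero pooled incidence at every
    age raises.
    """
    proxy = list(proxy_datasets)
    neighbours = list(neighbour_datasets)
    inc = incidence.subset(years=reference_period)
    mort = mortality.subset(years=reference_period)

    small_sites: set[tuple[str, str]] = set()
    if national_mortality is not None and neighbours:
        n_years = reference_period[1] - reference_period[0] + 1
        nat = national_mortality.subset(years=reference_period).data
        annual = nat.groupby(["sex", "site"])["count"].sum() / n_years
        small_sites = {key for key, v in annual.items() if v < pooling_threshold}

    sites = inc.subset(datasets=proxy + neighbours).data.groupby("sex")["site"].unique()
    rows = []
    provenance: dict[tuple[str, str], tuple[str, ...]] = {}
    for sex, site_list in sites.items():
        for site in sorted(site_list):
            pool = proxy + neighbours if (sex, site) in small_sites else proxy
            provenance[(sex, site)] = tuple(pool)
            pi = inc.subset(datasets=pool, sexes=[sex], sites=[site]).data
            pm = mort.subset(datasets=pool, sexes=[sex], sites=[site]).data
            inc_by_age = np.zeros(N_AGE_GROUPS)
            mort_by_age = np.zeros(N_AGE_GROUPS)
            for _, r in pi.iterrows():
                inc_by_age[int(r["age_group"])] += r["count"]
            for _, r in pm.iterrows():
                mort_by_age[int(r["age_group"])] += r["count"]
            if inc_by_age.sum() == 0:
                raise ValidationError(f"zero pooled incidence at all ages for ({sex}, {site})")
            ratios = _merged_ratios(inc_by_age, mort_by_age)
            for a in range(N_AGE_GROUPS):
                rows.append({"sex": sex, "site": site, "age_group": a, "ratio": ratios[a]})
    return MIRatioTable(pd.DataFrame(rows), provenance)


def _mortality_inversion(
    method: str,
    projected_mortality: RateTable,
    ratio_of,  # callable (sex, site, age_group) -> M:I ratio
    population: PopulationTable,
    target_year: int,
) -> EstimateTable:
    dataset = population.data["dataset"].iloc[0]
    rows = []
    for _, r in projected_mortality.data.iterrows():
        sex, site, age = r["sex"], r["site"], int(r["age_group"])
        m = float(r["rate"])
        ratio = ratio_of(sex, site, age)
        if m == 0.0:
            # the documented failure mode: no deaths implies no estimated
            # cases even where incidence exists
            rows.append({"sex": sex, "site": site, "age_group": age, "rate": 0.0})
            continue
        if ratio == 0.0:
            raise ValidationError(
                f"zero M:I ratio with nonzero mortality for ({sex}, {site}, age {age})"
            )
        rows.append({"sex": sex, "site": site, "age_group": age, "rate": m / ratio})
    zero_m = projected_mortality.data[projected_mortality.data["rate"] == 0.0]
    if not zero_m.empty:
        pairs = sorted(set(zip(zero_m["sex"], zero_m["site"])))
        warnings.warn(
            f"method {method}: zero projected mortality yields zero estimated incidence "
            f"in some age groups of {len(pairs)} (sex, site) pairs",
            stacklevel=3,
        )
    rates = RateTable(pd.DataFrame(rows))
    return _transport(method, rates, population, dataset, target_year)


def method_3(
    projected_national_mortality: RateTable,
    mi: MIRatioTable,
    population: PopulationTable,
    target_year: int = 2010,
) -> EstimateTable:
    """National mortality divided by regional-registry M:I ratios."""
    idx = mi.data.set_index(["sex", "site", "age_group"])["ratio"]

    def ratio_of(sex, site, age):
        try:
            return float(idx.loc[(sex, site, age)])
        except KeyError:
            raise ValidationError(f"M:I table does not cover ({sex}, {site}, age {age})") from None

    return _mortality_inversion("3", projected_national_mortality, ratio_of, population, target_year)


def method_4(
    projected_national_mortality: RateTable,
    mi_from_neighbours: MIRatioTable,
    population: PopulationTable,
    target_year: int = 2010,
) -> EstimateTable:
    """As method 3, with M:I ratios pooled from neighbouring countries."""
    est = method_3(projected_national_mortality, mi_from_neighbours, population, target_year)
    return EstimateTable("4", est.target_year, est.data, est.detail)


def method_5(
    projected_national_mortality: RateTable,
    survival: SurvivalTable,
    population: PopulationTable,
    target_year: int = 2010,
    s_cap: float = DEFAULT_S_CAP,
) -> EstimateTable:
    """Survival inversion of M = I(1-S): incidence rate I = M / (1 - S).

    S is the (sex, site)-level 5-year relative survival proportion, capped
    at ``s_cap`` so near-complete survival cannot blow the inversion up;
    capped sites are flagged with a warning as unreliable.
    """
    capped = []
    rows = []
    for _, r in projected_national_mortality.data.iterrows():
        s = survival.lookup(r["sex"], r["site"])
        if s > s_cap:
            capped.append((r["sex"], r["site"]))
        s_eff = min(s, s_cap)
        rows.append(
            {
                "sex": r["sex"],
                "site": r["site"],
                "age_group": int(r["age_group"]),
                "rate": float(r["rate"]) / (1.0 - s_eff),
            }
        )
    if capped:
        warnings.warn(
            f"survival capped at {DEFAULT_S_CAP} for sites {sorted(set(capped))}; "
            "estimates there are unreliable",
            stacklevel=2,
        )
    dataset = population.data["dataset"].iloc[0]
    return _transport("5", RateTable(pd.DataFrame(rows)), population, dataset, target_year)


def _regional(
    method: str,
    regional_incidence: EventTable,
    regional_population: PopulationTable,
    national_population: PopulationTable,
    regions,
    target_year,
    reference_period,
) -> EstimateTable:
    rates = pooled_rates(
        regional_incidence, regional_population, datasets=list(regions), years=reference_period
    )
    dataset = national_population.data["dataset"].iloc[0]
    return _transport(method, rates, national_population, dataset, target_year)


def method_6(
    regional_incidence: EventTable,
    regional_population: PopulationTable,
    national_population: PopulationTable,
    *,
    regions,
    target_year: int = 2010,
    reference_period: tuple[int, int] = DEFAULT_REFERENCE_PERIOD,
) -> EstimateTable:
    """Rates from a regional-registry pool applied to the national population."""
    return _regional(
        "6", regional_incidence, regional_population, national_population,
        regions, target_year, reference_period,
    )


def method_7(
    regional_incidence: EventTable,
    regional_population: PopulationTable,
    national_population: PopulationTable,
    *,
    regions,
    target_year: int = 2010,
    reference_period: tuple[int, int] = DEFAULT_REFERENCE_PERIOD,
) -> EstimateTable:
    """As method 6 with a different (typically capital-region) proxy set."""
    return _regional(
        "7", regional_incidence, regional_population, national_population,
        regions, target_year, reference_period,
    )


@dataclass
class FrequencyTable:
    """Per-sex proportions of all-sites cases by site (sum to 1 per sex)."""

    data: pd.DataFrame  # columns: sex, site, proportion

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data, columns=["sex", "site", "proportion"]).copy()
        df["proportion"] = df["proportion"].astype(float)
        sums = df.groupby("sex")["proportion"].sum()
        if not np.allclose(sums, 1.0, rtol=0, atol=1e-9):
            raise ValidationError(f"site proportions must sum to 1 per sex; got {dict(sums)}")
        self.data = df.reset_index(drop=True)


def build_frequency_table(
    events: EventTable,
    *,
    datasets,
    window: tuple[int, int] = DEFAULT_NEIGHBOUR_PERIOD,
) -> FrequencyTable:
    """Site frequency (proportion of all-sites cases) per sex over a pool."""
    df = events.subset(datasets=list(datasets), years=window).data
    by_site = df.groupby(["sex", "site"], as_index=False)["count"].sum()
    totals = by_site.groupby("sex")["count"].transform("sum")
    if (by_site.groupby("sex")["count"].sum() == 0).any():
        raise ValidationError("zero total cases for a sex in the frequency window")
    by_site["proportion"] = by_site["count"] / totals
    return FrequencyTable(by_site[["sex", "site", "proportion"]])


def method_8(
    all_sites_rates: RateTable,
    frequencies: FrequencyTable,
    population: PopulationTable,
    target_year: int = 2010,
) -> EstimateTable:
    """All-sites rate transport partitioned across sites by frequency.

    ``all_sites_rates`` holds rates per (sex, age_group) for all cancers
    combined (site label ignored). The all-sites expected cases per sex are
    then split across sites by the per-sex frequency table; the site totals
    sum to the all-sites total exactly by construction.
    """
    dataset = population.data["dataset"].iloc[0]
    pop = population.data
    pop = pop[(pop["dataset"] == dataset) & (pop["year"] == target_year)]
    merged = all_sites_rates.data.merge(pop[["sex", "age_group", "person_years"]], on=["sex", "age_group"], how="left")
    if merged["person_years"].isna().any():
        raise ValidationError("target population does not cover all-sites rate strata")
    merged["cases"] = merged["rate"] * merged["person_years"] / PER
    per_sex = merged.groupby("sex")["cases"].sum()
    freq = frequencies.data
    missing = set(per_sex.index) - set(freq["sex"].unique())
    if missing:
        raise ValidationError(f"frequency table missing sexes {sorted(missing)}")
    out = freq.copy()
    out["cases"] = [per_sex[s] * p for s, p in zip(freq["sex"], freq["proportion"])]
    return EstimateTable("8", target_year, out[["sex", "site", "cases"]])


def method_9(
    neighbour_incidence: EventTable,
    neighbour_population: PopulationTable,
    national_population: PopulationTable,
    *,
    neighbours,
    target_year: int = 2010,
    window: tuple[int, int] = DEFAULT_NEIGHBOUR_PERIOD,
) -> EstimateTable:
    """Pooled neighbouring-country rates applied to the national population.

    Neighbour counts and person-years are summed into one pool
    (person-year-weighted), not averaged country by country.
    """
    rates = pooled_rates(
        neighbour_incidence, neighbour_population, datasets=list(neighbours), years=window
    )
    dataset = national_population.data["dataset"].iloc[0]
    return _transport("9", rates, national_population, dataset, target_year)


@dataclass
class DataAvailability:
    """Which inputs exist for a country, for method selection."""

    national_incidence_history: bool = False
    recent_national_incidence: bool = False
    regional_registries: bool = False
    regional_registry_count: int = 0
    national_mortality: bool = False
    neighbour_data: bool = False
    frequency_data: bool = False
    survival: bool = False


def select_method(availability: DataAvailability) -> str:
    """First applicable method in the standard selection priority order.

    Priority: 1 (historical national incidence), 2 (recent national
    incidence), 3 (national mortality + regional registries), 4 (national
    mortality + neighbour data), 5 (national mortality + survival),
    6/7 (regional registries alone; 6 for a single registry, 7 for
    several), 8 (all-sites + frequency data), 9 (neighbour data alone).
    """
    a = availability
    if a.national_incidence_history:
        return "1"
    if a.recent_national_incidence:
        return "2"
    if a.national_mortality and a.regional_registries:
        return "3"
    if a.national_mortality and a.neighbour_data:
        return "4"
    if a.national_mortality and a.survival:
        return "5"
    if a.regional_registries:
        return "6" if a.regional_registry_count <= 1 else "7"
    if a.frequency_data and a.neighbour_data:
        return "8"
    if a.neighbour_data:
        return "9"
    raise ValidationError("no estimation method is applicable: no usable inputs")
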