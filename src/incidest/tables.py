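"""Core stratified registry tables and rate arithmetic.

All tables are thin wrappers over long-format :class:`pandas.DataFrame`
objects with fixed column schemas:

``EventTable``
    ``dataset, year, sex, site, age_group, count`` — incidence or mortality
    counts per stratum. A missing stratum means zero, not unknown. Counts
    are integers as recorded but become reals after the C55 reallocation.
``PopulationTable``
    ``dataset, year, sex, age_group, person_years`` — mid-year population
    approximating person-years at risk.
``RateTable``
    event columns with ``count`` replaced by ``rate`` (per 100 000
    person-years); key columns other than ``sex, site, age_group`` are
    optional depending on how the rates were pooled.
``SurvivalTable``
    ``sex, site, survival_5yr`` — 5-year relative survival proportions.
``EstimateTable``
    per-(sex, site) estimated cases for a target year, with optional
    age-resolved detail whose aggregation reproduces the totals exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sites import (
    FEMALE,
    MALE,
    N_AGE_GROUPS,
    SEXES,
    UTERUS_UNSPECIFIED,
    group_for,
    valid_sex_site,
)

logger = logging.getLogger(__name__)

PER = 100_000.0  # rate denominator: cases per 100 000 person-years

EVENT_COLUMNS = ["dataset", "year", "sex", "site", "age_group", "count"]
POPULATION_COLUMNS = ["dataset", "year", "sex", "age_group", "person_years"]
SURVIVAL_COLUMNS = ["sex", "site", "survival_5yr"]
STRATUM_COLUMNS = ["dataset", "year", "sex", "site", "age_group"]


class ValidationError(ValueError):
    """A table violated a structural invariant (bad sex, site, count...)."""


class FormatError(ValueError):
    """A delimited input file did not have the expected columns."""


def _check_age_groups(values: pd.Series) -> None:
    bad = ~values.isin(range(N_AGE_GROUPS))
    if bad.any():
        raise ValidationError(
            f"age_group indices must be 0..{N_AGE_GROUPS - 1}; "
            f"offending values: {sorted(values[bad].unique())[:5]}"
        )


def _check_sexes(values: pd.Series) -> None:
    bad = ~values.isin(SEXES)
    if bad.any():
        raise ValidationError(
            f"sex must be one of {SEXES}; offending values: "
            f"{sorted(values[bad].unique())[:5]}"
        )


@dataclass
class EventTable:
    """Stratified incidence or mortality counts."""

    kind: str  # "incidence" | "mortality"
    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self) -> None:
        if self.kind not in ("incidence", "mortality"):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        df = pd.DataFrame(self.data, columns=EVENT_COLUMNS).copy()
        df["year"] = df["year"].astype(int)
        df["age_group"] = df["age_group"].astype(int)
        df["count"] = df["count"].astype(float)
        _check_sexes(df["sex"])
        _check_age_groups(df["age_group"])
        if (df["count"] < 0).any():
            raise ValidationError("negative counts are not allowed")
        pairs = df[["sex", "site"]].drop_duplicates()
        for sex, site in pairs.itertuples(index=False):
            if not valid_sex_site(sex, site):
                row = df[(df["sex"] == sex) & (df["site"] == site)].iloc[0]
                raise ValidationError(
                    f"sex-site conflict: site {site!r} cannot occur for sex {sex!r} "
                    f"(dataset={row['dataset']}, year={row['year']})"
                )
        self.data = df.reset_index(drop=True)

    def total(self) -> float:
        return float(self.data["count"].sum())

    def subset(self, *, datasets=None, years=None, sexes=None, sites=None) -> "EventTable":
        """Restrict to the given datasets / closed year range / sexes / sites."""
        df = self.data
        if datasets is not None:
            df = df[df["dataset"].isin(list(datasets))]
        if years is not None:
            lo, hi = years
            df = df[(df["year"] >= lo) & (df["year"] <= hi)]
        if sexes is not None:
            df = df[df["sex"].isin(list(sexes))]
        if sites is not None:
            df = df[df["site"].isin(list(sites))]
        return EventTable(self.kind, df)

    def relabel_dataset(self, name: str) -> "EventTable":
        """Sum strata across datasets into a single dataset label ``name``."""
        df = (
            self.data.groupby(["year", "sex", "site", "age_group"], as_index=False)["count"]
            .sum()
            .assign(dataset=name)
        )
        return EventTable(self.kind, df[EVENT_COLUMNS])


@dataclass
class PopulationTable:
    """Person-years at risk per (dataset, year, sex, age_group)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data, columns=POPULATION_COLUMNS).copy()
        df["year"] = df["year"].astype(int)
        df["age_group"] = df["age_group"].astype(int)
        df["person_years"] = df["person_years"].astype(float)
        _check_sexes(df["sex"])
        _check_age_groups(df["age_group"])
        if (df["person_years"] <= 0).any():
            raise ValidationError("person-years must be positive")
        dup = df.duplicated(subset=["dataset", "year", "sex", "age_group"])
        if dup.any():
            raise ValidationError("duplicate population strata")
        self.data = df.reset_index(drop=True)

    def subset(self, *, datasets=None, years=None) -> "PopulationTable":
        df = self.data
        if datasets is not None:
            df = df[df["dataset"].isin(list(datasets))]
        if years is not None:
            lo, hi = years
            df = df[(df["year"] >= lo) & (df["year"] <= hi)]
        return PopulationTable(df)

    def relabel_dataset(self, name: str) -> "PopulationTable":
        df = (
            self.data.groupby(["year", "sex", "age_group"], as_index=False)["person_years"]
            .sum()
            .assign(dataset=name)
        )
        return PopulationTable(df[POPULATION_COLUMNS])


@dataclass
class SurvivalTable:
    """5-year relative survival proportion per (sex, site).

    Values are typically in [0, 1] but may marginally exceed 1 in registry
    practice; negative values are invalid.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data, columns=SURVIVAL_COLUMNS).copy()
        df["survival_5yr"] = df["survival_5yr"].astype(float)
        _check_sexes(df["sex"])
        if (df["survival_5yr"] < 0).any():
            raise ValidationError("survival proportions must be non-negative")
        self.data = df.reset_index(drop=True)

    def lookup(self, sex: str, site: str) -> float:
        hit = self.data[(self.data["sex"] == sex) & (self.data["site"] == site)]
        if hit.empty:
            raise KeyError((sex, site))
        return float(hit["survival_5yr"].iloc[0])


@dataclass
class RateTable:
    """Rates per 100 000 person-years; key columns depend on pooling."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "rate" not in df.columns:
            raise ValidationError("RateTable requires a 'rate' column")
        df["rate"] = df["rate"].astype(float)
        if not np.isfinite(df["rate"]).all():
            raise ValidationError("rates must be finite")
        if (df["rate"] < 0).any():
            raise ValidationError("rates must be non-negative")
        self.data = df.reset_index(drop=True)


@dataclass
class EstimateTable:
    """Estimated national cases for a target year by (sex, site)."""

    method: str
    target_year: int
    data: pd.DataFrame  # columns: sex, site, cases
    detail: pd.DataFrame | None = None  # columns: sex, site, age_group, cases

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data, columns=["sex", "site", "cases"]).copy()
        df["cases"] = df["cases"].astype(float)
        _check_sexes(df["sex"])
        if (df["cases"] < 0).any():
            raise ValidationError("estimated cases must be non-negative")
        self.data = df.sort_values(["sex", "site"]).reset_index(drop=True)
        if self.detail is not None:
            det = pd.DataFrame(self.detail, columns=["sex", "site", "age_group", "cases"]).copy()
            det["cases"] = det["cases"].astype(float)
            agg = det.groupby(["sex", "site"], as_index=False)["cases"].sum()
            merged = self.data.merge(agg, on=["sex", "site"], how="outer", suffixes=("", "_agg"))
            if not np.allclose(
                merged["cases"].fillna(0.0), merged["cases_agg"].fillna(0.0), rtol=0, atol=1e-9
            ):
                raise ValidationError("age-resolved detail does not aggregate to totals")
            self.detail = det.reset_index(drop=True)

    @classmethod
    def from_detail(cls, method: str, target_year: int, detail: pd.DataFrame) -> "EstimateTable":
        """Build with site totals derived from age-resolved cases (exact)."""
        totals = detail.groupby(["sex", "site"], as_index=False)["cases"].sum()
        return cls(method, target_year, totals, detail)

    def cases(self, sex: str, site: str) -> float:
        hit = self.data[(self.data["sex"] == sex) & (self.data["site"] == site)]
        return float(hit["cases"].iloc[0]) if not hit.empty else 0.0

    def sex_view(self, sex: str) -> pd.Series:
        """Series of cases indexed by site for one sex."""
        df = self.data[self.data["sex"] == sex]
        return df.set_index("site")["cases"]


# ---------------------------------------------------------------------------
# operations


def group_sites(events: EventTable) -> EventTable:
    """Map raw ICD-10 rubrics to site groups and sum counts within groups.

    Count totals are conserved exactly. Rubrics that belong to no named
    group fall into "Other and unspecified" (with a warning the first time);
    non-melanoma skin (C44) is dropped, as it is excluded from the site
    partition by convention.
    """
    df = events.data.copy()
    mapped = []
    dropped = 0.0
    unknown: set[str] = set()
    for token in df["site"].unique():
        try:
            name = group_for(token).name
        except KeyError:
            if token.strip().upper().startswith("C44"):
                name = None
            else:
                raise ValidationError(f"unrecognized site or ICD-10 code {token!r}") from None
        mapped.append((token, name))
    name_of = dict(mapped)
    drop_mask = df["site"].map(name_of).isna()
    dropped = float(df.loc[drop_mask, "count"].sum())
    if dropped:
        warnings.warn(f"dropping {dropped:g} non-melanoma skin (C44) cases", stacklevel=2)
    df = df[~drop_mask].copy()
    raw_other = {
        t for t, n in name_of.items() if n == "Other and unspecified" and t != "Other and unspecified"
    }
    if raw_other:
        logger.info("codes absorbed by catch-all group: %s", sorted(raw_other))
    df["site"] = df["site"].map(name_of)
    out = df.groupby(STRATUM_COLUMNS, as_index=False)["count"].sum()
    return EventTable(events.kind, out)


def reallocate_unspecified_uterus(events: EventTable) -> EventTable:
    """Split "uterus, unspecified" (C55) counts between cervix and corpus.

    Within each (dataset, year, age_group) cell the C55 count is divided
    proportionally to the recorded cervix (C53) and corpus (C54) counts of
    the same cell. Cells where both are zero fall back to the dataset-level
    cervix/corpus proportions (all years and ages pooled); if those are also
    zero the split is 50/50 (with a warning). The total uterine count is
    conserved exactly per cell and the staging group is removed from the
    output.
    """
    df = events.data
    c55 = df[df["site"] == UTERUS_UNSPECIFIED]
    if c55.empty:
        return EventTable(events.kind, df[df["site"] != UTERUS_UNSPECIFIED])
    if (c55["sex"] != FEMALE).any():
        raise ValidationError("unspecified uterus (C55) present in a male stratum")

    rest = df[df["site"] != UTERUS_UNSPECIFIED].copy()
    cell_keys = ["dataset", "year", "age_group"]
    cc = rest[(rest["sex"] == FEMALE) & rest["site"].isin(["Cervix uteri", "Corpus uteri"])]
    cell = cc.pivot_table(index=cell_keys, columns="site", values="count", aggfunc="sum").reindex(
        columns=["Cervix uteri", "Corpus uteri"], fill_value=0.0
    ).fillna(0.0)
    ds = cc.pivot_table(index="dataset", columns="site", values="count", aggfunc="sum").reindex(
        columns=["Cervix uteri", "Corpus uteri"], fill_value=0.0
    ).fillna(0.0)

    extra_rows = []
    fell_back_5050 = False
    for _, row in c55.iterrows():
        key = (row["dataset"], row["year"], row["age_group"])
        cervix = corpus = 0.0
        if key in cell.index:
            cervix, corpus = cell.loc[key, "Cervix uteri"], cell.loc[key, "Corpus uteri"]
        if cervix + corpus == 0 and row["dataset"] in ds.index:
            cervix, corpus = ds.loc[row["dataset"], "Cervix uteri"], ds.loc[row["dataset"], "Corpus uteri"]
        if cervix + corpus == 0:
            cervix = corpus = 1.0
            fell_back_5050 = True
        p = cervix / (cervix + corpus)
        for site, share in (("Cervix uteri", p), ("Corpus uteri", 1.0 - p)):
            extra_rows.append(
                {
                    "dataset": row["dataset"],
                    "year": row["year"],
                    "sex": FEMALE,
                    "site": site,
                    "age_group": row["age_group"],
                    "count": row["count"] * share,
                }
            )
    if fell_back_5050:
        warnings.warn(
            "no cervix/corpus counts available for some strata; C55 split 50/50", stacklevel=2
        )
    out = pd.concat([rest, pd.DataFrame(extra_rows, columns=EVENT_COLUMNS)], ignore_index=True)
    out = out.groupby(STRATUM_COLUMNS, as_index=False)["count"].sum()
    return EventTable(events.kind, out)


def compute_rates(events: EventTable, population: PopulationTable) -> RateTable:
    """Per-stratum rates: 100 000 x count / person-years.

    Every stratum with a nonzero count must have positive person-years;
    strata present in the events with zero count get rate 0.
    """
    merged = events.data.merge(
        population.data, on=["dataset", "year", "sex", "age_group"], how="left"
    )
    missing = merged["person_years"].isna() & (merged["count"] > 0)
    if missing.any():
        row = merged[missing].iloc[0]
        raise ValidationError(
            "no person-years for stratum with cases: "
            f"({row['dataset']}, {row['year']}, {row['sex']}, {row['site']}, "
            f"age_group={row['age_group']})"
        )
    merged["rate"] = np.where(
        merged["count"] > 0, PER * merged["count"] / merged["person_years"], 0.0
    )
    return RateTable(merged[STRATUM_COLUMNS + ["rate"]])


def pooled_rates(
    events: EventTable,
    population: PopulationTable,
    *,
    datasets,
    years,
) -> RateTable:
    """Person-year-weighted average annual rates over a pool.

    Counts per (sex, site, age_group) are summed over the given datasets and
    closed year range and divided by the summed person-years of the same
    (sex, age_group) pool. This is the pooling used for rate transport
    (methods based on recent, regional or neighbouring-country rates).
    """
    ev = events.subset(datasets=datasets, years=years).data
    pop = population.subset(datasets=datasets, years=years).data
    if pop.empty:
        raise ValidationError("no person-years in the requested pool")
    counts = ev.groupby(["sex", "site", "age_group"], as_index=False)["count"].sum()
    py = pop.groupby(["sex", "age_group"], as_index=False)["person_years"].sum()
    merged = counts.merge(py, on=["sex", "age_group"], how="left")
    if merged["person_years"].isna().any():
        row = merged[merged["person_years"].isna()].iloc[0]
        raise ValidationError(
            f"no person-years for pooled stratum ({row['sex']}, {row['site']}, "
            f"age_group={row['age_group']})"
        )
    merged["rate"] = PER * merged["count"] / merged["person_years"]
    return RateTable(merged[["sex", "site", "age_group", "rate"]])


def apply_rates(
    rates: RateTable,
    population: PopulationTable,
    *,
    dataset: str | None = None,
    year: int | None = None,
) -> EventTable:
    """Transport rates onto a population: expected count = rate x PY / 1e5.

    Join keys are ``sex`` and ``age_group`` plus whichever of
    ``dataset``/``year`` appear in both the rate table and the population
    (so per-stratum rate tables round-trip exactly). ``dataset``/``year``
    restrict the population side first, e.g. to the target country-year.
    """
    pop = population.data
    if dataset is not None:
        pop = pop[pop["dataset"] == dataset]
    if year is not None:
        pop = pop[pop["year"] == year]
    if pop.empty:
        raise ValidationError("no population strata selected for rate application")
    keys = ["sex", "age_group"] + [
        k for k in ("dataset", "year") if k in rates.data.columns and rates.data[k].notna().all()
    ]
    merged = rates.data.merge(pop, on=keys, how="left", suffixes=("_rate", ""))
    if merged["person_years"].isna().any():
        row = merged[merged["person_years"].isna()].iloc[0]
        raise ValidationError(
            f"population missing stratum ({row.get('sex')}, age_group={row.get('age_group')})"
        )
    merged["count"] = merged["rate"] * merged["person_years"] / PER
    if "dataset" not in merged.columns or dataset is not None:
        merged["dataset"] = dataset if dataset is not None else merged.get("dataset")
    if year is not None:
        merged["year"] = year
    out = merged[EVENT_COLUMNS]
    return EventTable("incidence", out)


def gold_standard(
    events: EventTable,
    years: tuple[int, int] = (2009, 2011),
    *,
    target_year: int = 2010,
) -> EstimateTable:
    """Observed reference: mean annual recorded cases over a year range.

    The default 2009-2011 window centred on 2010 defines the validation
    gold standard. Every year in the range must be present in the table
    (a year with zero cases overall would be indistinguishable from a
    missing extract).
    """
    lo, hi = years
    present = set(events.data["year"].unique())
    missing = [y for y in range(lo, hi + 1) if y not in present]
    if missing:
        raise ValidationError(f"gold-standard years missing from events: {missing}")
    window = events.subset(years=years).data
    n_years = hi - lo + 1
    det = (
        window.groupby(["sex", "site", "age_group"], as_index=False)["count"]
        .sum()
        .assign(cases=lambda d: d["count"] / n_years)
        [["sex", "site", "age_group", "cases"]]
    )
    return EstimateTable.from_detail("observed", target_year, det)
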