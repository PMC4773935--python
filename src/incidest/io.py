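"""Delimited-text readers/writers and the bundled directory layout.

All files are UTF-8 delimited text (comma by default; tab accepted), long
format with a header row. A registry bundle is a directory holding
``incidence.csv``, ``mortality.csv``, ``population.csv``, ``survival.csv``
and ``bundle.yaml`` (dataset roles: which datasets are the country's
regions, which are neighbouring countries, and the region sets used by the
regional-proxy methods). Synthetic bundles additionally carry
``truth.csv`` with the generator's expected 2010 national incidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .sites import AGE_LABELS, N_AGE_GROUPS, group_for
from .tables import (
    EVENT_COLUMNS,
    POPULATION_COLUMNS,
    SURVIVAL_COLUMNS,
    EstimateTable,
    EventTable,
    FormatError,
    PopulationTable,
    SurvivalTable,
    ValidationError,
)

_AGE_INDEX = {label: i for i, label in enumerate(AGE_LABELS)}
_AGE_INDEX.update({"85-89": 17, "90+": 18})  # 19-band inputs, collapsed on read


def _read_delimited(path, expected: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype={"dataset": str, "site": str})
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_age_column(values: pd.Series, path) -> pd.Series:
    """Accept integer band indices 0..17 or labels like "0-4", "85+"."""
    def parse(v, row):
        if isinstance(v, str) and v.strip() in _AGE_INDEX:
            return _AGE_INDEX[v.strip()]
        try:
            return int(v)
        except (TypeError, ValueError):
            raise FormatError(f"{path} row {row + 2}: unparseable age_group {v!r}") from None

    idx = pd.Series([parse(v, i) for i, v in enumerate(values)], index=values.index)
    if (idx == 18).any():
        warnings.warn("19-band age input detected; collapsing 85-89/90+ into 85+", stacklevel=3)
        idx = idx.clip(upper=N_AGE_GROUPS - 1)
    return idx


def read_registry_table(path, kind: str) -> EventTable:
    """Read a long-format event file into a validated :class:`EventTable`.

    Required columns: dataset, year, sex, site, age_group, count. The site
    column may hold group names or raw ICD-10 rubrics (rubrics are mapped
    to groups). Duplicate strata are summed with a warning; invalid rows
    raise with 1-based file row numbers in the message.
    """
    df = _read_delimited(path, EVENT_COLUMNS)
    df["age_group"] = _parse_age_column(df["age_group"], path)
    if (pd.to_numeric(df["count"], errors="coerce") < 0).any():
        bad = df.index[pd.to_numeric(df["count"], errors="coerce") < 0][0]
        raise ValidationError(f"{path} row {bad + 2}: negative count")
    df["site"] = [group_for(s).name for s in df["site"]]
    dup = df.duplicated(subset=["dataset", "year", "sex", "site", "age_group"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:6]]
        warnings.warn(f"{path}: duplicate strata at rows {rows}; counts summed", stacklevel=2)
        df = df.groupby(["dataset", "year", "sex", "site", "age_group"], as_index=False)["count"].sum()
    return EventTable(kind, df[EVENT_COLUMNS])


def read_population_table(path) -> PopulationTable:
    df = _read_delimited(path, POPULATION_COLUMNS)
    df["age_group"] = _parse_age_column(df["age_group"], path)
    if (df["age_group"] == N_AGE_GROUPS - 1).any() and "85-89" in set(map(str, df["age_group"])):
        pass  # collapsed above
    df = df.groupby(["dataset", "year", "sex", "age_group"], as_index=False)["person_years"].sum()
    return PopulationTable(df[POPULATION_COLUMNS])


def read_survival_table(path) -> SurvivalTable:
    df = _read_delimited(path, SURVIVAL_COLUMNS)
    df["site"] = [group_for(s).name for s in df["site"]]
    return SurvivalTable(df[SURVIVAL_COLUMNS])


def write_event_table(events: EventTable, path) -> None:
    events.data[EVENT_COLUMNS].to_csv(path, index=False)


def write_population_table(pop: PopulationTable, path) -> None:
    pop.data[POPULATION_COLUMNS].to_csv(path, index=False)


def write_survival_table(surv: SurvivalTable, path) -> None:
    surv.data[SURVIVAL_COLUMNS].to_csv(path, index=False)


def write_estimate_table(est: EstimateTable, path) -> None:
    """Long-format estimate output; age-resolved when detail is present."""
    if est.detail is not None:
        df = est.detail.copy()
        df.insert(0, "target_year", est.target_year)
        df.insert(0, "method", est.method)
        df[["method", "target_year", "sex", "site", "age_group", "cases"]].to_csv(path, index=False)
    else:
        df = est.data.copy()
        df.insert(0, "target_year", est.target_year)
        df.insert(0, "method", est.method)
        df.to_csv(path, index=False)


def read_estimate_table(path) -> EstimateTable:
    df = pd.read_csv(path, dtype={"site": str})
    method = str(df["method"].iloc[0])
    target_year = int(df["target_year"].iloc[0])
    if "age_group" in df.columns:
        return EstimateTable.from_detail(method, target_year, df[["sex", "site", "age_group", "cases"]])
    return EstimateTable(method, target_year, df[["sex", "site", "cases"]])


@dataclass
class BundleMeta:
    """Dataset roles inside a registry bundle."""

    country: str
    regions: list[str]
    neighbours: list[str]
    single_region_proxy: list[str] = field(default_factory=list)  # capital-style region set
    multi_region_proxy: list[str] = field(default_factory=list)  # e.g. north + west
    mi_proxy_regions: list[str] = field(default_factory=list)  # regions pooled for M:I ratios
    target_year: int = 2010

    def to_dict(self) -> dict:
        return {
            "country": self.country,
            "regions": list(self.regions),
            "neighbours": list(self.neighbours),
            "single_region_proxy": list(self.single_region_proxy),
            "multi_region_proxy": list(self.multi_region_proxy),
            "mi_proxy_regions": list(self.mi_proxy_regions),
            "target_year": self.target_year,
        }


@dataclass
class RegistryBundle:
    """Everything one evaluation run needs, plus optional ground truth."""

    incidence: EventTable
    mortality: EventTable | None
    population: PopulationTable
    survival: SurvivalTable | None
    meta: BundleMeta
    truth: pd.DataFrame | None = None  # columns: sex, site, cases (expected national)

    def national_incidence(self) -> EventTable:
        return self.incidence.subset(datasets=self.meta.regions).relabel_dataset(self.meta.country)

    def national_mortality(self) -> EventTable:
        if self.mortality is None:
            raise ValidationError("bundle has no mortality table")
        return self.mortality.subset(datasets=self.meta.regions).relabel_dataset(self.meta.country)

    def national_population(self) -> PopulationTable:
        return self.population.subset(datasets=self.meta.regions).relabel_dataset(self.meta.country)


def write_bundle(bundle: RegistryBundle, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_event_table(bundle.incidence, directory / "incidence.csv")
    if bundle.mortality is not None:
        write_event_table(bundle.mortality, directory / "mortality.csv")
    write_population_table(bundle.population, directory / "population.csv")
    if bundle.survival is not None:
        write_survival_table(bundle.survival, directory / "survival.csv")
    (directory / "bundle.yaml").write_text(yaml.safe_dump(bundle.meta.to_dict(), sort_keys=True))
    if bundle.truth is not None:
        bundle.truth.to_csv(directory / "truth.csv", index=False)


def read_bundle(directory) -> RegistryBundle:
    directory = Path(directory)
    meta_raw = yaml.safe_load((directory / "bundle.yaml").read_text())
    meta = BundleMeta(**meta_raw)
    incidence = read_registry_table(directory / "incidence.csv", "incidence")
    mortality = None
    if (directory / "mortality.csv").exists():
        mortality = read_registry_table(directory / "mortality.csv", "mortality")
    population = read_population_table(directory / "population.csv")
    survival = None
    if (directory / "survival.csv").exists():
        survival = read_survival_table(directory / "survival.csv")
    truth = None
    if (directory / "truth.csv").exists():
        truth = pd.read_csv(directory / "truth.csv", dtype={"site": str})
    return RegistryBundle(incidence, mortality, population, survival, meta, truth)
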