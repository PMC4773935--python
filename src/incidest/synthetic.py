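"""Synthetic multi-region cancer-registry bundles with known ground truth.

The generator emulates the structure of a Nordic-style registry extract:
several regions of one country plus neighbouring countries, annual
incidence and death counts by sex, site and 5-year age group over three
decades, person-years from a national age pyramid with steady growth, and
a 5-year relative survival table. Expected incidence per stratum is

    lambda = baseline(age) * trend(year) * region_multiplier * PY / 1e5

with a log-quadratic baseline in the age-band midpoint and a log-linear
calendar trend (optionally with a changepoint). Expected deaths are tied
to expected incidence through the survival link M = I(1-S), optionally
inflated by a late-mortality factor (deaths beyond 5 years of follow-up)
to emulate good-prognosis sites where 5-year survival overstates cure.
Observed counts are Poisson draws around these expectations, with a
single global seed and deterministic per-table substreams.

The preset scenarios are qualitative testbeds for the documented failure
modes of the estimation methods (screening-driven trend breaks, rare-death
sites, good-prognosis sites, urban/rural contrast); they do not calibrate
magnitudes to any real country's rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import BundleMeta, RegistryBundle
from .sites import AGE_MIDPOINTS, FEMALE, MALE, N_AGE_GROUPS
from .tables import (
    EVENT_COLUMNS,
    PER,
    EventTable,
    PopulationTable,
    SurvivalTable,
    ValidationError,
)


@dataclass(frozen=True)
class RegionSpec:
    """One region of the simulated country."""

    name: str
    share: float  # fraction of the national population
    multiplier: float = 1.0  # regional incidence-rate multiplier


@dataclass(frozen=True)
class SiteSpec:
    """Rate model for one cancer site.

    ``base_log_rate`` are (c0, c1, c2): log rate per 100 000 at age x
    (decades) is c0 + c1*x + c2*x^2, evaluated at band midpoints. ``trend``
    is the annual log-linear slope relative to the reference year 2000;
    with a ``changepoint_year`` the slope switches to ``post_trend`` after
    it. ``survival`` is the 5-year relative survival proportion reported
    in the survival table; ``late_mortality`` >= 1 inflates generated
    deaths beyond the survival link (deaths after 5 years of follow-up).
    """

    name: str
    sexes: tuple[str, ...] = (MALE, FEMALE)
    base_log_rate: tuple[float, float, float] = (0.0, 0.6, 0.0)
    trend: float = 0.0
    changepoint_year: int | None = None
    post_trend: float = 0.0
    survival: float = 0.5
    late_mortality: float = 1.0
    #: Optional (young, old) survival for the generative mortality link:
    #: the young value holds through age band 9 (ages < 50), then declines
    #: linearly to the old value at 85+. The survival table still reports
    #: the scalar ``survival``; use this to emulate sites whose deaths
    #: concentrate at ages carrying little of the incidence.
    survival_by_age: tuple[float, float] | None = None

    def survival_profile(self) -> np.ndarray:
        if self.survival_by_age is None:
            return np.full(N_AGE_GROUPS, self.survival)
        young, old = self.survival_by_age
        profile = np.full(N_AGE_GROUPS, young)
        profile[10:] = np.linspace(young, old, N_AGE_GROUPS - 10 + 1)[1:]
        return profile


@dataclass(frozen=True)
class NeighbourSpec:
    """A neighbouring country: population scale and rate perturbation."""

    name: str
    scale: float = 1.0  # population relative to the simulated country
    rate_factor: float = 1.0  # multiplies every site's rates


@dataclass
class ScenarioConfig:
    """Full description of a simulated registry world."""

    name: str
    regions: list[RegionSpec]
    sites: list[SiteSpec]
    neighbours: list[NeighbourSpec] = field(default_factory=list)
    years: tuple[int, int] = (1983, 2012)
    population_total: float = 5.0e6
    age_pyramid: tuple[float, ...] = ()
    pop_growth: float = 0.005  # annual growth factor - 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.age_pyramid:
            # gently ageing pyramid: linear decline with age band
            w = np.linspace(1.5, 0.4, N_AGE_GROUPS)
            self.age_pyramid = tuple(w / w.sum())
        shares = sum(r.share for r in self.regions)
        if abs(shares - 1.0) > 1e-9:
            raise ValidationError(f"region shares must sum to 1, got {shares}")
        for s in self.sites:
            if not (0.0 <= s.survival < 1.0):
                raise ValidationError(f"survival for {s.name} must be in [0, 1)")
            if (s.late_mortality * (1.0 - s.survival_profile()) > 1.0).any():
                raise ValidationError(f"late mortality for {s.name} implies M > I")


def _site_rate(site: SiteSpec, year: int) -> np.ndarray:
    """Expected incidence rate per 100 000 by age band for one year."""
    x = np.asarray(AGE_MIDPOINTS) / 10.0
    c0, c1, c2 = site.base_log_rate
    base = np.exp(c0 + c1 * x + c2 * x**2)
    if site.changepoint_year is not None and year > site.changepoint_year:
        log_t = site.trend * (site.changepoint_year - 2000) + site.post_trend * (
            year - site.changepoint_year
        )
    else:
        log_t = site.trend * (year - 2000)
    return base * np.exp(log_t)


def _population_frame(config: ScenarioConfig) -> pd.DataFrame:
    lo, hi = config.years
    years = np.arange(lo, hi + 1)
    pyramid = np.asarray(config.age_pyramid)
    growth = (1.0 + config.pop_growth) ** (years - 2000)
    units = [(r.name, r.share) for r in config.regions] + [
        (n.name, n.scale) for n in config.neighbours
    ]
    idx = pd.MultiIndex.from_product(
        [[u[0] for u in units], years, (MALE, FEMALE), range(N_AGE_GROUPS)],
        names=["dataset", "year", "sex", "age_group"],
    )
    scale = np.repeat([u[1] for u in units], len(years) * 2 * N_AGE_GROUPS)
    growth_col = np.tile(np.repeat(growth, 2 * N_AGE_GROUPS), len(units))
    pyramid_col = np.tile(pyramid, len(units) * len(years) * 2)
    py = config.population_total * scale * growth_col * 0.5 * pyramid_col
    return idx.to_frame(index=False).assign(person_years=py)


def _expected_events(config: ScenarioConfig, population: pd.DataFrame) -> pd.DataFrame:
    """Expected incidence and death counts per stratum (before noise)."""
    region_mult = {r.name: r.multiplier for r in config.regions}
    neighbour_fact = {n.name: n.rate_factor for n in config.neighbours}
    lo, hi = config.years
    years = np.arange(lo, hi + 1)
    frames = []
    for site in config.sites:
        rate_by_year = np.vstack([_site_rate(site, y) for y in years])  # (Y, A)
        fatality = (1.0 - site.survival_profile()) * site.late_mortality
        pop = population[population["sex"].isin(site.sexes)].copy()
        mult = pop["dataset"].map(lambda d: region_mult.get(d, 1.0) * neighbour_fact.get(d, 1.0))
        rates = rate_by_year[pop["year"].to_numpy() - lo, pop["age_group"].to_numpy()]
        lam_inc = rates * mult.to_numpy() * pop["person_years"].to_numpy() / PER
        frame = pop[["dataset", "year", "sex", "age_group"]].copy()
        frame["site"] = site.name
        frame["expected_incidence"] = lam_inc
        frame["expected_mortality"] = lam_inc * fatality[pop["age_group"].to_numpy()]
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out[
        ["dataset", "year", "sex", "site", "age_group", "expected_incidence", "expected_mortality"]
    ]


@dataclass
class SyntheticTruth:
    """Noise-free expectations backing a generated bundle."""

    expected: pd.DataFrame  # per-stratum expected incidence and mortality
    national_2010: pd.DataFrame  # columns: sex, site, cases (target-year truth)


def generate(config: ScenarioConfig) -> tuple[RegistryBundle, SyntheticTruth]:
    """Draw one registry bundle and its ground truth.

    Deterministic given ``config.seed``: incidence and mortality use
    separate substreams spawned from the seed in a fixed order, so the
    same seed reproduces the bundle bit for bit.
    """
    population = _population_frame(config)
    expected = _expected_events(config, population)
    ss = np.random.SeedSequence(config.seed)
    inc_rng, mort_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    inc = expected[["dataset", "year", "sex", "site", "age_group"]].copy()
    inc["count"] = inc_rng.poisson(expected["expected_incidence"].to_numpy()).astype(float)
    mort = expected[["dataset", "year", "sex", "site", "age_group"]].copy()
    mort["count"] = mort_rng.poisson(expected["expected_mortality"].to_numpy()).astype(float)

    survival = SurvivalTable(
        pd.DataFrame(
            [
                {"sex": sex, "site": s.name, "survival_5yr": s.survival}
                for s in config.sites
                for sex in s.sexes
            ]
        )
    )

    region_names = [r.name for r in config.regions]
    capital = region_names[0]
    non_capital = [r for r in region_names if r != capital]
    meta = BundleMeta(
        country=config.name,
        regions=region_names,
        neighbours=[n.name for n in config.neighbours],
        # study design: the capital region alone for method 7, the other
        # regions for method 6, and the non-capital pool for M:I ratios
        single_region_proxy=[capital],
        multi_region_proxy=non_capital or region_names,
        mi_proxy_regions=non_capital or region_names,
        target_year=2010,
    )

    nat = expected[expected["dataset"].isin(region_names) & (expected["year"] == meta.target_year)]
    truth_2010 = (
        nat.groupby(["sex", "site"], as_index=False)["expected_incidence"]
        .sum()
        .rename(columns={"expected_incidence": "cases"})
    )

    bundle = RegistryBundle(
        incidence=EventTable("incidence", inc[EVENT_COLUMNS]),
        mortality=EventTable("mortality", mort[EVENT_COLUMNS]),
        population=PopulationTable(population),
        survival=survival,
        meta=meta,
        truth=truth_2010,
    )
    return bundle, SyntheticTruth(expected, truth_2010)


# ---------------------------------------------------------------------------
# preset scenarios

_REGIONS = [
    RegionSpec("capital", 0.50, 1.0),
    RegionSpec("west", 0.25, 1.0),
    RegionSpec("north", 0.15, 1.0),
    RegionSpec("mid", 0.10, 1.0),
]
_NEIGHBOURS = [NeighbourSpec("nb_east", 1.1, 1.0), NeighbourSpec("nb_south", 0.9, 1.0)]

_STABLE_SITES = [
    SiteSpec("Lung", base_log_rate=(-1.5, 1.0, -0.03), survival=0.15),
    SiteSpec("Colon-rectum", base_log_rate=(-1.2, 1.0, -0.03), survival=0.60),
    SiteSpec("Stomach", base_log_rate=(-2.0, 0.9, -0.03), survival=0.25),
    SiteSpec("Breast", sexes=(FEMALE,), base_log_rate=(1.0, 0.8, -0.045), survival=0.85),
    SiteSpec("Prostate", sexes=(MALE,), base_log_rate=(-3.0, 1.6, -0.045), survival=0.85),
]


def preset_scenarios(seed: int = 0, population_total: float = 5.0e6) -> dict[str, ScenarioConfig]:
    """Named scenarios exercising the documented method failure modes.

    - ``stable``: flat trends, homogeneous regions and neighbours - every
      method should land near the truth.
    - ``screening_bump``: a prostate-like site whose rates rose steeply
      then plateaued; long-term projection overshoots, recent-rate
      transport does not.
    - ``rare_death``: a testis-like high-survival site with very few
      deaths; mortality-based methods underestimate.
    - ``good_prognosis``: high survival with late (post-5-year) excess
      mortality; survival inversion overestimates.
    - ``urban_rural``: strong regional rate multipliers; regional-proxy
      methods inherit the proxy's bias.
    """
    base = dict(regions=_REGIONS, neighbours=_NEIGHBOURS, seed=seed,
                population_total=population_total)
    scenarios = {
        "stable": ScenarioConfig(name="stable", sites=list(_STABLE_SITES), **base),
        "screening_bump": ScenarioConfig(
            name="screening_bump",
            sites=[
                replace(
                    _STABLE_SITES[4],
                    trend=0.043,  # steep rise...
                    changepoint_year=2005,
                    post_trend=0.0,  # ...then plateau
                ),
                _STABLE_SITES[0],
            ],
            **base,
        ),
        "rare_death": ScenarioConfig(
            name="rare_death",
            sites=[
                SiteSpec(
                    "Testis",
                    sexes=(MALE,),
                    base_log_rate=(0.0, 2.1, -0.35),  # incidence peaks at ~30
                    survival=0.95,
                    # near-complete cure at the young ages that carry the
                    # incidence; the few deaths occur at old ages
                    survival_by_age=(0.999, 0.75),
                ),
                _STABLE_SITES[0],
            ],
            **base,
        ),
        "good_prognosis": ScenarioConfig(
            name="good_prognosis",
            sites=[
                SiteSpec(
                    "Melanoma of skin",
                    base_log_rate=(0.5, 0.5, -0.02),
                    survival=0.85,
                    late_mortality=1.8,  # deaths beyond 5-year follow-up
                ),
                _STABLE_SITES[0],
            ],
            **base,
        ),
        "urban_rural": ScenarioConfig(
            name="urban_rural",
            sites=list(_STABLE_SITES[:3]),
            **{
                **base,
                "regions": [
                    RegionSpec("capital", 0.50, 1.4),
                    RegionSpec("west", 0.25, 0.7),
                    RegionSpec("north", 0.15, 0.6),
                    RegionSpec("mid", 0.10, 0.8),
                ],
            },
        ),
    }
    return scenarios
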