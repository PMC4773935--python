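import pandas as pd
import pytest

from incidest.sites import FEMALE, MALE, N_AGE_GROUPS
from incidest.tables import EventTable, PopulationTable


def make_events(rows, kind="incidence"):
    return EventTable(
        kind,
        pd.DataFrame(rows, columns=["dataset", "year", "sex", "site", "age_group", "count"]),
    )


def make_population(rows):
    return PopulationTable(
        pd.DataFrame(rows, columns=["dataset", "year", "sex", "age_group", "person_years"])
    )


def uniform_population(datasets, years, person_years=100_000.0):
    rows = [
        (d, y, sex, a, person_years)
        for d in datasets
        for y in years
        for sex in (MALE, FEMALE)
        for a in range(N_AGE_GROUPS)
    ]
    return make_population(rows)


def constant_rate_events(dataset, years, sex, site, rate, person_years=100_000.0, kind="incidence"):
    """Noise-free events with the same rate in every age group and year."""
    rows = [
        (dataset, y, sex, site, a, rate * person_years / 100_000.0)
        for y in years
        for a in range(N_AGE_GROUPS)
    ]
    return make_events(rows, kind)


@pytest.fixture(scope="session")
def stable_bundle():
    """One modest stable-scenario bundle shared by read-only tests."""
    from incidest.synthetic import generate, preset_scenarios

    config = preset_scenarios(seed=11)["stable"]
    bundle, truth = generate(config)
    return bundle, truth


@pytest.fixture(scope="session")
def stable_evaluation(stable_bundle):
    import warnings

    from incidest.pipeline import run_evaluation

    bundle, truth = stable_bundle
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_evaluation(bundle), truth
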