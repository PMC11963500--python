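import pytest

from mmrproj.core_data import CauseProfile, CountryRecord, MMRSeries, default_intervention_registry
from mmrproj.synthetic_panel import GeneratorConfig, generate_panel


@pytest.fixture(scope="session")
def registry():
    return default_intervention_registry()


@pytest.fixture(scope="session")
def intervention_ids(registry):
    return tuple(iv.id for iv in registry)


@pytest.fixture(scope="session")
def small_panel(intervention_ids):
    """A 12-country panel spanning several regions and income groups."""
    records, truths = generate_panel(GeneratorConfig(seed=3, n_countries=12), intervention_ids)
    return records, truths


def make_country(
    iso3="TST",
    mmr_2020=200.0,
    apc=-3.0,
    live_births=100_000,
    coverage=0.4,
    intervention_ids=(),
    region="AFR",
    income_group="lower_middle",
):
    """A deterministic, exactly log-linear country for worked examples."""
    years = tuple(range(2000, 2021))
    ratio = 1.0 + apc / 100.0
    mmr = tuple(mmr_2020 * ratio ** (y - 2020) for y in years)
    se = 0.08 * mmr_2020
    shares = {
        "antepartum_hemorrhage": 0.048,
        "intrapartum_hemorrhage": 0.006,
        "postpartum_hemorrhage": 0.146,
        "hypertensive_disorders": 0.20,
        "sepsis": 0.10,
        "abortion": 0.10,
        "other_direct": 0.15,
        "indirect": 0.25,
    }
    return CountryRecord(
        iso3=iso3,
        region=region,
        income_group=income_group,
        live_births=live_births,
        series=MMRSeries(iso3=iso3, years=years, mmr=mmr,
                         se=tuple(se if y == 2020 else None for y in years)),
        causes=CauseProfile(shares),
        coverage={iid: coverage for iid in intervention_ids},
        mmr_ui_2020=(mmr_2020 - 1.2815515655446004 * se, mmr_2020 + 1.2815515655446004 * se),
    )
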