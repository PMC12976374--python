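import pytest

from pahburden.synthetic_tds import (
    SynthConfig,
    generate_catalog,
    generate_concentrations,
    generate_survey,
)


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A reduced-size synthetic TDS for fast end-to-end tests."""
    return SynthConfig(
        n_categories=6, n_foods=36, samples_per_food=2, n_respondents=150,
        foods_per_day_mean=5.0, seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    catalog = generate_catalog(small_cfg)
    records = generate_concentrations(catalog, small_cfg)
    survey = generate_survey(catalog, small_cfg)
    return catalog, records, survey


@pytest.fixture(scope="session")
def default_cfg() -> SynthConfig:
    """The full study-condition configuration (264 foods, 2,000 respondents)."""
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def default_dataset(default_cfg):
    catalog = generate_catalog(default_cfg)
    records = generate_concentrations(catalog, default_cfg)
    survey = generate_survey(catalog, default_cfg)
    return catalog, records, survey
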