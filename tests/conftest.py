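import pytest

from cropclim.corpus import SimulationRecord
from cropclim.synthetic import GeneratorConfig, generate_corpus


def make_record(**overrides) -> SimulationRecord:
    """A valid site-scale maize record; override any field for a scenario."""
    base = dict(
        study_id="S001",
        ref_label="ref_001",
        pub_year=2015,
        crop="maize",
        country="USA",
        site_label="siteA",
        region_group="North America",
        lat=40.25,
        lon=-90.25,
        scale="site",
        climate_family="CMIP5",
        scenario="RCP8.5",
        esm="ESM1",
        future_start=2046,
        future_end=2055,
        base_start=1991,
        base_end=2000,
        Yb=5.0,
        Yf=4.5,
        YI_raw=-10.0,
        dTl=2.0,
        dTg_2005=1.8,
        dTg_pi=2.6,
        dPr=-30.0,
        Tave=12.5,
        Tave_w=12.8,
        Pr_base=800.0,
        co2_included=True,
        co2_ppm=541.0,
        adaptation=False,
    )
    base.update(overrides)
    return SimulationRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def three_records():
    return [
        make_record(),
        make_record(site_label="siteB", crop="wheat", lat=-10.75, Yf=5.5, YI_raw=10.0),
        make_record(
            site_label="siteC",
            adaptation=True,
            adaptation_options={"irrigation", "cultivar"},
            Yf=5.2,
            YI_raw=4.0,
        ),
    ]


@pytest.fixture(scope="session")
def synthetic_2000():
    """Mid-size corpus shared by recovery-style tests."""
    return generate_corpus(GeneratorConfig(n_records=2000, seed=11))


@pytest.fixture(scope="session")
def synthetic_5000():
    """The n=5000 corpus used by the imputation/pairing acceptance criteria."""
    return generate_corpus(GeneratorConfig(n_records=5000, seed=42))
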