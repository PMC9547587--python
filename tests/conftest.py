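import pytest
from hypothesis import HealthCheck, settings

from mirdmap.mapping import AssociationMap, build_db, merge_on_key
from mirdmap.synth import FixtureSpec, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def tiny_db():
    """Hand-checkable database: 5 miRNAs × 4 diseases."""
    forward = AssociationMap(
        {
            "hsa-miR-1-3p": {"Colorectal Neoplasms", "Stomach Neoplasms"},
            "hsa-miR-2-5p": {"Colorectal Neoplasms"},
            "hsa-miR-3-3p": {"Asthma", "Colorectal Neoplasms"},
            "hsa-miR-4-5p": {"Asthma"},
            "hsa-miR-5-3p": {"Myocardial Infarction"},
        }
    )
    return build_db(forward)


@pytest.fixture(scope="session")
def synthetic_db():
    """Merged database from the default synthetic two-layer fixture."""
    mg, gd, _ = generate(FixtureSpec(seed=1234))
    merged, _ = merge_on_key(mg, gd)
    return build_db(merged)
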