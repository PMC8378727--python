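import pytest

from rothc_grass import generate_fixture, pedotransfer_water


@pytest.fixture(scope="session")
def wet_grazed():
    """Seeded wet grazed site: weather, RothC_3 config, synthetic observations."""
    return generate_fixture(1, "wet_grazed")


@pytest.fixture(scope="session")
def wet_cut():
    return generate_fixture(1, "wet_cut")


@pytest.fixture(scope="session")
def dry_grazed():
    return generate_fixture(1, "dry_grazed")


@pytest.fixture(scope="session")
def loam_bounds():
    """Water bounds for a typical loam over 20 cm."""
    return pedotransfer_water(clay=25.0, sand=40.0, silt=35.0, depth_cm=20.0)
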