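import pytest

from vdgrs.cohort_io import default_manifest
from vdgrs.simulate import GeneratorConfig, checkerboard_fixture, generate


@pytest.fixture(scope="session")
def manifest():
    return default_manifest()


@pytest.fixture(scope="session")
def specs_by_rsid(manifest):
    return {spec.rsid: spec for spec in manifest}


@pytest.fixture()
def checkerboard():
    return checkerboard_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A 183-pair synthetic cohort under the default configuration."""
    return generate(GeneratorConfig(seed=11))
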