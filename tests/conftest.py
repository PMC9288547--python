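import pytest

from taxsig import (
    FixtureConfig,
    generate_fixture_alignment,
    generate_templates,
    reference_panel,
)


@pytest.fixture(scope="session")
def default_cfg():
    return FixtureConfig()


@pytest.fixture(scope="session")
def fixture_data(default_cfg):
    """(alignment, partition, reference id) for the default seeded fixture."""
    return generate_fixture_alignment(default_cfg)


@pytest.fixture(scope="session")
def ref_panel():
    return reference_panel()


@pytest.fixture(scope="session")
def target_templates(default_cfg):
    from taxsig import SampleClass

    return generate_templates(default_cfg, [SampleClass("target_sample", ("target",))])


@pytest.fixture(scope="session")
def background_templates(default_cfg):
    from taxsig import SampleClass

    return generate_templates(default_cfg, [SampleClass("background_sample", ("background",))])
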