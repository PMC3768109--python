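import pathlib

import pytest

from amlpanel import (
    CallerConfig,
    build_default_spec,
    generate_pileups,
    read_pileup_evidence,
    read_targets,
)


@pytest.fixture(scope="session")
def default_spec():
    return build_default_spec()


@pytest.fixture(scope="session")
def fixture_dir(default_spec, tmp_path_factory) -> pathlib.Path:
    """Deterministic pileup fixture set, generated once per session."""
    d = tmp_path_factory.mktemp("fixtures")
    generate_pileups(default_spec, d, mode="deterministic", seed=1)
    return d


@pytest.fixture(scope="session")
def caller_config():
    return CallerConfig()


@pytest.fixture(scope="session")
def panel_targets(fixture_dir):
    return read_targets(fixture_dir / "panel.bed")


@pytest.fixture(scope="session")
def control_evidence(fixture_dir, caller_config):
    """Shared control parsed once: every tumour is compared against it."""
    return read_pileup_evidence(
        fixture_dir / "CTRL.pileup",
        caller_config.min_base_quality,
        caller_config.min_mapping_quality,
    )
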