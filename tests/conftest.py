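"""Shared fixtures: small synthetic proteomes generated at test time."""

import pytest

from polyx_ppi.synthetic import FixtureConfig, generate


@pytest.fixture(scope="session")
def small_fixture():
    """A 300-protein polyQ fixture with strong planted signal and paralogs."""
    config = FixtureConfig(
        seed=11,
        n_proteins=300,
        positive_fraction=0.15,
        p_signal=0.9,
        paralog_fraction=0.1,
    )
    return generate(config)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """The same fixture written to disk for file-based tests."""
    out = tmp_path_factory.mktemp("fixture")
    config = FixtureConfig(
        seed=11,
        n_proteins=300,
        positive_fraction=0.15,
        p_signal=0.9,
        paralog_fraction=0.1,
    )
    generate(config, out)
    return out
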