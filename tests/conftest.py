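import pytest

from neorank import fixtures


@pytest.fixture(scope="session")
def toy_spec() -> fixtures.ToyCohortSpec:
    return fixtures.ToyCohortSpec(seed=7)


@pytest.fixture(scope="session")
def toy_cohort(toy_spec) -> fixtures.ToyCohort:
    return fixtures.build_toy_cohort(toy_spec)


@pytest.fixture(scope="session")
def toy_dir(toy_cohort, tmp_path_factory):
    """The toy cohort serialized to disk; returns the directory holding manifest.yaml."""
    out = tmp_path_factory.mktemp("toy_cohort")
    fixtures.write_cohort(toy_cohort, out)
    return out
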