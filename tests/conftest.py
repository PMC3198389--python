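import pytest

from satmut.design import DesignConfig
from satmut.fixtures import FixtureSpec, generate_fixture, reference_fixture


@pytest.fixture(scope="session")
def ref():
    """The synthetic plasmid embedding the published five-site local contexts."""
    return reference_fixture(seed=0)


@pytest.fixture(scope="session")
def ref_plans(ref):
    return ref.default_plan(DesignConfig())


@pytest.fixture(scope="session")
def small_fixture_factory():
    """Factory for small random designable plasmids (~1.5 kb, 5 sites)."""

    def make(seed: int, aa_indices=(10, 60, 120, 200, 300), plasmid_length=1500):
        spec = FixtureSpec(
            plasmid_length=plasmid_length,
            orf_start=400,
            orf_codons=320,
            aa_indices=aa_indices,
        )
        return generate_fixture(spec, seed=seed)

    return make
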