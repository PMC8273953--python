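import pytest

from phescore import builtin_cameroon_norms, gen_volunteers


@pytest.fixture(scope="session")
def cameroon():
    return builtin_cameroon_norms()


@pytest.fixture(scope="session")
def volunteer_sample(cameroon):
    """A seeded mid-size normative sample used across modules."""
    return gen_volunteers(500, cameroon, seed=20210)
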