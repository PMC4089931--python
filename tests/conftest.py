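import pytest

from anatomerge.fixtures import FixtureSpec, build_worked_examples, generate_fixture


@pytest.fixture(scope="session")
def worked():
    return build_worked_examples()


@pytest.fixture()
def small_fixture():
    """A 60-class source with 25 mapped classes, seeded."""
    return generate_fixture(FixtureSpec(60, 25, seed=11))


def make_fixture(n, m, **kw):
    kw.setdefault("seed", 0)
    return generate_fixture(FixtureSpec(n, m, **kw))
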