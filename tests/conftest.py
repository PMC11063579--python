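import datetime as dt

import pytest

from pseudoreg import Registry, SubjectIdentity, default_config


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture()
def registry(cfg):
    return Registry(cfg)


@pytest.fixture()
def identity():
    return SubjectIdentity(
        values={
            "first_name": "Maria",
            "last_name": "Rossi",
            "date_of_birth": "1980-03-04",
            "sex": "F",
        }
    )


@pytest.fixture()
def registered(registry, identity):
    """A registry with one subject already enrolled."""
    proof = registry.search_subjects(identity, mode="fuzzy")
    record = registry.register_subject(identity, proof, actor="nurse")
    return registry, record


@pytest.fixture(scope="session")
def today():
    return dt.date(2026, 9, 25)
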