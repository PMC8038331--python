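import pytest

from galfrag import (
    packaged_registry,
    packaged_rules,
    assemble,
    make_score_table,
    study_score_spec,
)


@pytest.fixture(scope="session")
def registry():
    return packaged_registry()


@pytest.fixture(scope="session")
def rules():
    return packaged_rules()


@pytest.fixture(scope="session")
def lead_candidate(registry):
    """The assembled lead: galantamine core + amide linker L10 + biphenyl Ar1a."""
    return assemble(registry.core, registry.get("L10"), registry.get("Ar1a"))


@pytest.fixture(scope="session")
def study_score_table():
    """Synthetic score table with the study's triage statistics."""
    return make_score_table(study_score_spec(seed=20260928))
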