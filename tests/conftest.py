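import warnings

import pytest

import phycofa.io as pio


@pytest.fixture(scope="session")
def reference_means():
    """Packaged species x FA mean matrix (%), canonical labels."""
    return pio.load_reference_means()


@pytest.fixture(scope="session")
def reference_profiles():
    """One single-replicate profile per reference species."""
    return pio.reference_profiles()


@pytest.fixture(scope="session")
def profiles_by_species(reference_profiles):
    return {p.species_id: p for p in reference_profiles}


@pytest.fixture
def no_warnings():
    """Silence expected diagnostics (undefined indices on degenerate input)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
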