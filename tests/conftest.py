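
import pytest

from circrep import load_human_mtdna


@pytest.fixture(scope="session")
def human_mtdna():
    """The bundled human mitochondrial genome (NC_001807.4, 16,571 bp)."""
    return load_human_mtdna()


@pytest.fixture(scope="session")
def human_repeats(human_mtdna):
    """Full four-class repeat call on the human genome (shared: ~20 s)."""
    from circrep import call_repeats

    return call_repeats(human_mtdna)
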