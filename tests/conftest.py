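import pytest

from mitochar import load_reference_annotation, load_named_orders
from mitochar.codon_usage import load_reference_codon_usage
from mitochar.synthetic import GenomeSpec, generate_genome


@pytest.fixture(scope="session")
def reference_annotation():
    """Bundled E. ensirostris organization table (no sequence)."""
    return load_reference_annotation()


@pytest.fixture(scope="session")
def named_orders():
    return load_named_orders()


@pytest.fixture(scope="session")
def reference_codon_table():
    return load_reference_codon_usage()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One deterministic ancestral-order synthetic mitogenome with sequence."""
    return generate_genome(GenomeSpec(seed=11, genome_length=16350))
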