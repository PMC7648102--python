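import pytest

from mitochar import datasets
from mitochar.codons import GeneticCode
from mitochar.simulate import default_config, simulate_mitogenome


@pytest.fixture(scope="session")
def lg():
    """Annotation of the 18,192 bp Lottia goshimai mitogenome."""
    return datasets.lottia_goshimai()


@pytest.fixture(scope="session")
def nf():
    """Annotation of the 18,720 bp Nipponacmea fuscoviridis mitogenome."""
    return datasets.nipponacmea_fuscoviridis()


@pytest.fixture(scope="session")
def code5():
    return GeneticCode(5)


@pytest.fixture(scope="session")
def sim():
    """One limpet-patterned synthetic mitogenome with its ground truth."""
    return simulate_mitogenome(default_config(seed=11))
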