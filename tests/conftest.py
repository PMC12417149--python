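import numpy as np
import pytest

from kirallo.core_types import (
    A_HAPLOTYPE_GENES,
    KIR_LOCI,
    HLATyping,
    KIRGenotype,
    LigandProfile,
)
from kirallo.ligand_assignment import load_default_table
from kirallo.allele_expression import load_default_allotypes


@pytest.fixture(scope="session")
def ligand_table():
    return load_default_table()


@pytest.fixture(scope="session")
def allotype_table():
    return load_default_allotypes()


@pytest.fixture
def a_haplotype_genotype():
    """Homozygous A-haplotype donor: the seven A genes + both pseudogenes."""
    return KIRGenotype.from_present(
        A_HAPLOTYPE_GENES + ("KIR2DP1", "KIR3DP1")
    )


@pytest.fixture
def all_genes_genotype():
    return KIRGenotype.from_present(KIR_LOCI)


def make_profile(C1=False, C2=False, I80=False, T80=False, Bw6=True, A3A11=False):
    return LigandProfile(
        has_C1=C1, has_C2=C2, has_Bw4_80I=I80, has_Bw4_80T=T80,
        has_Bw6=Bw6, has_A3A11=A3A11,
    )


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def typing_factory():
    def _make(*names):
        return HLATyping.from_strings(list(names))
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
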