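import numpy as np
import pytest

from pkdpanel import generate_locus, design_amplicons
from pkdpanel.experiments import masked_reference_of, study_locus


@pytest.fixture(scope="session")
def locus():
    """A mid-size duplicated locus shared by read-level tests."""
    return generate_locus(11, n_paralogs=6, identity=0.98, length=4000,
                          n_exons=3, exon_length=300)


@pytest.fixture(scope="session")
def amplicons(locus):
    return design_amplicons(locus, amplicon_length=900, min_overlap=250)


@pytest.fixture(scope="session")
def masked_ref(locus):
    return masked_reference_of(locus)


@pytest.fixture(scope="session")
def small_study():
    """The compact locus + amplicon pair used by the validation studies."""
    return study_locus(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
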