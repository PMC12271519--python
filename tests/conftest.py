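import pytest

from haplogeo.seqdata import collapse_haplotypes
from haplogeo.synthetic_data import make_study_fixture


@pytest.fixture(scope="session")
def fixture():
    """Reconstructed 102-sample, 801-base study alignment bundle."""
    return make_study_fixture(seed=11)


@pytest.fixture(scope="session")
def study_table(fixture):
    """Haplotype table with published labels (gaps as a fifth state)."""
    return collapse_haplotypes(fixture.alignment, label_map=fixture.label_map)
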