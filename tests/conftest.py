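import pytest

from cysmsa.cys_anchor import ScoringScheme
from cysmsa.fixtures import FixtureSpec, ToyComplexSpec, gen_cysrich_family


@pytest.fixture(scope="session")
def identity_scoring() -> ScoringScheme:
    """Simple scheme (match +1 / mismatch -1, open 2, extend 1) so oracle
    enumeration stays cheap and scores are exact integers."""
    return ScoringScheme(matrix="IDENTITY", gap_open=2.0, gap_extend=1.0)


@pytest.fixture(scope="session")
def blosum_scoring() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture
def small_family():
    spec = FixtureSpec(seed=7, n_sequences=5, n_cys=4, seg_min=1, seg_max=6,
                       sub_rate=0.15, indel_rate=0.2)
    return gen_cysrich_family(spec)


@pytest.fixture
def toy_complex_spec() -> ToyComplexSpec:
    return ToyComplexSpec(seed=0, len_a=12, len_b=10, n_interface=4,
                          ss_pairs=((1, 8), (2, 5), (3, 6), (4, 7)),
                          plddt_a=90.0, plddt_b=80.0, interface_pae=10.0)
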