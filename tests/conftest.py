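import pytest

from openlbd.lexicon import default_interaction_lexicon
from openlbd.synthetic_corpus import CorpusSpec, generate_corpus, generate_semantic_types

SAMPLE_FLAT = """\
PMID- 101
DP  - 1984 Jun
TI  - Raynaud syndrome and blood viscosity.
AB  - Blood viscosity may increase in raynaud syndrome. Further work is
      needed.
MH  - *Raynaud Syndrome/therapy
MH  - Blood Viscosity

PMID- 102
DP  - 1985
TI  - Platelet aggregation in peripheral disease.
AB  - Platelet aggregation (PA) was measured. Elevated PA was noted in
      patients.
MH  - Platelet Aggregation
MH  - Raynaud Syndrome
"""


@pytest.fixture
def sample_flat_text():
    return SAMPLE_FLAT


@pytest.fixture
def lexicon():
    return default_interaction_lexicon()


@pytest.fixture
def small_spec():
    return CorpusSpec(
        seed=7,
        n_records=40,
        decoy_b=tuple(f"linkdecoy{i}" for i in range(6)),
        abbrev_rate=0.3,
    )


@pytest.fixture
def small_corpus(small_spec):
    return generate_corpus(small_spec)


@pytest.fixture
def small_type_map(small_spec):
    return generate_semantic_types(small_spec)
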