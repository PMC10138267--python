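import pytest

from allodis.ontology import parse_obo
from allodis.simulate import SimConfig, write_all

CHAIN_OBO = """format-version: 1.2
ontology: test

[Term]
id: A
name: disease

[Term]
id: B
name: leukemia
is_a: A ! disease

[Term]
id: C
name: myeloid leukemia
is_a: B ! leukemia
"""

DIAMOND_OBO = """format-version: 1.2
ontology: test

[Term]
id: A
name: root

[Term]
id: B
name: left
is_a: A

[Term]
id: C
name: right
is_a: A

[Term]
id: D
name: bottom
is_a: B
is_a: C
"""


@pytest.fixture
def chain_ontology():
    return parse_obo(CHAIN_OBO)


@pytest.fixture
def diamond_ontology():
    return parse_obo(DIAMOND_OBO)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Full synthetic fixture set generated once per session."""
    d = tmp_path_factory.mktemp("fixtures")
    write_all(SimConfig(seed=11), d)
    return d
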