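import pytest

from helpers import make_toy_tree
from taxvote.taxonomy import TaxonomyTree


@pytest.fixture
def toy_tree() -> TaxonomyTree:
    return make_toy_tree()
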