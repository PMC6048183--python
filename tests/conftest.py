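import warnings

import pytest
from hypothesis import HealthCheck, settings

from stagematch.core import read_gene_tree
from stagematch.gmyc import GmycWarning

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_haplotype_warning():
    # most tests feed per-specimen (uncollapsed) trees to GMYC on purpose
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GmycWarning)
        yield


@pytest.fixture
def balanced4():
    return read_gene_tree("((A:1,B:1)0.99:1,(C:1,D:1)0.8:1);", "g")


@pytest.fixture
def caterpillar4():
    return read_gene_tree("(((A:1,B:1):1,C:2):1,D:3);", "g")


def make_tree(newick: str, gene: str = "g", **kw):
    return read_gene_tree(newick, gene, **kw)
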