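"""Shared fixtures: tiny hand-built graphs and a generated bundle."""

import pytest

from kgtool import FixtureConfig, load_triples, rice_worked_example
from kgtool.synth import generate

TOY_TRIPLES = """\
# toy graph from the loader contract
g1\tgene\tcorresponding_to\tp1\tprotein\tsrc
p1\tprotein\tinvolves_in_signal_pathway\ts1\tsignal_pathway\tsrc
g1\tgene\tperforms\tm1\tmolecular_function\tsrc
"""


@pytest.fixture
def toy_graph(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(TOY_TRIPLES)
    kg, report = load_triples(path, strict=True)
    return kg


@pytest.fixture
def toy_triples_path(tmp_path):
    path = tmp_path / "toy.tsv"
    path.write_text(TOY_TRIPLES)
    return path


@pytest.fixture(scope="session")
def worked_example():
    return rice_worked_example()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A written-out synthetic study with planted gene–trait links (seed 7)."""
    out = tmp_path_factory.mktemp("bundle")
    return generate(FixtureConfig(seed=7), out)
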