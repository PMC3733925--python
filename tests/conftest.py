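import pytest

from gochem.biochebi import build_biochebi
from gochem.defgen import bridge_ontologies, default_rules
from gochem.fixtures import worked_example


@pytest.fixture
def bundle():
    return worked_example()


@pytest.fixture
def rules():
    return default_rules()


@pytest.fixture
def bridge(bundle):
    """Bridging result (no minting) over the worked-example pair."""
    return bridge_ontologies(bundle.mini_go, bundle.mini_chebi)


@pytest.fixture
def gcis(bundle):
    overlay = build_biochebi(bundle.mini_chebi)
    return [ax for ax in overlay.axioms if ax.provenance == "gci"]
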