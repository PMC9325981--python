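import numpy as np
import pytest

from leachdom.chem import MolecularFormula
from leachdom.dom_metrics import SampleFormulaTable, load_additive_reference
from leachdom.synthetic import StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def additives():
    return load_additive_reference()


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


def make_table(sample_id, spec):
    """Build a SampleFormulaTable from {'C8H6O4': intensity, ...}."""
    pairs = [(MolecularFormula.parse(f), w) for f, w in spec.items()]
    return SampleFormulaTable.from_pairs(sample_id, pairs)
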