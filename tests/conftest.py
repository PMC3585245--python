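import numpy as np
import pytest

from heptatm.fixtures import BundleSpec, make_bundle
from heptatm.io_formats import SequenceRecord, TemplateRecord, ResidueEntry
from heptatm.scoring import AMINO_ACIDS, blosum62


@pytest.fixture(scope="session")
def scheme():
    return blosum62()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def bundle():
    return make_bundle(BundleSpec(seed=7, with_ligand=True))


def random_sequence(rng, n, alphabet=AMINO_ACIDS):
    return "".join(alphabet[k] for k in rng.integers(0, len(alphabet), size=n))


def random_chain_template(rng, n, tpl_id="chain", scale=20.0):
    """A template whose residues are random points, all inside one TM
    segment — the minimal structure the averaging machinery accepts."""
    seq = random_sequence(rng, n)
    coords = rng.uniform(-scale, scale, size=(n, 3))
    residues = [ResidueEntry(i + 1, seq[i], {"CA": coords[i]}) for i in range(n)]
    return TemplateRecord(
        id=tpl_id, sequence=SequenceRecord(tpl_id, seq), residues=residues,
        tm_segments=[(0, n)])
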