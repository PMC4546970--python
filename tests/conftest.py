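import numpy as np
import pytest

from fusionkit.io_formats import NUCLEOTIDE, PROTEIN, SequenceRecord
from fusionkit.synthetic_data import SyntheticConfig, gen_fusion_proteins


@pytest.fixture
def rng():
    return np.random.default_rng(20150810)


@pytest.fixture
def random_nt_record(rng):
    def make(seq_id="seq", length=50):
        residues = "".join(rng.choice(list("ACGT"), size=length))
        return SequenceRecord(id=seq_id, alphabet=NUCLEOTIDE, residues=residues)

    return make


@pytest.fixture(scope="session")
def small_fusion_corpus():
    """50 sandwich proteins with truth regions, shared across tests."""
    cfg = SyntheticConfig(seed=42, n_fusions=50)
    proteins, breakpoints, truth = gen_fusion_proteins(cfg)
    return cfg, proteins, breakpoints, truth
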