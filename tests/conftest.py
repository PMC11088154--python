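import pytest

import smmipkit as sk


@pytest.fixture(scope="session")
def small_cfg():
    return sk.SimConfig(seed=7, n_genes=2, exons_per_gene=3, exon_len=150,
                        n_samples=1, depth=50)


@pytest.fixture(scope="session")
def small_reference(small_cfg):
    return sk.make_reference(small_cfg)


@pytest.fixture(scope="session")
def small_panel(small_reference):
    return sk.design_panel(small_reference)


def make_assignment(probe_id, umb, read_id="r", insert="ACGT"):
    return sk.MoleculeAssignment(read_id=read_id, probe_id=probe_id, umb=umb,
                                 insert_seq=insert, insert_qual="I" * len(insert),
                                 arm_mismatches=0)
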