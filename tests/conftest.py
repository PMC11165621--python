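import numpy as np
import pytest

from phagetax.records import GenomeRecord, ProteinRecord
from phagetax.simulate import CladeSpec, TaxonNode, simulate_clade


@pytest.fixture
def tiny_fasta(tmp_path):
    p = tmp_path / "genomes.fna"
    p.write_text(">a desc one\nACGTACGT\nAACC\n>b\nTTTTGGGG\n")
    return p


@pytest.fixture(scope="session")
def small_clade():
    """A cheap 4-genome clade (two pairs) with related gene families."""
    tree = TaxonNode("root", children=[
        TaxonNode("cladeA", branch=0.08, children=[
            TaxonNode("a1", branch=0.01), TaxonNode("a2", branch=0.01)]),
        TaxonNode("cladeB", branch=0.08, children=[
            TaxonNode("b1", branch=0.01), TaxonNode("b2", branch=0.01)]),
    ])
    return simulate_clade(CladeSpec(tree=tree, n_core_families=20, seed=7))


@pytest.fixture(scope="session")
def small_proteins(small_clade):
    """Planted proteins of the small clade as ProteinRecords (<=80)."""
    out = []
    for (gid, fam), seq in small_clade.truth.proteins.items():
        out.append(ProteinRecord(id=f"{gid}|{fam}", seq=seq, source_genome=gid))
    return out


def random_genome(rng: np.random.Generator, n: int, gid: str = "r") -> GenomeRecord:
    return GenomeRecord(id=gid, seq="".join(rng.choice(list("ACGT"), size=n)))
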