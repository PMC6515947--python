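import pytest

from pepzone import seqcore


@pytest.fixture(scope="session")
def table1():
    """The packaged 79-peptide array table."""
    return seqcore.load_peptide_table()


@pytest.fixture(scope="session")
def antigen(table1):
    """The 326-residue antigen stitched from the array table."""
    return seqcore.stitch_peptides(table1, seq_id="b2gp1")


@pytest.fixture(scope="session")
def tiling(antigen):
    """Default re-tiling of the antigen, domain-annotated."""
    return seqcore.annotate_domains(seqcore.tile_protein(antigen))
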