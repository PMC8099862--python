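import pytest

from phosphodia import DilutionDesign
from phosphodia import io as pio
from phosphodia import simulate as sim

# EGFR 1161-1179 tryptic peptide; S/T/Y candidates at peptide positions 2, 6, 12
EGFR_PEPTIDE = "GSHQISLDNPDYQQDFFPK"


@pytest.fixture(scope="session")
def egfr_peptide():
    return EGFR_PEPTIDE


@pytest.fixture(scope="session")
def small_fasta():
    return sim.make_fasta(12, length_range=(150, 300), seed=11)


@pytest.fixture(scope="session")
def small_proteins(small_fasta):
    return pio.read_fasta_text(small_fasta)


@pytest.fixture(scope="session")
def small_panel(small_fasta):
    return sim.make_panel(small_fasta, counts=(20, 4, 1), seed=11)


@pytest.fixture(scope="session")
def design():
    return DilutionDesign()
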