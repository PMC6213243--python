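import pytest

from cubkit import STANDARD_CODE, CodonCountTable, CdsRecord


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture
def mini_counts():
    """The five-codon toy gene AUG GAU GAC UGG UAA."""
    return CodonCountTable({"AUG": 1, "GAU": 1, "GAC": 1, "UGG": 1, "UAA": 1})


@pytest.fixture
def even_counts(code):
    """Exactly even within-family usage, 600 codons per family (stops too)."""
    counts = {}
    for fam in code.families.values():
        for c in fam:
            counts[c] = 600 // len(fam)
    return CodonCountTable(counts)


@pytest.fixture
def one_codon_per_aa_counts(code):
    """Extreme bias: a single codon per amino acid, 100 copies each."""
    return CodonCountTable({code.families[aa][0]: 100 for aa in code.amino_acids})


GENBANK_FIXTURE = """\
LOCUS       SYNTEST              60 bp    DNA     circular PLN 01-JAN-2020
DEFINITION  Synthetic test plastid fragment.
ACCESSION   SYNTEST1
VERSION     SYNTEST1.1
SOURCE      synthetic construct
  ORGANISM  synthetic construct
FEATURES             Location/Qualifiers
     source          1..60
     CDS             5..10
                     /gene="fwd1"
                     /product="photosystem II protein D1"
     CDS             complement(5..10)
                     /gene="rev1"
                     /product="ribosomal protein S4"
     CDS             join(1..6,10..15)
                     /gene="spl1"
                     /product="maturase K"
     CDS             20..26
                     /gene="bad1"
                     /product="broken frame"
     CDS             <28..33
                     /gene="part1"
                     /product="partial thing"
ORIGIN
        1 atggatgact ggtaaatgga tgactggtaa atggatgact ggtaaatgga tgactggtaa
//
"""


@pytest.fixture
def genbank_file(tmp_path):
    path = tmp_path / "syntest.gb"
    path.write_text(GENBANK_FIXTURE)
    return path
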