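"""Genetic-code helpers and the package's E. coli codon-preference table.

The saturation library substitutes each targeted residue with every amino
acid using a single "preferred" codon per amino acid, following common
E. coli K-12 usage.  A ranked list per amino acid is shipped so that the
synonymous (wild-type amino acid) design can fall back to the next-ranked
codon when the preferred codon equals the native one — otherwise the
synonymous barcode would be indistinguishable from wild type.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

#: codon -> amino acid (one-letter), stop codons excluded
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: amino acid -> all codons encoding it, in no particular order
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))

# Ranked codons per amino acid, most preferred first, loosely following
# E. coli K-12 usage in highly expressed genes.  The first entry is the
# codon used for missense designs; the first entry differing from the
# native codon is used for the synonymous design.
PREFERRED_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCG", "GCC", "GCA", "GCT"),
    "R": ("CGT", "CGC", "CGG", "CGA", "AGA", "AGG"),
    "N": ("AAC", "AAT"),
    "D": ("GAT", "GAC"),
    "C": ("TGC", "TGT"),
    "Q": ("CAG", "CAA"),
    "E": ("GAA", "GAG"),
    "G": ("GGC", "GGT", "GGG", "GGA"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "L": ("CTG", "CTT", "CTC", "TTA", "TTG", "CTA"),
    "K": ("AAA", "AAG"),
    "M": ("ATG",),
    "F": ("TTT", "TTC"),
    "P": ("CCG", "CCA", "CCT", "CCC"),
    "S": ("AGC", "TCT", "TCC", "AGT", "TCG", "TCA"),
    "T": ("ACC", "ACG", "ACT", "ACA"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
    "V": ("GTG", "GTT", "GTC", "GTA"),
}

#: amino acid -> single most frequent codon (the default design table)
DEFAULT_CODON_TABLE: dict[str, str] = {aa: codons[0] for aa, codons in PREFERRED_CODONS.items()}

# 3-letter residue names (PDB) -> one-letter codes
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def translate_codon(codon: str) -> str:
    """Translate one codon to its one-letter amino acid ('*' for stop)."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def translate(cds: str) -> str:
    """Translate a coding sequence (length must be a multiple of 3)."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    return str(Seq(cds).translate())


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def synonymous_alternatives(codon: str) -> tuple[str, ...]:
    """Ranked synonymous codons for ``codon``, excluding ``codon`` itself."""
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError("stop codons have no design alternatives")
    return tuple(c for c in PREFERRED_CODONS[aa] if c != codon.upper())
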