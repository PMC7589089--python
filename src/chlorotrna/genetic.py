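"""Genetic-code helpers shared across the package.

Internal alphabet is DNA; codons and anticodons are rendered as RNA (U) at
reporting boundaries to match the conventions of tRNA tables.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

_STANDARD = unambiguous_dna_by_id[1]

#: 61 sense codons (DNA alphabet), standard genetic code.
SENSE_CODONS_DNA: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))
STOP_CODONS_DNA: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: codon (DNA) -> one-letter amino acid
CODON_TO_AA1: dict[str, str] = dict(_STANDARD.forward_table)

AA1_TO_AA3: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
AA3_TO_AA1: dict[str, str] = {v: k for k, v in AA1_TO_AA3.items()}


def rna(seq: str) -> str:
    """Render a DNA or mixed-case string as uppercase RNA."""
    return seq.upper().replace("T", "U")


def dna(seq: str) -> str:
    """Render an RNA or mixed-case string as uppercase DNA."""
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string, returned as RNA."""
    return rna(revcomp_dna(dna(seq)))


def codon_amino_acid3(codon_rna: str) -> str:
    """Three-letter amino acid for a sense codon given in RNA alphabet."""
    c = dna(codon_rna)
    if c not in CODON_TO_AA1:
        raise ValueError(f"{codon_rna!r} is not a sense codon")
    return AA1_TO_AA3[CODON_TO_AA1[c]]


def is_rna_triplet(s: str) -> bool:
    return len(s) == 3 and all(b in "ACGU" for b in s.upper().replace("T", "U"))
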