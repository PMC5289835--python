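"""Genetic-code-11 tables and small sequence helpers shared across modules.

The bacterial/plastid code (NCBI translation table 11) is the frame of
reference throughout: three stop codons (TAA, TAG, TGA), 61 sense codons,
and the standard amino-acid assignments, taken from Biopython rather than
restated by hand.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE11.forward_table))
#: codon -> 1-letter amino acid, sense codons only
AA1_OF_CODON: dict[str, str] = dict(_TABLE11.forward_table)
#: codon -> 3-letter amino acid (e.g. "Glu")
AA3_OF_CODON: dict[str, str] = {c: seq3(a) for c, a in AA1_OF_CODON.items()}

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string (raises on other characters)."""
    seq = seq.upper()
    if any(b not in BASES for b in seq):
        raise ValueError(f"non-ACGT character in {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def is_unambiguous(seq: str) -> bool:
    return all(b in BASES for b in seq)


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)
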