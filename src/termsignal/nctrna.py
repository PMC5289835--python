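"""Near-cognate tRNA classification for stop codons, and abundance fractions.

A tRNA is a near-cognate (nc_tRNA) of a stop codon when its Watson-Crick
decoded codon — the reverse complement of its anticodon — differs from the
stop codon at exactly one position; nc_tRNA1/2/3 index that mismatch
position. Strict Watson-Crick decoding (no wobble expansion) is used
throughout. tRNA gene copy numbers serve as the abundance proxy, so each
fraction is a copy-count ratio over the species' total tRNA gene copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genetics import AA3_OF_CODON, STOP_CODONS, revcomp
from .ingest import TRNAGene
from .statskit import OLSResult, ols


def decoded_codon(anticodon: str) -> str:
    """Codon read by strict Watson-Crick pairing: the 5'->3' reverse complement."""
    if len(anticodon) != 3:
        raise ValueError("anticodon must be a triplet")
    return revcomp(anticodon)


def classify_nc(anticodon: str, stop_codon: str) -> int | None:
    """Mismatch position (1-3) of the decoded codon vs the stop, else None.

    None is returned for zero mismatches (a cognate stop decoder, e.g. a
    suppressor tRNA) as well as for two or three mismatches.
    """
    if stop_codon not in STOP_CODONS:
        raise ValueError(f"{stop_codon!r} is not a stop codon")
    codon = decoded_codon(anticodon)
    mismatches = [i for i in range(3) if codon[i] != stop_codon[i]]
    return mismatches[0] + 1 if len(mismatches) == 1 else None


@dataclass
class NcClassification:
    stop_codon: str
    mismatch_position: int
    members: set[tuple[str, str]] = field(default_factory=set)  # (aa3, anticodon)


@dataclass
class NcAbundance:
    species_id: str
    p_nc1: float
    p_nc2: float
    p_nc3: float
    p_nc1_minus_gln: float
    total_trna_copies: int


def build_table1(trna_pool: list[TRNAGene]) -> list[NcClassification]:
    """Classify every distinct anticodon in the pool against each stop codon.

    The amino acid recorded for each member is the one encoded by the
    decoded codon under genetic code 11 (anticodons that decode a stop
    exactly are excluded by the single-mismatch rule).
    """
    anticodons = sorted({t.anticodon for t in trna_pool})
    out: list[NcClassification] = []
    for stop in STOP_CODONS:
        for pos in (1, 2, 3):
            members = set()
            for ac in anticodons:
                if classify_nc(ac, stop) == pos:
                    codon = decoded_codon(ac)
                    members.add((AA3_OF_CODON[codon], ac))
            if members:
                out.append(NcClassification(stop, pos, members))
    return out


def nc_abundance(trna_pool: list[TRNAGene], stop_codon: str,
                 species_id: str = "") -> NcAbundance:
    """Copy-number fractions of nc_tRNA1/2/3 for one stop codon.

    ``p_nc1_minus_gln`` repeats the position-1 fraction with the
    glutamine-decoding anticodon removed (for UAA that is 5'-TTG-3',
    cognate to CAA), since tRNA-Gln is the dominant known read-through
    contributor and can mask the remaining signal.
    """
    total = sum(t.copy_count for t in trna_pool)
    if total == 0:
        raise ValueError("total tRNA copy count is zero")
    copies = {1: 0, 2: 0, 3: 0}
    copies_nc1_gln = 0
    for t in trna_pool:
        pos = classify_nc(t.anticodon, stop_codon)
        if pos is None:
            continue
        copies[pos] += t.copy_count
        if pos == 1 and AA3_OF_CODON[decoded_codon(t.anticodon)] == "Gln":
            copies_nc1_gln += t.copy_count
    return NcAbundance(
        species_id=species_id,
        p_nc1=copies[1] / total,
        p_nc2=copies[2] / total,
        p_nc3=copies[3] / total,
        p_nc1_minus_gln=(copies[1] - copies_nc1_gln) / total,
        total_trna_copies=total,
    )


def nc_vs_plus4_regression(
    species_stats: list[tuple[float, NcAbundance]],
) -> dict[str, OLSResult | None]:
    """Regress per-species +4U usage on each nc_tRNA abundance fraction.

    ``species_stats`` pairs the +4U fraction of a species' stop-codon HEG
    set with its NcAbundance. Constant predictors are flagged with None.
    """
    if len(species_stats) < 3:
        raise ValueError("need at least 3 species")
    y = [p4u for p4u, _ in species_stats]
    out: dict[str, OLSResult | None] = {}
    for name in ("p_nc1", "p_nc2", "p_nc3", "p_nc1_minus_gln"):
        x = [getattr(nc, name) for _, nc in species_stats]
        if len(set(x)) == 1:
            out[name] = None
        else:
            out[name] = ols(x, y)
    return out
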