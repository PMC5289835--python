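"""Read annotated bacterial genomes into per-gene coding records.

Two input layouts are supported: a GenBank flat file, or a FASTA genome plus
a tab-delimited feature table (columns feature_type, start, end, strand,
locus_tag, product, anticodon; 1-based inclusive coordinates, the GenBank
convention). Internally every coordinate is 0-based half-open.

Each coding sequence is checked against the genome: its length must be a
multiple of three and its final triplet one of the genetic-code-11 stop
codons, otherwise it is skipped with a logged warning. Downstream (+4 ...)
and upstream context windows are read strand-aware from the genomic
neighbourhood, wrapping around the origin on circular replicons; on a linear
replicon a +4 base falling off the end is recorded as missing.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .genetics import STOP_CODONS, gc_fraction, is_unambiguous, revcomp

logger = logging.getLogger(__name__)

CONTEXT_LENGTH = 20  # default upstream/downstream window, bases

FEATURE_COLUMNS = (
    "feature_type", "start", "end", "strand", "locus_tag", "product", "anticodon",
)


@dataclass
class GenomeRecord:
    species_id: str
    replicon_id: str
    sequence: str
    topology: str  # "circular" | "linear"
    gc_content: float = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        self.gc_content = gc_fraction(self.sequence)


@dataclass
class CodingSequence:
    gene_id: str
    species_id: str
    codons: list[str]          # in-frame triplets, stop excluded
    stop_codon: str
    plus_four_base: str | None  # None when missing or ambiguous
    downstream: str
    upstream: str
    strand: str
    is_pseudo: bool = False
    is_hypothetical: bool = False
    is_ribosomal: bool = False
    has_ambiguity: bool = False
    product: str = ""

    def __post_init__(self) -> None:
        if self.stop_codon not in STOP_CODONS:
            raise ValueError(f"{self.stop_codon!r} is not a stop codon")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.plus_four_base is not None and self.downstream:
            if self.plus_four_base != self.downstream[0]:
                raise ValueError("plus_four_base must equal downstream[0]")


@dataclass
class TRNAGene:
    amino_acid: str      # 3-letter code, e.g. "Glu"
    anticodon: str       # 5'->3'
    copy_count: int = 1
    inferred: bool = False

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3:
            raise ValueError("anticodon must be a triplet")
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")


@dataclass
class ParsedGenome:
    genome: GenomeRecord
    cds_list: list[CodingSequence]
    trna_genes: list[TRNAGene]
    warnings: list[str]


# ---------------------------------------------------------------------------
# context extraction
# ---------------------------------------------------------------------------

def _slice_circular(seq: str, start: int, length: int) -> str:
    """length bases from 0-based start, wrapping; assumes length < len(seq)."""
    L = len(seq)
    start %= L
    if start + length <= L:
        return seq[start:start + length]
    return seq[start:] + seq[:(start + length) % L]


def extract_context(
    seq: str, start: int, end: int, strand: str, topology: str,
    n: int = CONTEXT_LENGTH,
) -> tuple[str, str]:
    """(upstream, downstream) windows of a 0-based half-open feature.

    Both are returned in coding orientation; the last upstream base adjoins
    the start codon and the first downstream base is the +4 site. On linear
    replicons a window is truncated at the end.
    """
    L = len(seq)
    if strand == "+":
        if topology == "circular":
            down = _slice_circular(seq, end, n)
            up = _slice_circular(seq, start - n, n)
        else:
            down = seq[end:end + n]
            up = seq[max(0, start - n):start]
    else:
        if topology == "circular":
            down = revcomp(_slice_circular(seq, start - n, n))
            up = revcomp(_slice_circular(seq, end, n))
        else:
            down = revcomp(seq[max(0, start - n):start])
            up = revcomp(seq[end:end + n])
    return up, down


def _make_cds(
    gene_id: str,
    species_id: str,
    cds_seq: str,
    up: str,
    down: str,
    strand: str,
    product: str,
    pseudo: bool,
    warnings: list[str],
) -> CodingSequence | None:
    if len(cds_seq) % 3 != 0:
        warnings.append(f"{gene_id}: length {len(cds_seq)} not a multiple of 3; skipped")
        return None
    stop = cds_seq[-3:]
    if stop not in STOP_CODONS:
        warnings.append(f"{gene_id}: final triplet {stop} is not a stop codon; skipped")
        return None
    codons = [cds_seq[i:i + 3] for i in range(0, len(cds_seq) - 3, 3)]
    ambiguous = not is_unambiguous(cds_seq)
    plus4: str | None = down[0] if down else None
    if plus4 is not None and plus4 not in "ACGT":
        plus4 = None
        ambiguous = True
    if ambiguous:
        warnings.append(f"{gene_id}: ambiguity codes present; excluded from +4 statistics")
    if not down:
        warnings.append(f"{gene_id}: +4 base beyond replicon end; marked missing")
    prod_l = product.lower()
    return CodingSequence(
        gene_id=gene_id,
        species_id=species_id,
        codons=codons,
        stop_codon=stop,
        plus_four_base=plus4,
        downstream=down,
        upstream=up,
        strand=strand,
        is_pseudo=pseudo,
        is_hypothetical="hypothetical" in prod_l,
        is_ribosomal="ribosomal protein" in prod_l,
        has_ambiguity=ambiguous,
        product=product,
    )


# ---------------------------------------------------------------------------
# tRNA helpers
# ---------------------------------------------------------------------------

_ANTICODON_SEQ_RE = re.compile(r"seq\s*:\s*([acgtACGT]{3})")
_TRNA_PRODUCT_RE = re.compile(r"tRNA-([A-Za-z]{3})")


def _trna_from_feature(
    product: str, anticodon_qualifier: str | None, trna_seq: str | None,
    warnings: list[str], gene_id: str,
) -> TRNAGene | None:
    m = _TRNA_PRODUCT_RE.search(product or "")
    aa = m.group(1) if m else "Xaa"
    anticodon = None
    inferred = False
    if anticodon_qualifier:
        q = anticodon_qualifier.strip()
        m2 = _ANTICODON_SEQ_RE.search(q)
        if m2:
            anticodon = m2.group(1).upper()
        elif len(q) == 3 and is_unambiguous(q.upper()):
            anticodon = q.upper()
    if anticodon is None and trna_seq:
        # canonical cloverleaf: anticodon at positions 34-36 (1-based)
        if len(trna_seq) >= 36:
            candidate = trna_seq[33:36].upper()
            if is_unambiguous(candidate):
                anticodon = candidate
                inferred = True
    if anticodon is None:
        warnings.append(f"{gene_id}: tRNA anticodon unavailable; feature skipped")
        return None
    return TRNAGene(amino_acid=aa, anticodon=anticodon, inferred=inferred)


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def parse_genome(
    path: str | Path,
    annotation_filters: dict | None = None,
    context_length: int = CONTEXT_LENGTH,
) -> ParsedGenome:
    """Parse a GenBank flat file or a FASTA + feature-table bundle.

    ``path`` may be a ``.gb``/``.gbk``/``.gbff`` file, or a FASTA file whose
    sibling ``<stem>.features.tsv`` holds the feature table (or a directory
    containing ``genome.fasta`` and ``features.tsv``).
    """
    path = Path(path)
    if path.is_dir():
        return parse_fasta_tsv(
            path / "genome.fasta", path / "features.tsv",
            context_length=context_length,
        )
    if path.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank"):
        return parse_genbank(path, context_length=context_length)
    return parse_fasta_tsv(
        path, path.with_suffix("").with_suffix(".features.tsv")
        if path.suffix else path.parent / "features.tsv",
        context_length=context_length,
    )


def parse_genbank(path: str | Path, context_length: int = CONTEXT_LENGTH) -> ParsedGenome:
    record = SeqIO.read(str(path), "genbank")
    topology = record.annotations.get("topology", "linear")
    genome = GenomeRecord(
        species_id=record.annotations.get("organism", record.id) or record.id,
        replicon_id=record.id,
        sequence=str(record.seq).upper(),
        topology=topology if topology in ("circular", "linear") else "linear",
    )
    seq = genome.sequence
    warnings: list[str] = []
    cds_list: list[CodingSequence] = []
    trnas: list[TRNAGene] = []
    counter = 0
    for feat in record.features:
        quals = feat.qualifiers
        locus = (quals.get("locus_tag", [None])[0]
                 or quals.get("gene", [None])[0]
                 or f"feature_{counter}")
        counter += 1
        product = quals.get("product", [""])[0]
        if feat.type == "CDS":
            strand = "+" if (feat.location.strand or 1) >= 0 else "-"
            cds_seq = str(feat.location.extract(record.seq)).upper()
            start = int(feat.location.start)
            end = int(feat.location.end)
            up, down = extract_context(
                seq, start, end, strand, genome.topology, context_length)
            cds = _make_cds(
                locus, genome.species_id, cds_seq, up, down, strand,
                product, "pseudo" in quals or "pseudogene" in quals, warnings)
            if cds is not None:
                cds_list.append(cds)
        elif feat.type == "tRNA":
            trna_seq = str(feat.location.extract(record.seq)).upper()
            t = _trna_from_feature(
                product, quals.get("anticodon", [None])[0], trna_seq,
                warnings, locus)
            if t is not None:
                trnas.append(t)
    for w in warnings:
        logger.warning("%s: %s", path, w)
    return ParsedGenome(genome, cds_list, _merge_trnas(trnas), warnings)


def parse_fasta_tsv(
    fasta_path: str | Path,
    features_path: str | Path,
    context_length: int = CONTEXT_LENGTH,
) -> ParsedGenome:
    record = SeqIO.read(str(fasta_path), "fasta")
    topology = "circular" if "topology=circular" in record.description else "linear"
    genome = GenomeRecord(
        species_id=record.id,
        replicon_id=record.id,
        sequence=str(record.seq).upper(),
        topology=topology,
    )
    seq = genome.sequence
    L = len(seq)
    warnings: list[str] = []
    cds_list: list[CodingSequence] = []
    trnas: list[TRNAGene] = []
    with open(features_path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")
        missing = set(FEATURE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        for row in reader:
            start = int(row["start"]) - 1      # 1-based inclusive -> 0-based half-open
            end = int(row["end"])
            strand = row["strand"]
            locus = row["locus_tag"]
            product = row.get("product", "") or ""
            if row["feature_type"] == "CDS":
                if end <= L:
                    segment = seq[start:end]
                else:                           # wraps the origin (circular)
                    segment = seq[start:] + seq[:end - L]
                cds_seq = segment if strand == "+" else revcomp(segment)
                up, down = extract_context(
                    seq, start, end, strand, genome.topology, context_length)
                pseudo = product.strip().lower() == "pseudo" or \
                    row.get("pseudo", "").strip().lower() in ("1", "true", "yes")
                cds = _make_cds(locus, genome.species_id, cds_seq, up, down,
                                strand, product, pseudo, warnings)
                if cds is not None:
                    cds_list.append(cds)
            elif row["feature_type"] == "tRNA":
                segment = seq[start:end] if strand == "+" else revcomp(seq[start:end])
                t = _trna_from_feature(
                    product, row.get("anticodon") or None, segment, warnings, locus)
                if t is not None:
                    trnas.append(t)
    for w in warnings:
        logger.warning("%s: %s", fasta_path, w)
    return ParsedGenome(genome, cds_list, _merge_trnas(trnas), warnings)


def _merge_trnas(trnas: Iterable[TRNAGene]) -> list[TRNAGene]:
    """Collapse identical (amino acid, anticodon) features into copy counts."""
    pool: dict[tuple[str, str], TRNAGene] = {}
    for t in trnas:
        key = (t.amino_acid, t.anticodon)
        if key in pool:
            pool[key].copy_count += t.copy_count
        else:
            pool[key] = TRNAGene(t.amino_acid, t.anticodon, t.copy_count, t.inferred)
    return sorted(pool.values(), key=lambda t: (t.amino_acid, t.anticodon))


# ---------------------------------------------------------------------------
# gene filtering
# ---------------------------------------------------------------------------

def filter_genes(
    cds_list: list[CodingSequence],
    nonpseudo_nonhypothetical: bool = False,
    ribosomal_only: bool = False,
    stop_codon: str | None = None,
) -> list[CodingSequence]:
    """Return the genes satisfying every active predicate, order preserved."""
    out = []
    for cds in cds_list:
        if nonpseudo_nonhypothetical and (cds.is_pseudo or cds.is_hypothetical):
            continue
        if ribosomal_only and not cds.is_ribosomal:
            continue
        if stop_codon is not None and cds.stop_codon != stop_codon:
            continue
        out.append(cds)
    return out
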