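"""Reference gene sets (HEG/LEG) from protein abundance, and codon-usage tables.

Highly-expressed genes (HEGs) are the k ribosomal-protein genes with the
largest protein abundance (ppm); lowly-expressed genes (LEGs) are the k
genes with the smallest strictly positive abundance, drawn from all
non-pseudo, non-hypothetical genes. Abundance ties at the selection boundary
break by ascending gene id so the partition is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genetics import AA1_OF_CODON, SENSE_CODONS
from .ingest import CodingSequence


@dataclass
class AbundanceTable:
    species_id: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.entries.values()):
            raise ValueError("abundances must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path, species_id: str | None = None) -> "AbundanceTable":
        entries: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                gene_id, value = line.split("\t")[:2]
                if gene_id == "gene_id":
                    continue
                if gene_id in entries:
                    raise ValueError(f"duplicate gene_id {gene_id}")
                entries[gene_id] = float(value)
        return cls(species_id or Path(path).stem, entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tabundance_ppm\n")
            for gid in sorted(self.entries):
                fh.write(f"{gid}\t{self.entries[gid]:.6g}\n")


@dataclass
class ExpressionPartition:
    heg_ids: list[str]
    leg_ids: list[str]
    method: str

    def __post_init__(self) -> None:
        if set(self.heg_ids) & set(self.leg_ids):
            raise ValueError("HEG and LEG sets overlap")


@dataclass
class CodonUsageTable:
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in SENSE_CODONS})

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codons in usage table: {sorted(bad)}")
        for c in SENSE_CODONS:
            self.counts.setdefault(c, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def scaled(self, factor: int) -> "CodonUsageTable":
        return CodonUsageTable({c: n * factor for c, n in self.counts.items()})


def select_reference_sets(
    abundance: AbundanceTable,
    cds_list: list[CodingSequence],
    k: int = 40,
    leg_exclude_ribosomal: bool = False,
) -> ExpressionPartition:
    """Pick the k top-abundance ribosomal genes (HEG) and k lowest-nonzero (LEG)."""
    eligible = [c for c in cds_list
                if not c.is_pseudo and not c.is_hypothetical
                and c.gene_id in abundance.entries]
    ribo = [c for c in eligible if c.is_ribosomal]
    if len(ribo) < k:
        raise ValueError(
            f"only {len(ribo)} ribosomal-protein genes with abundance; need k={k}")
    heg = sorted(ribo, key=lambda c: (-abundance.entries[c.gene_id], c.gene_id))[:k]
    heg_ids = [c.gene_id for c in heg]
    leg_pool = [c for c in eligible
                if abundance.entries[c.gene_id] > 0
                and c.gene_id not in set(heg_ids)
                and not (leg_exclude_ribosomal and c.is_ribosomal)]
    if len(leg_pool) < k:
        raise ValueError(
            f"only {len(leg_pool)} genes with nonzero abundance for LEG; need k={k}")
    leg = sorted(leg_pool, key=lambda c: (abundance.entries[c.gene_id], c.gene_id))[:k]
    return ExpressionPartition(heg_ids, [c.gene_id for c in leg], "top40_ribosomal")


def compile_codon_usage(cds_subset: list[CodingSequence]) -> CodonUsageTable:
    """Aggregate sense-codon counts over genes (start codon as its literal triplet)."""
    if not cds_subset:
        raise ValueError("empty gene subset")
    counts = {c: 0 for c in SENSE_CODONS}
    for cds in cds_subset:
        for codon in cds.codons:
            if codon in counts:
                counts[codon] += 1
            # ambiguous or in-frame stop triplets are simply not counted
    return CodonUsageTable(counts)


# synonymous families of the full code (6-fold families intact), for RSCU
_FAMILIES: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _FAMILIES.setdefault(AA1_OF_CODON[_c], []).append(_c)


def rscu(table: CodonUsageTable) -> dict[str, float | None]:
    """Relative synonymous codon usage; None where a family has zero total."""
    if table.total == 0:
        raise ValueError("empty codon usage table")
    out: dict[str, float | None] = {}
    for family in _FAMILIES.values():
        T = sum(table.counts[c] for c in family)
        f = len(family)
        for c in family:
            out[c] = (table.counts[c] * f / T) if T > 0 else None
    return out


def heg_leg_distinctness(
    heg_table: CodonUsageTable,
    leg_table: CodonUsageTable,
    threshold: float = 0.8,
) -> tuple[float, str]:
    """Pearson correlation of HEG vs LEG RSCU over families defined in both.

    A high correlation means the two reference sets share their codon usage,
    so an HEG/LEG-contrast index is not a valid expression proxy for that
    species. Returns (correlation, verdict) with verdict in
    {"distinct", "not distinct", "undetermined"}.
    """
    r_h = rscu(heg_table)
    r_l = rscu(leg_table)
    xs, ys = [], []
    n_shared = 0
    for family in _FAMILIES.values():
        if all(r_h[c] is not None and r_l[c] is not None for c in family):
            n_shared += 1
            xs.extend(r_h[c] for c in family)
            ys.extend(r_l[c] for c in family)
    if n_shared < 10:
        return float("nan"), "undetermined"
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.std() == 0 or y.std() == 0:
        return float("nan"), "undetermined"
    r = float(np.corrcoef(x, y)[0, 1])
    if math.isnan(r):
        return r, "undetermined"
    return r, ("not distinct" if r >= threshold else "distinct")
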