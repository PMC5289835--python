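"""Index of Translation Elongation (I_TE) and CAI codon weights and scoring.

I_TE contrasts the within-family codon frequencies of highly-expressed genes
(shaped by tRNA-mediated selection) against those of lowly-expressed genes
(approximating the background mutation bias): within each synonymous family

    r(c) = f_HEG(c) / f_LEG(c),      w(c) = r(c) / max_family r,

and a gene's score is the geometric mean of w over its scored codons. CAI
uses the HEG frequencies alone, w(c) = f_HEG(c) / max_family f_HEG. With the
six-fold families split, the Leu/Ser/Arg families are scored as their
four-codon and two-codon subfamilies, which keeps the ratio comparison
within groups read by the same tRNA isoacceptor pools.

Scored codons exclude the start codon (whatever its triplet), the stop
codon, and the single-codon families Met (ATG) and Trp (TGG), whose weight
is 1 by construction and carries no information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .expression import CodonUsageTable
from .genetics import AA1_OF_CODON, SENSE_CODONS
from .ingest import CodingSequence


@dataclass(frozen=True)
class FamilyScheme:
    description: str
    families: tuple[tuple[str, ...], ...]

    def family_of(self, codon: str) -> tuple[str, ...] | None:
        return self._index.get(codon)

    @property
    def _index(self) -> dict[str, tuple[str, ...]]:
        idx = self.__dict__.get("_idx")
        if idx is None:
            idx = {c: fam for fam in self.families for c in fam}
            self.__dict__["_idx"] = idx
        return idx

    @property
    def single_codon_families(self) -> set[str]:
        return {fam[0] for fam in self.families if len(fam) == 1}


def build_family_partition(split_six_fold: bool = True) -> FamilyScheme:
    """Synonymous families of genetic code 11.

    With ``split_six_fold`` the three six-fold families (Leu, Ser, Arg) are
    split into their four-codon subfamily (constant first two bases) and
    their two-codon subfamily.
    """
    by_aa: dict[str, list[str]] = {}
    for c in SENSE_CODONS:
        by_aa.setdefault(AA1_OF_CODON[c], []).append(c)
    families: list[tuple[str, ...]] = []
    for aa in sorted(by_aa):
        fam = sorted(by_aa[aa])
        if split_six_fold and len(fam) == 6:
            by_prefix: dict[str, list[str]] = {}
            for c in fam:
                by_prefix.setdefault(c[:2], []).append(c)
            four = next(v for v in by_prefix.values() if len(v) == 4)
            two = sorted(c for c in fam if c not in four)
            families.append(tuple(sorted(four)))
            families.append(tuple(two))
        else:
            families.append(tuple(fam))
    desc = "code11, 6-fold families split" if split_six_fold else "code11"
    return FamilyScheme(desc, tuple(families))


@dataclass
class WeightTable:
    w: dict[str, float]
    scheme: FamilyScheme
    kind: str = "ITE"

    def __post_init__(self) -> None:
        for fam in self.scheme.families:
            wmax = max(self.w[c] for c in fam)
            if abs(wmax - 1.0) > 1e-9:
                raise ValueError(f"family {fam}: max weight {wmax} != 1")
        if any(not (0.0 < v <= 1.0 + 1e-12) for v in self.w.values()):
            raise ValueError("weights must lie in (0, 1]")


@dataclass
class ITEScore:
    gene_id: str
    ite: float
    n_scored_codons: int


@dataclass
class DecileBinning:
    bins: list[list[str]]        # gene ids, lowest-scoring bin first
    bin_mean_ite: list[float]


def _family_frequencies(
    table: CodonUsageTable, family: tuple[str, ...], pseudocount: float,
) -> dict[str, float]:
    tot = sum(table.counts[c] + pseudocount for c in family)
    if tot == 0:
        raise ValueError(
            f"family {family} unobserved; use a positive pseudocount")
    return {c: (table.counts[c] + pseudocount) / tot for c in family}


def compute_weights(
    heg: CodonUsageTable,
    leg: CodonUsageTable,
    scheme: FamilyScheme | None = None,
    pseudocount: float = 0.5,
) -> WeightTable:
    """I_TE weights from HEG and LEG codon-usage tables."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if scheme is None:
        scheme = build_family_partition(split_six_fold=True)
    w: dict[str, float] = {}
    for fam in scheme.families:
        if pseudocount == 0 and any(
            heg.counts[c] == 0 or leg.counts[c] == 0 for c in fam
        ):
            raise ValueError(
                f"family {fam} has zero counts; use a positive pseudocount")
        f_h = _family_frequencies(heg, fam, pseudocount)
        f_l = _family_frequencies(leg, fam, pseudocount)
        r = {c: f_h[c] / f_l[c] for c in fam}
        rmax = max(r.values())
        for c in fam:
            w[c] = r[c] / rmax
    return WeightTable(w, scheme, "ITE")


def cai_weights(
    heg: CodonUsageTable,
    scheme: FamilyScheme | None = None,
    pseudocount: float = 0.5,
) -> WeightTable:
    """Classical relative-adaptiveness weights from HEG usage alone."""
    if scheme is None:
        scheme = build_family_partition(split_six_fold=True)
    w: dict[str, float] = {}
    for fam in scheme.families:
        f_h = _family_frequencies(heg, fam, pseudocount)
        fmax = max(f_h.values())
        if fmax == 0:
            raise ValueError(f"family {fam} unobserved; use a positive pseudocount")
        for c in fam:
            w[c] = f_h[c] / fmax
    return WeightTable(w, scheme, "CAI")


def score_gene(cds: CodingSequence, weights: WeightTable) -> ITEScore:
    """Geometric-mean codon-weight score of one gene."""
    singles = weights.scheme.single_codon_families
    log_sum = 0.0
    n = 0
    for codon in cds.codons[1:]:              # position 0 is the start codon
        if codon in singles or codon not in weights.w:
            continue
        log_sum += math.log(weights.w[codon])
        n += 1
    if n == 0:
        raise ValueError(f"{cds.gene_id}: no scorable codons")
    return ITEScore(cds.gene_id, math.exp(log_sum / n), n)


def score_genes(cds_list: list[CodingSequence], weights: WeightTable) -> list[ITEScore]:
    return [score_gene(c, weights) for c in cds_list]


def bin_by_ite(scores: list[ITEScore], n_bins: int = 10) -> DecileBinning:
    """Rank genes by score and split into near-equal ordered bins.

    Bins are ordered lowest score first; when the gene count is not a
    multiple of ``n_bins`` the remainder genes go to the lowest bins.
    """
    if len(scores) < n_bins:
        raise ValueError(f"need at least {n_bins} genes, got {len(scores)}")
    ordered = sorted(scores, key=lambda s: (s.ite, s.gene_id))
    base, rem = divmod(len(ordered), n_bins)
    bins: list[list[str]] = []
    means: list[float] = []
    pos = 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        chunk = ordered[pos:pos + size]
        pos += size
        bins.append([s.gene_id for s in chunk])
        means.append(sum(s.ite for s in chunk) / len(chunk))
    return DecileBinning(bins, means)
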