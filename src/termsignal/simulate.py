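"""Synthetic multi-species inputs with the statistical structure under study.

The generator emulates what the analysis assumes about real bacterial data:

* genes are drawn codon-by-codon from expression-class codon profiles, with
  each gene's profile a mixture of a HEG (selection-shaped) and a LEG
  (mutation-background) profile weighted by its expression percentile, so
  codon-usage indices recover the expression gradient;
* GC content is controlled through the base composition underlying the
  codon profiles (third positions carry most of the tilt) and the
  intergenic spacers, keeping GC and codon usage coupled;
* stop-codon usage and the +4-base distribution depend on expression class
  (and, across a cohort, on GC via a logistic link), planting the
  expression -> +4U enrichment with a configurable effect size;
* protein abundances are log-normal with a class-dependent location;
* across a cohort, near-cognate tRNA copy numbers for UAA are coupled to
  +4U usage with a configurable slope, and bivariate Brownian traits can be
  simulated on the cohort tree.

All randomness flows from per-spec integer seeds; identical specs give
byte-identical outputs, including file serialisations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .expression import AbundanceTable
from .genetics import AA3_OF_CODON, BASES, SENSE_CODONS, STOP_CODONS, revcomp
from .ingest import CodingSequence, GenomeRecord, TRNAGene

DEFAULT_STOP_USAGE = {
    "HEG": {"TAA": 0.70, "TAG": 0.12, "TGA": 0.18},
    "LEG": {"TAA": 0.45, "TAG": 0.25, "TGA": 0.30},
}
# (stop, class) -> probabilities over +4 = A, C, G, T
DEFAULT_PLUS4 = {
    ("TAA", "HEG"): (0.14, 0.10, 0.14, 0.62),
    ("TAA", "LEG"): (0.26, 0.22, 0.22, 0.30),
    ("TAG", "HEG"): (0.23, 0.17, 0.20, 0.40),
    ("TAG", "LEG"): (0.25, 0.25, 0.25, 0.25),
    ("TGA", "HEG"): (0.20, 0.15, 0.20, 0.45),
    ("TGA", "LEG"): (0.24, 0.23, 0.23, 0.30),
}
#: completely structureless +4 model: the zero-effect (null) condition
NULL_PLUS4 = {key: (0.25, 0.25, 0.25, 0.25) for key in DEFAULT_PLUS4}


@dataclass
class SpeciesSpec:
    species_id: str = "synthetic_sp"
    gc_content: float = 0.45
    n_genes: int = 2000
    heg_fraction: float = 0.12
    n_ribosomal: int = 50
    length_range: tuple[int, int] = (90, 150)   # codons incl. start, excl. stop
    heg_boost: float = 4.0
    codon_profiles: tuple[np.ndarray, np.ndarray] | None = None
    stop_usage: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STOP_USAGE.items()})
    plus4_model: dict[tuple[str, str], tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PLUS4))
    trna_spec: list[tuple[str, str, int]] | None = None
    hypothetical_fraction: float = 0.05
    pseudo_fraction: float = 0.02
    spacer_length: int = 40
    seed: int = 0

    def validate(self) -> None:
        if not 0.05 <= self.gc_content <= 0.95:
            raise ValueError(f"GC target {self.gc_content} infeasible")
        for cls, d in self.stop_usage.items():
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ValueError(f"stop usage for {cls} does not sum to 1")
        for key, probs in self.plus4_model.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"+4 distribution for {key} does not sum to 1")
        if not 0.0 <= self.heg_fraction <= 1.0:
            raise ValueError("heg_fraction must lie in [0, 1]")


@dataclass
class SpeciesBundle:
    genome: GenomeRecord
    cds_list: list[CodingSequence]
    trna_genes: list[TRNAGene]
    abundance: AbundanceTable
    metadata: dict


_PREFERRED_THIRD = "CTGA"   # deterministic per-family preferred-codon choice


def _profiles_at(base_gc: float, heg_boost: float) -> tuple[np.ndarray, np.ndarray]:
    p_base = {"A": (1 - base_gc) / 2, "T": (1 - base_gc) / 2,
              "G": base_gc / 2, "C": base_gc / 2}
    leg = np.array([np.prod([p_base[b] for b in c]) for c in SENSE_CODONS])
    leg /= leg.sum()
    heg = leg.copy()
    by_aa: dict[str, list[int]] = {}
    for i, c in enumerate(SENSE_CODONS):
        by_aa.setdefault(AA3_OF_CODON[c], []).append(i)
    for idxs in by_aa.values():
        if len(idxs) == 1:
            continue
        best = min(idxs, key=lambda i: (_PREFERRED_THIRD.index(SENSE_CODONS[i][2]),
                                        SENSE_CODONS[i]))
        heg[best] *= heg_boost
    heg /= heg.sum()
    return heg, leg


def default_codon_profiles(
    gc: float, heg_boost: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(HEG, LEG) codon probability vectors over the 61 sense codons.

    The LEG profile is the pure mutation-background expectation, each codon
    proportional to the product of its base probabilities; the HEG profile
    boosts one deterministically preferred codon per synonymous family,
    emulating translational selection. The underlying base composition is
    calibrated (by root finding) so the coding GC of the average profile
    matches the genomic target, since excluding stop codons and boosting
    preferred codons shifts GC away from the raw base tilt.
    """
    from scipy.optimize import brentq

    codon_gc = np.array([(c.count("G") + c.count("C")) / 3.0 for c in SENSE_CODONS])

    def gap(base_gc: float) -> float:
        heg, leg = _profiles_at(base_gc, heg_boost)
        return float(0.5 * (heg + leg) @ codon_gc) - gc

    lo, hi = 0.02, 0.98
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"GC target {gc} infeasible for codon profiles")
    base_gc = brentq(gap, lo, hi, xtol=1e-10)
    return _profiles_at(base_gc, heg_boost)


def default_trna_pool(
    rng: np.random.Generator, nc1_copies: dict[str, int] | None = None,
) -> list[TRNAGene]:
    """One isoacceptor per synonymous family plus the UAA near-cognate trio.

    ``nc1_copies`` overrides copy counts for the anticodons TTC/TTG/TTT
    (Glu/Gln/Lys), the position-1 near-cognates of UAA.
    """
    by_aa: dict[str, list[str]] = {}
    for c in SENSE_CODONS:
        by_aa.setdefault(AA3_OF_CODON[c], []).append(c)
    pool: dict[str, TRNAGene] = {}
    for aa in sorted(by_aa):
        fam = sorted(by_aa[aa])
        preferred = min(fam, key=lambda c: (_PREFERRED_THIRD.index(c[2]), c))
        ac = revcomp(preferred)
        pool[ac] = TRNAGene(aa, ac, int(rng.integers(1, 5)))
    for ac, aa in (("TTC", "Glu"), ("TTG", "Gln"), ("TTT", "Lys")):
        copies = (nc1_copies or {}).get(ac, int(rng.integers(1, 5)))
        pool[ac] = TRNAGene(aa, ac, copies)
    return sorted(pool.values(), key=lambda t: (t.amino_acid, t.anticodon))


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def generate_species(spec: SpeciesSpec) -> SpeciesBundle:
    """Generate one species' genome, gene records, tRNA pool and abundances."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    n_high = int(round(spec.heg_fraction * n))
    heg_profile, leg_profile = (
        spec.codon_profiles
        if spec.codon_profiles is not None
        else default_codon_profiles(spec.gc_content, spec.heg_boost)
    )
    heg_profile = np.asarray(heg_profile, dtype=float)
    leg_profile = np.asarray(leg_profile, dtype=float)
    for name, prof in (("HEG", heg_profile), ("LEG", leg_profile)):
        if prof.shape != (61,) or abs(prof.sum() - 1.0) > 1e-9 or (prof < 0).any():
            raise ValueError(f"{name} codon profile is not a distribution over 61 codons")

    # abundances: log-normal, class-dependent location; HEGs enriched
    abund = np.empty(n)
    abund[:n_high] = rng.lognormal(np.log(500.0), 1.0, size=n_high)
    abund[n_high:] = rng.lognormal(np.log(5.0), 1.0, size=n - n_high)
    # expression percentile in [0, 1] drives profile mixing and +4/stop models
    order = np.argsort(np.argsort(abund))
    q = order / (n - 1) if n > 1 else np.full(n, 0.5)

    stop_vec = {cls: np.array([spec.stop_usage[cls][s] for s in STOP_CODONS])
                for cls in ("HEG", "LEG")}
    plus4_vec = {k: np.asarray(v, dtype=float) for k, v in spec.plus4_model.items()}

    n_rib = min(spec.n_ribosomal, n_high)
    rib_ids = set(np.argsort(-abund[:n_high])[:n_rib]) if n_high else set()
    n_hyp = int(round(spec.hypothetical_fraction * n))
    n_pseudo = int(round(spec.pseudo_fraction * n))
    low_idx = list(range(n_high, n))
    hyp_ids = set(low_idx[:n_hyp])
    pseudo_ids = set(low_idx[n_hyp:n_hyp + n_pseudo])

    sense = np.array(list(SENSE_CODONS))
    base_arr = np.array(list(BASES))
    parts: list[str] = [_draw_bases(rng, spec.spacer_length, spec.gc_content)]
    offset = spec.spacer_length
    cds_list: list[CodingSequence] = []
    feature_rows: list[dict] = []
    entries: dict[str, float] = {}
    width = len(str(n))
    for i in range(n):
        gid = f"g{i:0{width}d}"
        profile = q[i] * heg_profile + (1 - q[i]) * leg_profile
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        body = sense[rng.choice(61, size=L - 1, p=profile)]
        codons = ["ATG", *body.tolist()]
        stop_p = q[i] * stop_vec["HEG"] + (1 - q[i]) * stop_vec["LEG"]
        stop = STOP_CODONS[rng.choice(3, p=stop_p)]
        p4_p = q[i] * plus4_vec[(stop, "HEG")] + (1 - q[i]) * plus4_vec[(stop, "LEG")]
        plus4 = base_arr[rng.choice(4, p=p4_p)]
        upstream = _draw_bases(rng, 20, spec.gc_content)
        downstream = plus4 + _draw_bases(rng, 19, spec.gc_content)
        strand = "+" if rng.random() < 0.5 else "-"
        cds_seq = "".join(codons) + stop
        block = upstream + cds_seq + downstream
        if i in rib_ids:
            product = f"50S ribosomal protein L{i + 1}"
        elif i in hyp_ids:
            product = "hypothetical protein"
        else:
            product = f"uncharacterized enzyme {gid}"
        cds_list.append(CodingSequence(
            gene_id=gid, species_id=spec.species_id, codons=codons,
            stop_codon=stop, plus_four_base=plus4, downstream=downstream,
            upstream=upstream, strand=strand, is_pseudo=i in pseudo_ids,
            is_hypothetical=i in hyp_ids, is_ribosomal=i in rib_ids,
            product=product,
        ))
        B = len(block)
        if strand == "+":
            start_1based = offset + 20 + 1
            end_1based = offset + 20 + len(cds_seq)
            parts.append(block)
        else:
            start_1based = offset + B - 20 - len(cds_seq) + 1
            end_1based = offset + B - 20
            parts.append(revcomp(block))
        feature_rows.append({
            "feature_type": "CDS", "start": start_1based, "end": end_1based,
            "strand": strand, "locus_tag": gid, "product": product,
            "anticodon": "", "pseudo": "1" if i in pseudo_ids else "",
        })
        parts.append(_draw_bases(rng, spec.spacer_length, spec.gc_content))
        offset += B + spec.spacer_length
        entries[gid] = float(abund[i])

    trnas = (
        [TRNAGene(aa, ac, cp) for aa, ac, cp in spec.trna_spec]
        if spec.trna_spec is not None
        else default_trna_pool(rng)
    )
    genome = GenomeRecord(
        species_id=spec.species_id,
        replicon_id=spec.species_id,
        sequence="".join(parts),
        topology="circular",
    )
    if spec.n_genes >= 500 and abs(genome.gc_content - spec.gc_content) > 0.03:
        raise AssertionError(
            f"realized GC {genome.gc_content:.3f} off target {spec.gc_content:.3f}")
    metadata = {
        "species_id": spec.species_id,
        "gc_target": spec.gc_content,
        "gc_realized": genome.gc_content,
        "n_genes": n,
        "stop_usage": spec.stop_usage,
        "plus4_model": {f"{s}.{c}": list(map(float, v))
                        for (s, c), v in spec.plus4_model.items()},
        "seed": spec.seed,
        "_feature_rows": feature_rows,
    }
    return SpeciesBundle(genome, cds_list, trnas,
                         AbundanceTable(spec.species_id, entries),
                         metadata)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Coupling:
    """Cross-species effect structure planted in a cohort.

    delta scales the HEG-vs-LEG +4U enrichment (1 = the default per-species
    +4 model, 0 = no expression effect); beta is the slope linking a
    species' UAA nc_tRNA1 copy fraction to its UAA-HEG +4U probability;
    gc_stop_k is the steepness of the logistic link sending GC-rich species
    toward UAG/UGA stops.
    """

    delta: float = 1.0
    beta: float = 2.0
    gc_stop_k: float = 8.0


@dataclass
class CohortSpec:
    tree_newick: str
    coupling: Coupling = field(default_factory=Coupling)
    gc_contents: dict[str, float] | None = None
    n_genes: int = 2000
    seed: int = 0


@dataclass
class CohortBundle:
    tree_newick: str
    species: dict[str, SpeciesBundle]
    traits: dict[str, dict[str, float]]
    metadata: dict


def _interpolate_plus4(delta: float, u_heg_taa: float | None = None) -> dict:
    """Scale the HEG/LEG +4 contrast by delta, optionally pinning UAA-HEG +4U."""
    model = {}
    for (stop, cls), probs in DEFAULT_PLUS4.items():
        leg = np.asarray(DEFAULT_PLUS4[(stop, "LEG")])
        tgt = np.asarray(probs)
        if cls == "HEG":
            v = leg + delta * (tgt - leg)
        else:
            v = tgt.astype(float)
        model[(stop, cls)] = tuple(np.round(v, 10))
    if u_heg_taa is not None:
        v = np.asarray(model[("TAA", "HEG")], dtype=float)
        rest = 1.0 - v[3]
        scale = (1.0 - u_heg_taa) / rest if rest > 0 else 0.0
        v[:3] *= scale
        v[3] = u_heg_taa
        model[("TAA", "HEG")] = tuple(v)
    return model


def generate_cohort(cohort: CohortSpec) -> CohortBundle:
    """Generate a full multi-species input bundle with planted couplings."""
    tree = dendropy.Tree.get(data=cohort.tree_newick, schema="newick")
    tips = sorted(t.label.replace(" ", "_") for t in tree.taxon_namespace)
    rng = np.random.default_rng(cohort.seed)
    cpl = cohort.coupling
    species: dict[str, SpeciesBundle] = {}
    traits: dict[str, dict[str, float]] = {}
    true_params: dict[str, dict] = {}
    for i, sp in enumerate(tips):
        gc = (cohort.gc_contents or {}).get(sp) if cohort.gc_contents else None
        if gc is None:
            gc = float(rng.uniform(0.30, 0.66))
        # GC-rich species drift away from UAA (logistic link)
        p_taa_heg = 0.85 / (1.0 + np.exp(cpl.gc_stop_k * (gc - 0.5)))
        p_taa_leg = 0.70 / (1.0 + np.exp(cpl.gc_stop_k * (gc - 0.5)))
        stop_usage = {
            "HEG": {"TAA": p_taa_heg, "TAG": 0.4 * (1 - p_taa_heg),
                    "TGA": 0.6 * (1 - p_taa_heg)},
            "LEG": {"TAA": p_taa_leg, "TAG": 0.45 * (1 - p_taa_leg),
                    "TGA": 0.55 * (1 - p_taa_leg)},
        }
        # nc_tRNA1 pool size varies across species and drives +4U via beta
        nc1 = {ac: 1 + int(rng.integers(0, 8)) for ac in ("TTC", "TTG", "TTT")}
        pool = default_trna_pool(rng, nc1_copies=nc1)
        total = sum(t.copy_count for t in pool)
        p_nc1 = sum(nc1.values()) / total
        leg_u = DEFAULT_PLUS4[("TAA", "LEG")][3]
        heg_u = DEFAULT_PLUS4[("TAA", "HEG")][3]
        u_heg_taa = float(np.clip(
            leg_u + cpl.delta * (heg_u - leg_u) + cpl.beta * (p_nc1 - 0.10),
            0.05, 0.95))
        spec = SpeciesSpec(
            species_id=sp,
            gc_content=gc,
            n_genes=cohort.n_genes,
            stop_usage=stop_usage,
            plus4_model=_interpolate_plus4(cpl.delta, u_heg_taa=u_heg_taa),
            trna_spec=[(t.amino_acid, t.anticodon, t.copy_count) for t in pool],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bundle = generate_species(spec)
        species[sp] = bundle
        # realized traits for contrast analyses
        taa_heg = [c for c in bundle.cds_list
                   if c.stop_codon == "TAA" and not c.is_pseudo
                   and not c.is_hypothetical]
        top = sorted(taa_heg, key=lambda c: -bundle.abundance.entries[c.gene_id])[:100]
        p_u = sum(c.plus_four_base == "T" for c in top) / len(top) if top else float("nan")
        traits[sp] = {"P_U_UAA_HEG": p_u, "p_nc1": p_nc1, "gc": gc}
        true_params[sp] = {"gc": gc, "p_nc1": p_nc1, "u_heg_taa": u_heg_taa,
                           "seed": spec.seed}
    metadata = {"coupling": asdict(cpl), "seed": cohort.seed, "species": true_params}
    return CohortBundle(cohort.tree_newick, species, traits, metadata)


def write_cohort(cohort: CohortBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(cohort.tree_newick.strip() + "\n")
    with open(out / "traits.tsv", "w") as fh:
        fh.write("species_id\ttrait_name\tvalue\n")
        for sp in sorted(cohort.traits):
            for name in sorted(cohort.traits[sp]):
                fh.write(f"{sp}\t{name}\t{cohort.traits[sp][name]:.6g}\n")
    with open(out / "metadata.json", "w") as fh:
        json.dump(cohort.metadata, fh, indent=1, sort_keys=True)
    for sp, bundle in cohort.species.items():
        write_species_files(bundle, out / sp)


def write_species_files(bundle: SpeciesBundle, out_dir: str | Path) -> None:
    """FASTA + feature-table + abundance + tRNA serialisation of one species."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = bundle.metadata.get("_feature_rows") or _feature_rows_from_bundle(bundle)
    with open(out / "genome.fasta", "w") as fh:
        fh.write(f">{bundle.genome.replicon_id} topology={bundle.genome.topology}\n")
        seq = bundle.genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    with open(out / "features.tsv", "w") as fh:
        fh.write("feature_type\tstart\tend\tstrand\tlocus_tag\tproduct\tanticodon\tpseudo\n")
        for row in rows:
            fh.write("\t".join(str(row[k]) for k in (
                "feature_type", "start", "end", "strand", "locus_tag",
                "product", "anticodon", "pseudo")) + "\n")
    bundle.abundance.to_tsv(out / "abundance.tsv")
    with open(out / "trna_pool.tsv", "w") as fh:
        fh.write("amino_acid\tanticodon\tcopy_count\n")
        for t in bundle.trna_genes:
            fh.write(f"{t.amino_acid}\t{t.anticodon}\t{t.copy_count}\n")
    with open(out / "metadata.json", "w") as fh:
        json.dump({k: v for k, v in bundle.metadata.items()
                   if not k.startswith("_")}, fh, indent=1, sort_keys=True)


def _feature_rows_from_bundle(bundle: SpeciesBundle) -> list[dict]:
    """Locate each CDS in the genome to rebuild its 1-based feature row."""
    seq = bundle.genome.sequence
    rows = []
    pos = 0
    for cds in bundle.cds_list:
        cds_seq = "".join(cds.codons) + cds.stop_codon
        target = cds_seq if cds.strand == "+" else revcomp(cds_seq)
        idx = seq.find(target, pos)
        if idx < 0:
            idx = seq.find(target)
        if idx < 0:
            raise ValueError(f"{cds.gene_id}: CDS not found in genome")
        rows.append({
            "feature_type": "CDS", "start": idx + 1, "end": idx + len(target),
            "strand": cds.strand, "locus_tag": cds.gene_id,
            "product": cds.product, "anticodon": "",
            "pseudo": "1" if cds.is_pseudo else "",
        })
        pos = idx + len(target)
    return rows


# ---------------------------------------------------------------------------
# trees and Brownian traits
# ---------------------------------------------------------------------------

def random_tree(n_tips: int, seed: int, prefix: str = "sp") -> str:
    """Random rooted binary newick with exponential-ish positive branch lengths."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    width = len(str(n_tips))
    nodes = [f"{prefix}{i:0{width}d}" for i in range(n_tips)]
    subtrees = {name: name for name in nodes}
    active = list(nodes)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        l1 = float(rng.exponential(0.2) + 0.05)
        l2 = float(rng.exponential(0.2) + 0.05)
        merged = f"({subtrees[a]}:{l1:.6f},{subtrees[b]}:{l2:.6f})"
        del active[j]
        active[i] = a
        subtrees[a] = merged
    return subtrees[active[0]] + ";"


def simulate_bm_traits(
    tree: str | dendropy.Tree,
    sigma2: float = 1.0,
    rho: float = 0.0,
    seed: int = 0,
    trait_names: tuple[str, str] = ("trait_x", "trait_y"),
) -> dict[str, dict[str, float]]:
    """Bivariate Brownian motion along the tree; increments correlated rho."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    cov = sigma2 * np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov + 1e-15 * np.eye(2))
    values: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(2)}
    out: dict[str, dict[str, float]] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            v = values[id(node)]
        else:
            t = node.edge.length or 0.0
            step = chol @ rng.standard_normal(2) * np.sqrt(t)
            v = values[id(node.parent_node)] + step
            values[id(node)] = v
        if node.is_leaf():
            name = node.taxon.label.replace(" ", "_")
            out[name] = {trait_names[0]: float(v[0]), trait_names[1]: float(v[1])}
    return out
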