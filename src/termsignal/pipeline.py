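"""End-to-end orchestration: ingest -> indices -> context tables -> tests.

`run_full` drives the whole analysis over one or more species input bundles
(FASTA + feature table + abundance TSV + optional tRNA pool), writing TSV
tables and a JSON run manifest. `run_table2_tests` applies the three
cross-species Wilcoxon tests to a table of per-species +4U proportions in
HEGs and LEGs for each stop codon.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .contrasts import TraitTree, batch_contrasts, read_trait_table
from .expression import (AbundanceTable, compile_codon_usage,
                         heg_leg_distinctness, select_reference_sets)
from .genetics import STOP_CODONS
from .ingest import CodingSequence, ParsedGenome, TRNAGene, filter_genes, parse_genome
from .ite import bin_by_ite, build_family_partition, compute_weights, score_genes
from .nctrna import build_table1, nc_abundance, nc_vs_plus4_regression
from .statskit import TestResult, wilcoxon_rank_sum
from .stop_context import (decile_trend, loglinear_stop_by_plus4,
                           shuffle_control, summarize_context)

logger = logging.getLogger(__name__)

TABLE2_COLUMNS = ("UAA_heg", "UAA_leg", "UAG_heg", "UAG_leg", "UGA_heg", "UGA_leg")


@dataclass
class RunConfig:
    species_inputs: list[str]           # dirs with genome.fasta/features.tsv/...
    out_dir: str
    reference_method: str = "top40_ribosomal"
    k: int = 40
    genes_per_stop: int = 100
    n_bins: int = 10
    pseudocount: float = 0.5
    split_six_fold: bool = True
    seed: int = 0
    tree_path: str | None = None
    trait_path: str | None = None


def packaged_table(name: str) -> Path:
    """Path of a fixture shipped with the package (table1.tsv / table2.tsv)."""
    return Path(str(importlib.resources.files("termsignal") / "data" / name))


# ---------------------------------------------------------------------------
# per-species analysis
# ---------------------------------------------------------------------------

@dataclass
class SpeciesAnalysis:
    species_id: str
    gc_percent: float
    partition_heg: list[str]
    partition_leg: list[str]
    distinctness: tuple[float, str]
    scores: dict[str, float]
    binning: object
    trend: object
    per_stop_pu: dict[str, tuple[float | None, float | None]]  # stop -> (heg, leg)
    heg_counts: pd.DataFrame
    shortfalls: dict[str, tuple[int, int]] = field(default_factory=dict)


def analyze_species(
    genome_bundle,
    config: RunConfig,
    trna_genes: list[TRNAGene] | None = None,
) -> SpeciesAnalysis:
    """Scores, decile trend, and per-stop HEG/LEG +4U for one species.

    ``genome_bundle`` needs .genome, .cds_list, .abundance attributes (a
    synthetic SpeciesBundle or a parsed-input equivalent).
    """
    genome = genome_bundle.genome
    cds_list = genome_bundle.cds_list
    abundance = genome_bundle.abundance
    clean = filter_genes(cds_list, nonpseudo_nonhypothetical=True)
    partition = select_reference_sets(abundance, clean, k=config.k)
    index = {c.gene_id: c for c in clean}
    heg_table = compile_codon_usage([index[g] for g in partition.heg_ids])
    leg_table = compile_codon_usage([index[g] for g in partition.leg_ids])
    distinct = heg_leg_distinctness(heg_table, leg_table)
    scheme = build_family_partition(config.split_six_fold)
    weights = compute_weights(heg_table, leg_table, scheme, config.pseudocount)
    scores = score_genes(clean, weights)
    binning = bin_by_ite(scores, config.n_bins)
    trend = decile_trend(binning, index)

    # Table-2-style per-stop contrast: the genes_per_stop highest/lowest
    # scoring genes ending in each stop codon
    score_of = {s.gene_id: s.ite for s in scores}
    per_stop: dict[str, tuple[float | None, float | None]] = {}
    shortfalls: dict[str, tuple[int, int]] = {}
    for stop in STOP_CODONS:
        ending = [c for c in clean if c.stop_codon == stop]
        ranked = sorted(ending, key=lambda c: (-score_of[c.gene_id], c.gene_id))
        top = ranked[:config.genes_per_stop]
        bottom = ranked[-config.genes_per_stop:][::-1] if ranked else []
        if len(ending) < 2 * config.genes_per_stop:
            shortfalls[stop] = (len(top), len(bottom))
        def _pu(genes):
            known = [c for c in genes if c.plus_four_base is not None]
            if not known:
                return None
            return sum(c.plus_four_base == "T" for c in known) / len(known)
        per_stop[stop] = (_pu(top), _pu(bottom))
    heg_summary = summarize_context(
        [index[g] for g in partition.heg_ids])
    return SpeciesAnalysis(
        species_id=genome.species_id,
        gc_percent=100.0 * genome.gc_content,
        partition_heg=partition.heg_ids,
        partition_leg=partition.leg_ids,
        distinctness=distinct,
        scores={s.gene_id: s.ite for s in scores},
        binning=binning,
        trend=trend,
        per_stop_pu=per_stop,
        heg_counts=heg_summary.counts,
        shortfalls=shortfalls,
    )


# ---------------------------------------------------------------------------
# Table-2-style cross-species Wilcoxon battery
# ---------------------------------------------------------------------------

def run_table2_tests(table2_tsv: str | Path) -> dict[str, TestResult]:
    """Three two-sample Wilcoxon tests (UAA/UAG/UGA; HEG vs LEG columns).

    The continuity-corrected, tie-corrected normal approximation is used,
    matching how such a table is conventionally tested.
    """
    df = pd.read_csv(table2_tsv, sep="\t")
    missing = set(TABLE2_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Table-2-style file missing columns: {sorted(missing)}")
    out: dict[str, TestResult] = {}
    for stop_rna, stop in (("UAA", "TAA"), ("UAG", "TAG"), ("UGA", "TGA")):
        x = df[f"{stop_rna}_heg"].astype(float).tolist()
        y = df[f"{stop_rna}_leg"].astype(float).tolist()
        out[stop_rna] = wilcoxon_rank_sum(x, y, continuity=True, mode="normal")
    return out


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class InputBundle:
    genome: object
    cds_list: list[CodingSequence]
    abundance: AbundanceTable
    trna_genes: list[TRNAGene]


def load_species_dir(path: str | Path) -> InputBundle:
    path = Path(path)
    parsed: ParsedGenome = parse_genome(path)
    abundance = AbundanceTable.from_tsv(path / "abundance.tsv",
                                        parsed.genome.species_id)
    trnas = list(parsed.trna_genes)
    pool_path = path / "trna_pool.tsv"
    if pool_path.exists():
        df = pd.read_csv(pool_path, sep="\t")
        trnas = [TRNAGene(r.amino_acid, r.anticodon, int(r.copy_count))
                 for r in df.itertuples()]
    return InputBundle(parsed.genome, parsed.cds_list, abundance, trnas)


def run_full(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; abort cleanly on error.

    Emits: table2_style.tsv, table1_style.tsv, decile_trends.tsv,
    wilcoxon.tsv, nctrna_regressions.tsv, loglinear.tsv, shuffle_control.tsv,
    contrasts.json (when a tree is given) and manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    stage = "setup"
    try:
        stage = "ingest"
        bundles = {Path(p).name: load_species_dir(p) for p in config.species_inputs}

        stage = "per-species analysis"
        analyses: dict[str, SpeciesAnalysis] = {}
        for name, bundle in bundles.items():
            analyses[name] = analyze_species(bundle, config)

        stage = "table2"
        rows = []
        for name, a in analyses.items():
            row = {"species": a.species_id, "accession": name,
                   "gc_percent": round(a.gc_percent, 3)}
            for stop_rna, stop in (("UAA", "TAA"), ("UAG", "TAG"), ("UGA", "TGA")):
                heg, leg = a.per_stop_pu[stop]
                row[f"{stop_rna}_heg"] = heg
                row[f"{stop_rna}_leg"] = leg
            rows.append(row)
        table2 = pd.DataFrame(rows).sort_values("species").reset_index(drop=True)
        emit("table2_style.tsv",
             lambda p: table2.to_csv(p, sep="\t", index=False))

        stage = "wilcoxon battery"
        if len(table2) >= 3 and not table2.filter(like="_heg").isna().any().any():
            results = {}
            for stop_rna in ("UAA", "UAG", "UGA"):
                results[stop_rna] = wilcoxon_rank_sum(
                    table2[f"{stop_rna}_heg"], table2[f"{stop_rna}_leg"],
                    continuity=True, mode="normal")
            wdf = pd.DataFrame([
                {"stop": s, "statistic": r.statistic, "p_value": r.p_value,
                 "n": r.n[0]} for s, r in results.items()])
            emit("wilcoxon.tsv", lambda p: wdf.to_csv(p, sep="\t", index=False))

        stage = "log-linear tests"
        ll_rows = []
        for name, a in analyses.items():
            res = loglinear_stop_by_plus4(a.heg_counts.to_numpy())
            ll_rows.append({"species": a.species_id, "test": "two-way",
                            "G": res.statistic, "df": res.notes["df"],
                            "p_value": res.p_value})
        names = sorted(analyses)
        if len(names) >= 2:
            res3 = loglinear_stop_by_plus4(
                analyses[names[0]].heg_counts.to_numpy(),
                analyses[names[1]].heg_counts.to_numpy())
            ll_rows.append({"species": f"{names[0]}|{names[1]}",
                            "test": "three-way", "G": res3.statistic,
                            "df": res3.notes["df"], "p_value": res3.p_value})
        lldf = pd.DataFrame(ll_rows)
        emit("loglinear.tsv", lambda p: lldf.to_csv(p, sep="\t", index=False))

        stage = "decile trends"
        t_rows = []
        for name, a in analyses.items():
            for series, reg in a.trend.regressions.items():
                t_rows.append({"species": a.species_id, "series": series,
                               "slope": reg.slope, "r_squared": reg.r_squared,
                               "p_value": reg.p_value})
        tdf = pd.DataFrame(t_rows)
        emit("decile_trends.tsv", lambda p: tdf.to_csv(p, sep="\t", index=False))

        stage = "shuffle control"
        s_rows = []
        for name, (bundle, a) in ((n, (bundles[n], analyses[n])) for n in analyses):
            index = {c.gene_id: c for c in bundle.cds_list}
            reg, _ = shuffle_control(
                [index[g] for g in a.scores], a.binning, seed=config.seed)
            s_rows.append({"species": a.species_id, "slope": reg.slope,
                           "r_squared": reg.r_squared, "p_value": reg.p_value})
        sdf = pd.DataFrame(s_rows)
        emit("shuffle_control.tsv", lambda p: sdf.to_csv(p, sep="\t", index=False))

        stage = "nc_tRNA"
        t1_rows = []
        species_stats = []
        for name, bundle in bundles.items():
            a = analyses[name]
            for cls in build_table1(bundle.trna_genes):
                for aa, ac in sorted(cls.members):
                    t1_rows.append({"species": a.species_id,
                                    "stop_codon": cls.stop_codon,
                                    "mismatch_position": cls.mismatch_position,
                                    "amino_acid": aa, "anticodon": ac})
            if bundle.trna_genes:
                nc = nc_abundance(bundle.trna_genes, "TAA", a.species_id)
                pu = a.per_stop_pu["TAA"][0]
                if pu is not None:
                    species_stats.append((pu, nc))
        t1df = pd.DataFrame(t1_rows)
        emit("table1_style.tsv", lambda p: t1df.to_csv(p, sep="\t", index=False))
        if len(species_stats) >= 3:
            regs = nc_vs_plus4_regression(species_stats)
            ndf = pd.DataFrame([
                {"predictor": k, "slope": r.slope, "r_squared": r.r_squared,
                 "p_value": r.p_value}
                for k, r in regs.items() if r is not None])
            emit("nctrna_regressions.tsv",
                 lambda p: ndf.to_csv(p, sep="\t", index=False))

        stage = "independent contrasts"
        if config.tree_path and config.trait_path:
            traits = read_trait_table(config.trait_path)
            text = Path(config.tree_path).read_text()
            newicks = [ln for ln in text.splitlines() if ln.strip()]
            trees = [TraitTree.from_newick(nw, traits) for nw in newicks]
            if len(trees[0].tip_names()) < 4:
                raise ValueError(
                    "contrast regression needs at least 4 tips "
                    f"({len(trees[0].tip_names())} given)")
            trait_names = sorted(next(iter(traits.values())))
            pairs = {}
            for i, x in enumerate(trait_names):
                for y in trait_names[i + 1:]:
                    batch = batch_contrasts(trees, x, y)
                    pairs[f"{y}~{x}"] = batch["summary"]
            emit("contrasts.json",
                 lambda p: p.write_text(json.dumps(pairs, indent=1, sort_keys=True)))

        stage = "manifest"
        manifest = {
            "package": "termsignal",
            "version": __version__,
            "config": asdict(config),
            "n_species": len(bundles),
            "outputs": [p.name for p in written] + ["manifest.json"],
        }
        emit("manifest.json",
             lambda p: p.write_text(json.dumps(manifest, indent=1, sort_keys=True)))
        return manifest
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        logger.error("run_full aborted during stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc
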