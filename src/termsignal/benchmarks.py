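"""Parameter-recovery benchmarks run on the synthetic generator's defaults.

Genome-scale results from the original comparative study cannot be
recomputed without the underlying genome set, so the pipeline is validated
by recovery of effects the generator plants: the expression -> +4U decile
trend, its null (zero-effect) counterpart, the shuffled-5'-window control,
and Brownian-motion contrast calibration. Every function is deterministic
given its seed and reports the quantities the validation asserts on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contrasts import TraitTree, contrast_correlation, independent_contrasts
from .nctrna import build_table1
from .ingest import TRNAGene
from .pipeline import RunConfig, packaged_table, run_table2_tests
from .simulate import (NULL_PLUS4, SpeciesSpec, generate_species, random_tree,
                       simulate_bm_traits)
from .stop_context import shuffle_control


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def trend_recovery(
    n_reps: int, seed: int, null: bool = False, with_shuffle: bool = False,
    n_genes: int | None = None,
) -> dict:
    """Decile-trend P_U regression over seeded synthetic replicates.

    Returns the fraction of replicates with a positive slope at p < 0.05,
    the slope distribution, and (optionally) the shuffled-window R^2 per
    replicate. ``null=True`` removes all +4 structure from the generator.
    """
    from .pipeline import analyze_species

    config = RunConfig([], out_dir=".")
    slopes, pvals, shuffle_r2 = [], [], []
    hits = 0
    for i, sub in enumerate(_sub_seeds(seed, n_reps)):
        spec = SpeciesSpec(species_id=f"rep{i}", seed=int(sub))
        if n_genes is not None:
            spec.n_genes = n_genes
        if null:
            spec.plus4_model = dict(NULL_PLUS4)
        bundle = generate_species(spec)
        analysis = analyze_species(bundle, config)
        reg = analysis.trend.regressions["P_U"]
        slopes.append(reg.slope)
        pvals.append(reg.p_value)
        hits += (reg.slope > 0 and reg.p_value < 0.05)
        if with_shuffle:
            index = {c.gene_id: c for c in bundle.cds_list}
            sreg, _ = shuffle_control(
                [index[g] for g in analysis.scores], analysis.binning,
                seed=int(sub))
            shuffle_r2.append(sreg.r_squared)
    out = {
        "n_reps": n_reps,
        "recovery_rate": hits / n_reps,
        "slope_mean": float(np.mean(slopes)),
        "slope_sd": float(np.std(slopes, ddof=1)) if n_reps > 1 else 0.0,
        "slopes": slopes,
        "p_values": pvals,
    }
    if with_shuffle:
        out["shuffle_r2_mean"] = float(np.mean(shuffle_r2))
        out["shuffle_r2"] = shuffle_r2
    return out


def contrast_calibration(
    seed: int, n_var_reps: int = 1000, n_rho_reps: int = 500,
    rho: float = 0.8, n_tips: int = 19,
) -> dict:
    """Brownian-motion contrast benchmarks on a random rooted binary tree.

    Standardized contrasts of unit-rate Brownian traits are i.i.d. N(0, 1),
    so their pooled variance should sit near 1; the through-origin contrast
    correlation should recover the simulated rho.
    """
    newick = random_tree(n_tips, seed)
    var_seeds = _sub_seeds(seed + 1, n_var_reps)
    all_contrasts: list[float] = []
    for sub in var_seeds:
        traits = simulate_bm_traits(newick, sigma2=1.0, rho=0.0, seed=int(sub))
        tt = TraitTree.from_newick(newick, traits)
        all_contrasts.extend(independent_contrasts(tt, "trait_x").contrasts)
    rho_seeds = _sub_seeds(seed + 2, n_rho_reps)
    corrs = []
    for sub in rho_seeds:
        traits = simulate_bm_traits(newick, sigma2=1.0, rho=rho, seed=int(sub))
        tt = TraitTree.from_newick(newick, traits)
        corrs.append(contrast_correlation(
            independent_contrasts(tt, "trait_x"),
            independent_contrasts(tt, "trait_y")))
    return {
        "contrast_variance": float(np.var(all_contrasts, ddof=1)),
        "rho_true": rho,
        "rho_mean": float(np.mean(corrs)),
        "n_contrasts": len(all_contrasts),
        "n_rho_reps": n_rho_reps,
    }


def table1_discrepancies() -> int:
    """Mismatches between the classifier and the shipped reference table."""
    ref = pd.read_csv(packaged_table("table1.tsv"), sep="\t")
    pool = [TRNAGene(r.amino_acid, r.anticodon)
            for r in ref.drop_duplicates("anticodon").itertuples()]
    got = {(c.stop_codon, aa, ac)
           for c in build_table1(pool) for aa, ac in c.members}
    expected = {(r.stop_codon, r.amino_acid, r.anticodon)
                for r in ref.itertuples()}
    return len(got ^ expected)


def table2_pvalues() -> dict[str, float]:
    """The three cross-species Wilcoxon p-values from the shipped table."""
    results = run_table2_tests(packaged_table("table2.tsv"))
    return {stop: res.p_value for stop, res in results.items()}
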