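"""Stop-codon and +4-base usage statistics for gene sets.

Proportions are exact count ratios. Genes whose +4 base is missing or
ambiguous contribute to stop-codon usage but not to the +4 distribution.
The dependence of the +4 distribution on the stop codon is tested with
likelihood-ratio (G) statistics: independence in the two-way case, and the
no-three-way-interaction log-linear model (fitted by iterative proportional
fitting) when two species are compared.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genetics import BASES, STOP_CODONS
from .ingest import CodingSequence
from .ite import DecileBinning
from .statskit import OLSResult, TestResult, ols

logger = logging.getLogger(__name__)

#: names of the per-bin series tracked along the expression gradient
TREND_SERIES = ("P_UAA", "P_UAG", "P_UGA", "P_A", "P_C", "P_G", "P_U")

_RNA_OF_STOP = {"TAA": "UAA", "TAG": "UAG", "TGA": "UGA"}
_RNA_OF_BASE = {"A": "A", "C": "C", "G": "G", "T": "U"}


@dataclass
class StopContextSummary:
    n_genes: int
    p_stop: dict[str, float]
    p4: dict[tuple[str, str], float | None]  # (stop, base) -> fraction | None
    counts: pd.DataFrame                      # 3 stops x 4 bases, +4-known genes
    stop_counts: dict[str, int]
    plus4_base_counts: dict[str, int] = field(default_factory=dict)

    @property
    def p4_unconditional(self) -> dict[str, float | None]:
        tot = sum(self.plus4_base_counts.values())
        if tot == 0:
            return {b: None for b in BASES}
        return {b: self.plus4_base_counts[b] / tot for b in BASES}


def summarize_context(cds_subset: list[CodingSequence]) -> StopContextSummary:
    """Exact stop-codon and conditional +4-base proportions of a gene set."""
    if not cds_subset:
        raise ValueError("empty gene subset")
    stop_counts = {s: 0 for s in STOP_CODONS}
    table = pd.DataFrame(0, index=list(STOP_CODONS), columns=list(BASES))
    base_counts = {b: 0 for b in BASES}
    for cds in cds_subset:
        stop_counts[cds.stop_codon] += 1
        if cds.plus_four_base is not None and not cds.has_ambiguity:
            table.loc[cds.stop_codon, cds.plus_four_base] += 1
            base_counts[cds.plus_four_base] += 1
    n = len(cds_subset)
    p_stop = {s: stop_counts[s] / n for s in STOP_CODONS}
    p4: dict[tuple[str, str], float | None] = {}
    for s in STOP_CODONS:
        row_total = int(table.loc[s].sum())
        for b in BASES:
            p4[(s, b)] = table.loc[s, b] / row_total if row_total > 0 else None
    return StopContextSummary(n, p_stop, p4, table, stop_counts, base_counts)


def contrast_heg_leg(
    heg_summary: StopContextSummary, leg_summary: StopContextSummary,
) -> pd.DataFrame:
    """Per (stop, base): HEG proportion, LEG proportion, and their difference."""
    rows = []
    for s in STOP_CODONS:
        for b in BASES:
            ph = heg_summary.p4[(s, b)]
            pl = leg_summary.p4[(s, b)]
            rows.append({
                "stop": _RNA_OF_STOP[s],
                "base": _RNA_OF_BASE[b],
                "p_heg": ph,
                "p_leg": pl,
                "delta": (ph - pl) if ph is not None and pl is not None else None,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# log-linear G-tests
# ---------------------------------------------------------------------------

def _g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    mask = observed > 0
    return float(2.0 * (observed[mask] * np.log(observed[mask] / expected[mask])).sum())


def _ipf_no_three_way(observed: np.ndarray, tol: float = 1e-10,
                      max_sweeps: int = 1000) -> np.ndarray:
    """Fit the no-three-way-interaction model to a 3-d table by IPF."""
    fitted = np.ones_like(observed, dtype=float)
    targets = [observed.sum(axis=2), observed.sum(axis=1), observed.sum(axis=0)]
    for _ in range(max_sweeps):
        m01 = fitted.sum(axis=2)
        fitted *= np.divide(targets[0], m01, out=np.ones_like(m01), where=m01 > 0)[:, :, None]
        m02 = fitted.sum(axis=1)
        fitted *= np.divide(targets[1], m02, out=np.ones_like(m02), where=m02 > 0)[:, None, :]
        m12 = fitted.sum(axis=0)
        fitted *= np.divide(targets[2], m12, out=np.ones_like(m12), where=m12 > 0)[None, :, :]
        err = max(
            np.abs(fitted.sum(axis=2) - targets[0]).max(),
            np.abs(fitted.sum(axis=1) - targets[1]).max(),
            np.abs(fitted.sum(axis=0) - targets[2]).max(),
        )
        if err < tol:
            break
    return fitted


def loglinear_stop_by_plus4(
    counts_3x4,
    second_species_counts=None,
) -> TestResult:
    """G-test of +4-base/stop-codon association.

    One table: likelihood-ratio test of independence (df 6 on a full 3x4
    table; rows/columns with zero margins are dropped with the df adjusted).
    Two tables: likelihood-ratio test of the species x stop x base
    interaction against the no-three-way-interaction log-linear model.
    """
    obs = np.asarray(counts_3x4, dtype=float)
    if obs.shape != (3, 4):
        raise ValueError("expected a 3x4 stop-by-base table")
    notes: dict = {}
    if second_species_counts is None:
        keep_r = obs.sum(axis=1) > 0
        keep_c = obs.sum(axis=0) > 0
        if not keep_r.all() or not keep_c.all():
            notes["dropped"] = f"rows={int((~keep_r).sum())}, cols={int((~keep_c).sum())}"
            logger.warning("zero margins dropped from G-test: %s", notes["dropped"])
        t = obs[np.ix_(keep_r, keep_c)]
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        g = _g_statistic(t, expected)
        df = (t.shape[0] - 1) * (t.shape[1] - 1)
        method = "G-test of independence (stop x +4 base)"
    else:
        obs2 = np.asarray(second_species_counts, dtype=float)
        if obs2.shape != (3, 4):
            raise ValueError("expected a 3x4 stop-by-base table")
        stack = np.stack([obs, obs2])
        fitted = _ipf_no_three_way(stack)
        g = _g_statistic(stack, np.where(fitted > 0, fitted, 1.0))
        df = (stack.shape[0] - 1) * (stack.shape[1] - 1) * (stack.shape[2] - 1)
        method = "G-test of species x stop x +4 interaction (IPF)"
    p = float(sps.chi2.sf(g, df))
    notes["df"] = df
    return TestResult(method, g, p, False, (int(obs.sum()),), notes)


# ---------------------------------------------------------------------------
# expression-decile trends
# ---------------------------------------------------------------------------

@dataclass
class DecileTrend:
    bin_mean_ite: list[float]
    series: dict[str, list[float]]
    regressions: dict[str, OLSResult]


def decile_trend(
    binning: DecileBinning,
    cds_index: dict[str, CodingSequence],
) -> DecileTrend:
    """Stop-codon and +4-base usage per expression bin, regressed on mean score.

    P_UAA/P_UAG/P_UGA are stop-codon fractions; P_A/P_C/P_G/P_U are +4-base
    fractions unconditional on the stop codon.
    """
    series: dict[str, list[float]] = {name: [] for name in TREND_SERIES}
    for gene_ids in binning.bins:
        if not gene_ids:
            raise ValueError("empty expression bin")
        summary = summarize_context([cds_index[g] for g in gene_ids])
        for s in STOP_CODONS:
            series[f"P_{_RNA_OF_STOP[s]}"].append(summary.p_stop[s])
        uncond = summary.p4_unconditional
        for b in BASES:
            v = uncond[b]
            series[f"P_{_RNA_OF_BASE[b]}"].append(v if v is not None else math.nan)
    regressions = {
        name: ols(binning.bin_mean_ite, vals)
        for name, vals in series.items()
        if not any(math.isnan(v) for v in vals)
    }
    return DecileTrend(list(binning.bin_mean_ite), series, regressions)


def shuffle_control(
    cds_list: list[CodingSequence],
    binning: DecileBinning,
    seed: int,
    region: str = "upstream20",
) -> tuple[OLSResult, dict[str, list[float]]]:
    """Shuffle each gene's 20-base 5' window and re-measure the U trend there.

    Each gene's window is permuted with a seeded generator (composition
    preserved by construction) and the fraction of U at the shuffled
    window's first base is regressed on bin mean score, exactly as the +4U
    series is. A planted +4-specific signal does not survive this because
    the upstream window carries no stop-context information.
    Returns (regression, per-bin U-fraction series).
    """
    if region != "upstream20":
        raise ValueError(f"unknown region {region!r}")
    rng = np.random.default_rng(seed)
    first_base: dict[str, str] = {}
    shuffled_windows: dict[str, str] = {}
    dropped = 0
    for cds in cds_list:
        window = cds.upstream[-20:] if len(cds.upstream) >= 20 else None
        if not window:
            dropped += 1
            continue
        shuffled = "".join(rng.permutation(list(window)))
        shuffled_windows[cds.gene_id] = shuffled
        first_base[cds.gene_id] = shuffled[0]
    if dropped:
        logger.warning("shuffle control: %d genes without a 20-base 5' window", dropped)
    series: list[float] = []
    for gene_ids in binning.bins:
        present = [g for g in gene_ids if g in first_base]
        if not present:
            raise ValueError("expression bin with no shuffleable genes")
        series.append(sum(first_base[g] == "T" for g in present) / len(present))
    reg = ols(binning.bin_mean_ite, series)
    return reg, {"P_U_shuffled": series, "windows": shuffled_windows}
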