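"""Stop-context summaries, HEG/LEG contrasts, G-tests, trends, shuffle control."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from termsignal.ingest import CodingSequence
from termsignal.ite import DecileBinning
from termsignal.stop_context import (contrast_heg_leg, decile_trend,
                                     loglinear_stop_by_plus4, shuffle_control,
                                     summarize_context)


def gene_of(gid, stop="TAA", plus4="T", upstream=None):
    up = upstream if upstream is not None else "ACGTACGTACGTACGTACGT"
    return CodingSequence(
        gene_id=gid, species_id="s", codons=["ATG", "AAA"], stop_codon=stop,
        plus_four_base=plus4, downstream=plus4 + "G" * 19, upstream=up,
        strand="+")


class TestSummarize:
    def test_ecoli_heg_uaa_worked_example(self):
        # 100 UAA-ending genes, 62 with +4U: the E. coli HEG P_U.UAA cell
        genes = [gene_of(f"g{i}", "TAA", "T" if i < 62 else "A")
                 for i in range(100)]
        s = summarize_context(genes)
        assert s.p4[("TAA", "T")] == pytest.approx(0.62)

    def test_uniform_four_bases(self):
        genes = [gene_of(f"g{i}", "TAA", b) for i, b in enumerate("ACGT")]
        s = summarize_context(genes)
        assert all(s.p4[("TAA", b)] == pytest.approx(0.25) for b in "ACGT")

    def test_absent_stop_is_missing(self):
        genes = [gene_of("a", "TAA"), gene_of("b", "TAG")]
        s = summarize_context(genes)
        assert s.p_stop["TGA"] == 0.0
        assert all(s.p4[("TGA", b)] is None for b in "ACGT")

    def test_counts_reconstruct_exactly(self):
        rng = np.random.default_rng(0)
        stops = ["TAA", "TAG", "TGA"]
        genes = [gene_of(f"g{i}", stops[rng.integers(3)], "ACGT"[rng.integers(4)])
                 for i in range(57)]
        s = summarize_context(genes)
        assert int(s.counts.to_numpy().sum()) == 57
        for stop in stops:
            row = int(s.counts.loc[stop].sum())
            for b in "ACGT":
                if row:
                    assert s.p4[(stop, b)] * row == pytest.approx(
                        s.counts.loc[stop, b], abs=1e-9)
        assert sum(s.p_stop.values()) == pytest.approx(1.0)

    def test_missing_plus4_kept_in_stop_usage(self):
        genes = [gene_of("a", "TAA"), gene_of("b", "TAA")]
        genes[1].plus_four_base = None
        genes[1].downstream = ""
        s = summarize_context(genes)
        assert s.p_stop["TAA"] == 1.0
        assert s.p4[("TAA", "T")] == pytest.approx(1.0)   # only gene a counts

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_context([])


class TestContrast:
    def test_worked_deltas(self):
        heg = summarize_context(
            [gene_of(f"h{i}", "TAA", "T" if i < 62 else "C") for i in range(100)])
        leg = summarize_context(
            [gene_of(f"l{i}", "TAA", "T" if i < 30 else "C") for i in range(100)])
        df = contrast_heg_leg(heg, leg)
        row = df[(df.stop == "UAA") & (df.base == "U")].iloc[0]
        assert row.delta == pytest.approx(0.32)

    def test_identical_summaries_zero_delta(self):
        s = summarize_context([gene_of(f"g{i}", "TAA", "T") for i in range(5)])
        df = contrast_heg_leg(s, s)
        assert (df.dropna().delta == 0).all()


class TestLogLinear:
    def test_proportional_rows_give_zero_g(self):
        t = np.array([[10, 20, 30, 40], [1, 2, 3, 4], [5, 10, 15, 20]])
        res = loglinear_stop_by_plus4(t)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_direct_formula_and_scipy(self):
        t = np.array([[30, 10, 10, 50], [25, 25, 25, 25], [10, 40, 40, 10]])
        res = loglinear_stop_by_plus4(t)
        expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
        g_direct = 2 * (t * np.log(t / expected)).sum()
        assert res.statistic == pytest.approx(g_direct, abs=1e-10)
        g_scipy, p_scipy, df, _ = chi2_contingency(t, lambda_="log-likelihood",
                                                   correction=False)
        assert res.statistic == pytest.approx(g_scipy, abs=1e-10)
        assert res.p_value == pytest.approx(p_scipy, abs=1e-12)
        assert res.notes["df"] == df == 6

    def test_zero_margin_dropped_with_df_adjusted(self):
        t = np.array([[30, 10, 10, 50], [25, 25, 25, 25], [0, 0, 0, 0]])
        res = loglinear_stop_by_plus4(t)
        assert res.notes["df"] == 3
        assert "dropped" in res.notes

    def test_three_way_identical_tables_zero_interaction(self):
        t = np.array([[30, 10, 10, 50], [25, 25, 25, 25], [10, 40, 40, 10]])
        res = loglinear_stop_by_plus4(t, t)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.notes["df"] == 6

    def test_three_way_detects_planted_interaction(self):
        t1 = np.array([[60, 10, 10, 20], [10, 60, 20, 10], [10, 10, 60, 20]])
        t2 = t1[::-1].copy()    # stop-by-base association reversed in species 2
        res = loglinear_stop_by_plus4(t1, t2)
        assert res.p_value < 1e-6


class TestDecileTrend:
    @staticmethod
    def _make(series_pu):
        """10 bins of 50 genes with prescribed +4U fractions."""
        bins, index = [], {}
        for b, pu in enumerate(series_pu):
            ids = []
            for i in range(50):
                gid = f"b{b}g{i}"
                plus4 = "T" if i < round(pu * 50) else "A"
                index[gid] = gene_of(gid, "TAA", plus4)
                ids.append(gid)
            bins.append(ids)
        binning = DecileBinning(bins, [0.1 * (b + 1) for b in range(10)])
        return binning, index

    def test_linear_series_recovered_exactly(self):
        target = [0.1 * (b + 1) for b in range(10)]
        binning, index = self._make(target)
        trend = decile_trend(binning, index)
        assert trend.series["P_U"] == pytest.approx(target)
        reg = trend.regressions["P_U"]
        assert reg.slope == pytest.approx(1.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_series_r2_zero(self):
        binning, index = self._make([0.5] * 10)
        trend = decile_trend(binning, index)
        assert trend.regressions["P_U"].r_squared == pytest.approx(0.0)
        assert trend.regressions["P_UAA"].r_squared == pytest.approx(0.0)

    def test_planted_expression_trend_recovered(self):
        from termsignal.pipeline import RunConfig, analyze_species
        from termsignal.simulate import SpeciesSpec, generate_species
        bundle = generate_species(SpeciesSpec(species_id="sp", seed=99))
        a = analyze_species(bundle, RunConfig([], out_dir="."))
        reg = a.trend.regressions["P_U"]
        assert reg.slope > 0 and reg.p_value < 0.05


class TestShuffleControl:
    @staticmethod
    def _setup(seed=0):
        rng = np.random.default_rng(4)
        bins, index, genes = [], {}, []
        for b in range(10):
            ids = []
            for i in range(20):
                gid = f"b{b}g{i}"
                up = "".join(rng.choice(list("ACGT"), size=20))
                g = gene_of(gid, "TAA", "T", upstream=up)
                index[gid] = g
                genes.append(g)
                ids.append(gid)
            bins.append(ids)
        return genes, DecileBinning(bins, [0.1 * (b + 1) for b in range(10)])

    def test_determinism(self):
        genes, binning = self._setup()
        r1, d1 = shuffle_control(genes, binning, seed=7)
        r2, d2 = shuffle_control(genes, binning, seed=7)
        assert r1 == r2 and d1["P_U_shuffled"] == d2["P_U_shuffled"]

    def test_composition_preserved_per_gene(self):
        genes, binning = self._setup()
        _, detail = shuffle_control(genes, binning, seed=3)
        for g in genes:
            assert sorted(detail["windows"][g.gene_id]) == sorted(g.upstream)

    def test_genes_without_window_dropped(self):
        genes, binning = self._setup()
        genes[0].upstream = "ACG"
        reg, detail = shuffle_control(genes, binning, seed=1)
        assert genes[0].gene_id not in detail["windows"]
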