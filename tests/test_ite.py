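"""I_TE / CAI weight computation, gene scoring, and expression binning."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from termsignal.expression import CodonUsageTable, compile_codon_usage
from termsignal.ingest import CodingSequence
from termsignal.ite import (ITEScore, bin_by_ite, build_family_partition,
                            cai_weights, compute_weights, score_gene,
                            score_genes)


def gene_of(codons, gid="g"):
    return CodingSequence(
        gene_id=gid, species_id="s", codons=codons, stop_codon="TAA",
        plus_four_base="T", downstream="T" * 20, upstream="A" * 20, strand="+")


class TestFamilyPartition:
    def test_six_fold_families_split(self):
        scheme = build_family_partition(split_six_fold=True)
        fams = set(scheme.families)
        assert ("CTA", "CTC", "CTG", "CTT") in fams      # Leu 4-subfamily
        assert ("TTA", "TTG") in fams                    # Leu 2-subfamily
        assert ("TCA", "TCC", "TCG", "TCT") in fams      # Ser 4-subfamily
        assert ("AGC", "AGT") in fams                    # Ser 2-subfamily
        assert ("CGA", "CGC", "CGG", "CGT") in fams      # Arg 4-subfamily
        assert ("AGA", "AGG") in fams

    def test_unsplit_keeps_six_fold(self):
        scheme = build_family_partition(split_six_fold=False)
        leu = next(f for f in scheme.families if "CTT" in f)
        assert len(leu) == 6 and "TTA" in leu

    def test_partition_covers_all_sense_codons_once(self):
        scheme = build_family_partition(True)
        all_codons = [c for fam in scheme.families for c in fam]
        assert len(all_codons) == 61 == len(set(all_codons))


def lys_tables(heg_aaa, heg_aag, leg_aaa, leg_aag):
    heg = CodonUsageTable({"AAA": heg_aaa, "AAG": heg_aag})
    leg = CodonUsageTable({"AAA": leg_aaa, "AAG": leg_aag})
    return heg, leg


class TestComputeWeights:
    def test_closed_form_ratio(self):
        heg, leg = lys_tables(9, 1, 5, 5)
        # fill other families so pseudocount 0 is legal
        for c in heg.counts:
            if heg.counts[c] == 0:
                heg.counts[c] = leg.counts[c] = 1
        wt = compute_weights(heg, leg, pseudocount=0.0)
        assert wt.w["AAA"] == pytest.approx(1.0)
        assert wt.w["AAG"] == pytest.approx((0.1 / 0.5) / (0.9 / 0.5))

    def test_identity_when_heg_equals_leg(self):
        t = CodonUsageTable({c: 7 for c in CodonUsageTable().counts})
        wt = compute_weights(t, t, pseudocount=0.0)
        assert all(v == pytest.approx(1.0) for v in wt.w.values())

    def test_pseudocount_hand_computed(self):
        # Lys family: HEG {AAA: 0, AAG: 10}, LEG {5, 5}, pseudocount 0.5
        heg, leg = lys_tables(0, 10, 5, 5)
        wt = compute_weights(heg, leg, pseudocount=0.5)
        f_h = (0.5 / 11, 10.5 / 11)
        f_l = (5.5 / 11, 5.5 / 11)
        r = (f_h[0] / f_l[0], f_h[1] / f_l[1])
        assert wt.w["AAA"] == pytest.approx(r[0] / r[1])
        assert wt.w["AAG"] == pytest.approx(1.0)

    def test_zero_pseudocount_with_zero_counts_rejected(self):
        heg, leg = lys_tables(0, 10, 5, 5)
        with pytest.raises(ValueError):
            compute_weights(heg, leg, pseudocount=0.0)

    @given(st.integers(2, 9), st.integers(1, 6))
    def test_scale_invariance(self, factor, shift):
        # pseudocount must be 0 for exact scale invariance
        heg = CodonUsageTable({c: (i % 4) + shift
                               for i, c in enumerate(CodonUsageTable().counts)})
        leg = CodonUsageTable({c: ((i * 7) % 5) + 1
                               for i, c in enumerate(CodonUsageTable().counts)})
        w1 = compute_weights(heg, leg, pseudocount=0.0).w
        w2 = compute_weights(heg.scaled(factor), leg.scaled(factor),
                             pseudocount=0.0).w
        assert all(math.isclose(w1[c], w2[c], rel_tol=1e-9) for c in w1)

    @given(st.integers(1, 20))
    def test_monotone_in_heg_count(self, bump):
        heg1, leg = lys_tables(4, 6, 5, 5)
        heg2, _ = lys_tables(4 + bump, 6, 5, 5)
        w1 = compute_weights(heg1, leg).w["AAA"]
        w2 = compute_weights(heg2, leg).w["AAA"]
        assert w2 >= w1 - 1e-12


class TestCaiWeights:
    @staticmethod
    def _fill(counts):
        base = {c: 1 for c in CodonUsageTable().counts}
        base.update(counts)
        return CodonUsageTable(base)

    def test_relative_adaptiveness(self):
        wt = cai_weights(self._fill({"AAA": 9, "AAG": 1}), pseudocount=0.0)
        assert wt.w["AAA"] == pytest.approx(1.0)
        assert wt.w["AAG"] == pytest.approx(1 / 9)

    def test_uniform_family_all_one(self):
        wt = cai_weights(self._fill({c: 4 for c in ("GGT", "GGC", "GGA", "GGG")}),
                         pseudocount=0.0)
        assert all(wt.w[c] == pytest.approx(1.0)
                   for c in ("GGT", "GGC", "GGA", "GGG"))

    def test_unobserved_family_rejected_without_pseudocount(self):
        heg = CodonUsageTable({"AAA": 9})
        with pytest.raises(ValueError):
            cai_weights(heg, pseudocount=0.0)

    def test_rank_agreement_with_ite_on_synthetic(self, small_bundle):
        from scipy.stats import spearmanr

        from termsignal.expression import select_reference_sets
        from termsignal.ingest import filter_genes
        clean = filter_genes(small_bundle.cds_list, nonpseudo_nonhypothetical=True)
        part = select_reference_sets(small_bundle.abundance, clean, k=40)
        index = {c.gene_id: c for c in clean}
        heg = compile_codon_usage([index[g] for g in part.heg_ids])
        leg = compile_codon_usage([index[g] for g in part.leg_ids])
        ite_scores = score_genes(clean, compute_weights(heg, leg))
        cai_scores = score_genes(clean, cai_weights(heg))
        rho = spearmanr([s.ite for s in ite_scores],
                        [s.ite for s in cai_scores]).statistic
        assert rho > 0.9


class TestScoreGene:
    def _uniform_weights(self):
        t = CodonUsageTable({c: 3 for c in CodonUsageTable().counts})
        return compute_weights(t, t, pseudocount=0.0)

    def test_all_weight_one_scores_one(self):
        wt = self._uniform_weights()
        s = score_gene(gene_of(["ATG", "AAA", "CCC", "GGG"]), wt)
        assert s.ite == pytest.approx(1.0)

    def test_geometric_mean_examples(self):
        wt = self._uniform_weights()
        wt.w["AAA"] = 0.5
        s = score_gene(gene_of(["ATG", "AAA", "AAA"]), wt)
        assert s.ite == pytest.approx(0.5)
        wt.w["AAA"] = 1.0
        wt.w["CCC"] = 0.25
        s = score_gene(gene_of(["ATG", "AAA", "CCC"]), wt)
        assert s.ite == pytest.approx(0.5)   # sqrt(1.0 * 0.25)

    def test_start_met_trp_excluded(self):
        wt = self._uniform_weights()
        wt.w["AAA"] = 0.3
        # start AAA is excluded even though it is not ATG; ATG/TGG unscored
        s = score_gene(gene_of(["AAA", "ATG", "TGG", "CCC"]), wt)
        assert s.n_scored_codons == 1
        assert s.ite == pytest.approx(wt.w["CCC"])

    def test_no_scorable_codons_errors(self):
        wt = self._uniform_weights()
        with pytest.raises(ValueError):
            score_gene(gene_of(["ATG", "ATG", "TGG"]), wt)

    def test_concatenation_is_count_weighted_geometric_mean(self):
        wt = self._uniform_weights()
        wt.w["AAA"] = 0.4
        wt.w["CCC"] = 0.9
        g1 = gene_of(["ATG", "AAA", "AAA"], "a")
        g2 = gene_of(["ATG", "CCC"], "b")
        cat = gene_of(["ATG", "AAA", "AAA", "CCC"], "ab")
        s1, s2, sc = (score_gene(g, wt) for g in (g1, g2, cat))
        expected = math.exp((s1.n_scored_codons * math.log(s1.ite)
                             + s2.n_scored_codons * math.log(s2.ite))
                            / (s1.n_scored_codons + s2.n_scored_codons))
        assert sc.ite == pytest.approx(expected)


class TestBinning:
    def test_even_split(self):
        scores = [ITEScore(f"g{i:02d}", (i + 1) / 20, 10) for i in range(20)]
        b = bin_by_ite(scores)
        assert [len(x) for x in b.bins] == [2] * 10
        assert b.bin_mean_ite == sorted(b.bin_mean_ite)

    def test_remainder_goes_to_lowest_bins(self):
        scores = [ITEScore(f"g{i:02d}", (i + 1) / 23, 10) for i in range(23)]
        b = bin_by_ite(scores)
        assert [len(x) for x in b.bins] == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    def test_equal_scores_partition_by_gene_id(self):
        scores = [ITEScore(f"g{i:02d}", 0.5, 10) for i in range(10)]
        b = bin_by_ite(scores)
        assert [x[0] for x in b.bins] == [f"g{i:02d}" for i in range(10)]

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError):
            bin_by_ite([ITEScore("a", 0.5, 3)], n_bins=10)


def test_heg_leg_mean_score_separation(small_bundle):
    """Genes drawn from the HEG profile outscore genes drawn from the LEG one."""
    from termsignal.expression import select_reference_sets
    from termsignal.ingest import filter_genes
    clean = filter_genes(small_bundle.cds_list, nonpseudo_nonhypothetical=True)
    part = select_reference_sets(small_bundle.abundance, clean, k=40)
    index = {c.gene_id: c for c in clean}
    heg = compile_codon_usage([index[g] for g in part.heg_ids])
    leg = compile_codon_usage([index[g] for g in part.leg_ids])
    wt = compute_weights(heg, leg)
    mean_heg = sum(score_gene(index[g], wt).ite for g in part.heg_ids) / 40
    mean_leg = sum(score_gene(index[g], wt).ite for g in part.leg_ids) / 40
    assert mean_heg > mean_leg
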