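# termsignal

Tools for studying the base immediately 3′ of a bacterial stop codon — the
**+4 site** — as part of an extended translation-termination signal.

In bacteria, termination efficiency differs among the three stop codons
(UAA, UAG, UGA) and depends on the +4 base, with +4U associated with low
read-through. If +4U strengthens the stop signal, highly-expressed genes
(HEGs), which are under the strongest selection for translation accuracy,
should prefer +4U over lowly-expressed genes (LEGs) — and the preference
should track the abundance of **near-cognate tRNAs** (nc_tRNAs), whose
Watson–Crick decoded codon differs from a stop codon at exactly one
position and which cause stop-codon misreading. `termsignal` implements
the full comparative pipeline needed to test these predictions on
annotated genomes, and a synthetic-genome generator so every stage is
testable without downloads.

## What it computes

* **Expression proxies.** The Index of Translation Elongation, per gene:
  within each synonymous codon family, `r(c) = f_HEG(c) / f_LEG(c)` and
  `w(c) = r(c) / max r`, where `f` are within-family codon frequencies in
  the HEG (selection) and LEG (mutation-background) reference sets; a
  gene's score is the geometric mean of `w` over its codons
  (start/stop/Met/Trp excluded). CAI (`w = f_HEG / max f_HEG`) is provided
  for cross-validation, along with RSCU tables and an HEG/LEG
  distinctness check.
* **Stop-context statistics.** Per gene set: stop-codon proportions
  P(UAA)/P(UAG)/P(UGA), the 3×4 stop-by-+4-base table and its conditional
  +4 distributions (P_U.UAA etc.), HEG-vs-LEG contrasts, log-linear
  (likelihood-ratio G) tests of stop × +4 dependence, expression-decile
  trends, and a shuffled-5′-window control.
* **nc_tRNA accounting.** Classification of every anticodon against each
  stop codon by single-mismatch position (nc_tRNA1/2/3), copy-number
  abundance fractions (with and without tRNA-Gln), and their regression
  on +4U usage.
* **Phylogenetic correction.** Felsenstein's independent contrasts on
  rooted trees with branch lengths, through-origin contrast regression,
  and batch mode over bootstrap trees.
* **Statistics kernel.** Wilcoxon rank-sum (exact enumeration or
  tie/continuity-corrected normal approximation), Spearman, OLS, and a
  power-curve fit.

## Worked example

The package ships a 19-species table of +4U proportions in the 100
highest- and 100 lowest-scoring genes per stop codon. The cross-species
Wilcoxon battery asks, per stop codon, whether HEGs use +4U more than
LEGs:

```sh
$ termsignal table2
UAA: U=304.0 p=0.00032724 (n=19 vs 19)
UAG: U=220.0 p=0.25383 (n=19 vs 19)
UGA: U=238.5 p=0.092799 (n=19 vs 19)
```

+4U enrichment in HEGs is highly significant for UAA-ending genes and not
for UAG; UGA is marginal. Near-cognate accounting for a toy tRNA pool:

```python
>>> from termsignal.ingest import TRNAGene
>>> from termsignal.nctrna import nc_abundance
>>> pool = [TRNAGene("Glu", "TTC", 2), TRNAGene("Gln", "TTG", 1),
...         TRNAGene("Gly", "GCC", 7)]
>>> nc = nc_abundance(pool, "TAA")
>>> print(f"p_nc1={nc.p_nc1:.2f}  p_nc1_minus_gln={nc.p_nc1_minus_gln:.2f}")
p_nc1=0.30  p_nc1_minus_gln=0.20
```

Glu-TTC decodes GAA and Gln-TTG decodes CAA — both one mismatch from UAA
at position 1 — so 3 of 10 tRNA gene copies are first-position
near-cognates of UAA (2 of 10 after removing tRNA-Gln); Gly-GCC decodes
GGC, which is no neighbour of any stop.

An end-to-end run over synthetic species:

```sh
termsignal simulate --out cohort --n-species 5 --seed 1
termsignal full --species cohort/sp0 --species cohort/sp1 \
    --species cohort/sp2 --species cohort/sp3 --species cohort/sp4 \
    --tree cohort/tree.nwk --traits cohort/traits.tsv --out report
```

writes per-species +4U contrast tables, decile trends, log-linear and
Wilcoxon test results, nc_tRNA regressions, contrast summaries, and a JSON
manifest under `report/`.

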