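# overlapscan

Genome-scale analysis of **unidirectional (serial) gene pairs** in archaea
and bacteria — adjacent genes transcribed in the same direction, whose very
short overlaps (−4 nt, −1 nt) enable translational coupling by
termination–reinitiation (TeRe), and which frequently encode subunits of
heteromeric protein complexes.

The package is aimed at comparative genomicists and molecular biologists who
want to scan annotations for overlap architecture, test the codon-level
feasibility of short overlaps, decompose distance variation across taxa, and
quantify complex-subunit enrichment with proper resampling statistics.

## What it computes

Working in an internal coordinate format (every coding region is
`(start, stop, strand)` with `start < stop`; on the forward strand `start`
is the first base of the start codon, on the reverse strand it is the last
base of the stop codon), the library provides:

* **Pair extraction and classification** — cleanup (drop stable-RNA genes,
  gene-internal transposases, truncated termini), adjacent-pair extraction
  per replicon, orientation classes (serial / convergent → ← / divergent ← →),
  and the intergenic distance

  `k = second.start − first.stop − 1`

  (negative = overlap; the ATGA boundary motif gives −4, TAATG gives −1),
  with the reading-frame phase `p = k mod 3` computed by the piecewise
  formula `p = k − 3⌊k/3⌋` (k ≥ 0), `p = k + 3⌈−k/3⌉` (k < 0).
* **Overlap feasibility** — for overlaps of 1–5 nt the downstream start
  codon and upstream stop codon share bases; `overlap_feasibility(k)`
  enumerates all compatible joint boundary motifs (e.g. {ATGA, GTGA, TTGA}
  at −4) and proves −2, −3 and −5 impossible with canonical codons.
* **Distance distributions** — per-nt histograms, phase-split histograms and
  window fractions (the −8..+6 nt window marks efficient TeRe).
* **Two-factor distance decomposition** — `d_k[i,j] = C_i + P_j + e_k` with
  COG-pair effects `C`, phylum effects `P` (reference phylum pinned to 0),
  fitted by alternating least-squares minimization of `Σe_k²`; yields
  taxonomically adjusted distances and per-COG-pair summaries.
* **Complex enrichment** — shared-gene-name-stem heuristic (xyzA/xyzB),
  short (−8..+10 nt) vs long (> +20 nt) distance bins, 2×2 contingency
  table, enrichment ratio, Pearson χ² (df=1, no continuity correction), and
  a double-resampling bootstrap (COG pairs kept with probability
  1 − e⁻¹ ≈ 0.63, then gene pairs redrawn with replacement) summarized by
  `z = mean(log ratio) / sd(log ratio)` with a one-sided normal p-value.
* **Reporter efficiencies** — (activity − control) / transcript level,
  normalized to wildtype, for double-reporter coupling experiments.
* **Synthetic data** — a genome-annotation simulator with a configurable
  distance mixture and codon-consistent boundary sequences, and a
  multi-phylum observation generator with known ground truth, so every
  pipeline stage is testable without external data.

## Worked example

```python
from overlapscan import ContingencyTable2x2, chi_square_test, enrichment_ratio

table = ContingencyTable2x2(a=253, b=307, c=51, d=859)  # curated counts
print(f"{100 * table.short_fraction:.1f}% vs {100 * table.long_fraction:.1f}%")
print(f"{enrichment_ratio(table):.1f}-fold, p = {chi_square_test(table)[1]:.0e}")
```

prints

```
45.2% vs 5.6%
8.1-fold, p = 6e-74
```

i.e. among curated gene pairs 45.2% of the tightly spaced ones (−8..+10 nt)
encode heteromeric-complex subunits versus 5.6% of the widely spaced ones
(> +20 nt) — an 8.1-fold, overwhelmingly significant enrichment.

The `examples/` directory holds one narrative script per capability
(`genome_scan.py`, `overlap_motifs.py`, `factor_decomposition.py`,
`complex_enrichment_analysis.py`, `reporter_efficiency_table.py`); each
builds or simulates a small input, runs the method and explains the printed
numbers. A thin CLI mirrors the library:

```bash
overlapscan feasible --k -5 --ext-starts ATT
overlapscan simulate genome --seed 5 --out-prefix sim
overlapscan hist --pairs sim.pairs.tsv --lo -20 --hi 200
overlapscan enrich --pairs sim.pairs.tsv --use-name-heuristic --bootstrap 1000
```

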