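# sigconcord

Concordance analysis of gene-expression signatures, built around the kind of
question that arises when a tumor's molecular subtypes, a cell-state program
(such as the epithelial-to-mesenchymal transition, EMT), and a
marker-sorted cell population (such as CD133+/− fractions) each come with
their own up/down gene signature: which of these signatures agree, which
oppose each other, and can a subtype's disagreement with one program be
explained by its agreement with an opposing one?

The package provides, as a library plus a `sigconcord` command line:

* **Fold-change signature derivation** from log2 expression matrices: a gene
  is up-regulated when mean(group) − mean(reference) ≥ τ on the log2 scale
  (τ = 1 is a two-fold change), with group-vs-reference, subtype-vs-rest,
  and paired (per-sample, with an "at least *m* of *n* pairs" consensus)
  variants.
* **Background-harmonized two-sided Fisher exact testing** (TSFET) of
  list overlaps.  Lists A and B are restricted to the background N = genes
  measured in *all* datasets; the observed overlap *a* is compared with the
  expected overlap E = n_A·n_B/N, and the two-sided p-value sums all
  hypergeometric outcomes no more probable than the observed one, so both
  enrichment (a > E) and depletion (a < E) are detected.
* **Consensus k-means subtype discovery**: MAD filtering, row
  standardization, resampled k-means, a consensus-matrix *quality factor*
  QF = mean 2·|m_ij − ½| ∈ [0, 1], and selection of the number of clusters
  at the largest QF drop.
* **Correlation profiling** of per-sample fold-change vectors against
  inducer programs, with per-subtype and per-inducer averages.
* **Three-way reconciliation**: discordant sets between two signatures
  (e.g. genes down in EMT but up in the mesenchymal subtype) tested against
  the matching side of a third signature on the triple-harmonized
  background.
* A **synthetic-study generator** that plants all of the above structure —
  subtypes with markers, inducers sharing a core program, sorted pairs
  whose signature opposes the core — with full ground truth, so the entire
  pipeline is testable without external downloads.

## Worked example

Reproduce a published-style overlap row from its summary counts alone —
78 core-EMT up genes vs. 1386 tumor up genes, overlap 34, background 11296:

```python
>>> from sigconcord import tsfet_counts
>>> r = tsfet_counts(overlap=34, n_a=78, n_b=1386, n_background=11296)
>>> round(r.expected, 2), float(f"{r.p_value:.3g}"), r.direction
(9.57, 4.53e-12, 'enriched')
```

The overlap of 34 genes is 3.6× the 9.57 expected by chance; the two-sided
p-value 4.53×10⁻¹² marks a strongly enriched overlap.

Run the whole pipeline on a synthetic study:

```bash
sigconcord run-all --seed 1 --out report/
```

which simulates the default study (5000 genes; 4 subtypes × 30 samples vs.
10 normals; 5 inducers; 4 sorted pairs), derives all signatures, writes the
overlap tables, the consensus-clustering quality-factor curve and labels,
the correlation grid, and the reconciliation report.  On this study the
quality factor climbs to 1.0 at k = 4 and drops sharply at k = 5, the
planted subtypes are recovered exactly, and all four reconciliation tests
come out enriched.

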