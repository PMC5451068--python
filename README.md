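# lncprior

Identification and prioritization of candidate disorder-associated long
non-coding RNAs (lncRNAs) by integrating case/control differential
expression, multi-tissue selectivity, and a developmental brain
co-expression network — the guilt-by-association strategy used to nominate
lncRNA risk genes for neurodevelopmental disorders such as autism spectrum
disorder (ASD).

lncRNAs are transcripts > 200 nt with no protein product. They are largely
uncharacterized, so direct evidence rarely exists; instead, a lncRNA is
prioritized when several independent lines of evidence converge:

1. **Differential expression** in affected cortex (negative-binomial Wald
   test; significant at BH-adjusted p < 0.05 and |log₂FC| ≥ 1).
2. **Brain selectivity**: fractional brain expression
   `100 · Σ_brain x / Σ_all x > 50%` across a multi-tissue panel (tissues
   with < 50 donors removed).
3. **Co-expression with known risk genes** in a signed weighted network
   built from non-affected developmental cortex: biweight midcorrelation
   `c_ij`, soft-thresholded adjacency `a_ij = ((1 + c_ij)/2)^β` with β = 12,
   topological overlap TOM, average-linkage clustering of `1 − TOM`, and a
   dynamic height cut into modules summarized by eigengenes (first PC).
4. **Statistical validation**: permutation nulls (B = 10,000 random
   same-size gene sets) for module co-expression, for the mean differential
   log₂FC overlaid per module, and for the summed lncRNA-to-risk-gene
   correlation; one-sided Fisher exact enrichment of risk-gene sets per
   module (enriched ⇔ adjusted p < 0.05 and odds ratio > 1).
5. **CNV burden**: counts of copy-number-variant intervals overlapping each
   gene (half-open coordinates, any shared base).

The final table ranks DE lncRNAs module-first (risk-gene-enriched modules,
then lncRNA-enriched modules), by descending CNV overlaps within a module.

Because the original external datasets (case/control cortex counts,
developmental transcriptome, tissue medians, curated risk-gene and CNV
lists) cannot be redistributed, the package ships a first-class synthetic
data generator that emulates all of their shapes with *planted* structure —
known DE genes, known modules jointly containing risk genes and lncRNAs,
known brain-selective and CNV-hit lncRNAs — so every stage is testable
against ground truth.

## Worked example

```bash
printf 'n_permutations: 2000\n' > cfg.yaml
lncprior run-all --config cfg.yaml --outdir demo --seed 1
```

runs the full pipeline on the default synthetic fixture (1,000 genes, 150
lncRNAs, 3 cases vs 3 controls with two technical replicates each, four
planted developmental modules, 40 tissues, 120 CNVs) and prints the top of
the priority table:

```
lncrna_id     module   module_tier  cnv_overlaps  log2fc_asd  fractional_brain_expression top_corr_gene  top_corr_r  top_corr_gene_risk_score  final_rank
   G00712  turquoise risk_enriched             3   -2.011358                    74.134239        G00633    0.749953                       NaN           1
   G00268  turquoise risk_enriched             3   -2.008004                    78.994618        G00943    0.766073                       2.0           2
   G00706  turquoise risk_enriched             3   -1.790242                    78.177413        G00807    0.732589                       NaN           3
```

Reading row 1: lncRNA `G00712` is down-regulated in cases (log₂FC ≈ −2),
brain-selective (74% of its expression in brain tissues), sits in the
`turquoise` module — which is enriched for the risk-gene set — is hit by 3
CNVs, and its most co-expressed protein-coding gene is `G00633`
(bicor ≈ 0.75). These are exactly the three lncRNAs the generator planted
with full evidence (DE + risk-module co-membership + CNV hits), recovered
at ranks 1–3. `demo/` holds every intermediate table (`de.tsv`,
`specificity.tsv`, `modules.tsv`, `eigengenes.tsv`, permutation and
enrichment tables, `cnv_overlaps.tsv`, `priority.tsv`) plus a
`manifest.json` with content hashes for reproducibility.

Each stage is also available standalone: `lncprior simulate|de|tissue|
network|permute|enrich|overlaps` with `--help` for options.

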