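# mitocub

Codon-usage-bias analysis of mitochondrial genomes, built for AT-rich
invertebrate mitogenomes such as those of mygalomorph spiders (tarantulas
and their relatives). Starting from annotated GenBank records, the package
extracts the 13 protein-coding genes under the invertebrate mitochondrial
genetic code (translation table 5), and computes the classical diagnostics
used to separate mutation pressure from natural selection in shaping
synonymous codon choice:

* **RSCU** — relative synonymous codon usage,
  `RSCU(c) = count(c) · n(F) / N(F)` for codon *c* in a synonymous family
  *F* of size *n(F)* with total count *N(F)*; codons are classed as
  strongly preferred (RSCU > 1.6), neutral (0.6 ≤ RSCU ≤ 1.6) or rarely
  used (RSCU < 0.6). Stop codons and Met/Trp are excluded.
* **ENC** — Wright's effective number of codons from per-family codon
  homozygosity `F̂ = (n·Σp² − 1)/(n − 1)` pooled by degeneracy class
  (`ENC = 2 + 10/F̂₂ + 6/F̂₄ + 1/F̂₆ + 1/F̂₈` under table 5, where Leu is the
  6-fold and Ser the 8-fold family), with the mutation-drift expectation
  `ENC_exp = 2 + GC3s + 29/[GC3s² + (1 − GC3s)²]` and the deviation index
  `ENC ratio = (ENC_obs − ENC_exp)/(61 − ENC_exp)`.
* **Neutrality regression** — OLS of GC12 on GC3 across a species' genes;
  slope ≈ 1 indicates mutation-pressure dominance, slope ≈ 0 selection
  constraint, judged by the slope's 95% confidence interval.
* **PR2 parity coordinates** — `A3/(A3+T3)` versus `G3/(G3+C3)` at third
  positions of fourfold-degenerate families; (0.5, 0.5) is the
  no-asymmetry point.
* **Cross-species summaries** — moment statistics (mean, sd, CV, skewness,
  excess kurtosis), aligned RSCU matrices, and complete-linkage Euclidean
  clustering for heatmap row ordering (emitted as Newick text).

Because complete mitogenomes must normally be fetched from NCBI, the
package also ships a **synthetic mitogenome generator**
(`mitocub.simulate`) that writes GenBank-format circular genomes with 13
CDS on both strands, atypical start codons (ATT/ATA/TTG), incomplete stop
codons (trailing T or TA) and a tunable third-position GC bias θ whose
implied RSCU and GC3s are known in closed form — so the entire pipeline is
testable offline, including parameter recovery.

## Worked example

Generate three synthetic mitogenomes and run the full analysis:

```
$ mitocub simulate -o genomes --n-species 3 --seed 7
$ mitocub all -o results genomes/*.gb
```

`results/gene_inventory.tsv` lists each extracted gene with strand, start
codon and stop type — note the incomplete stop on `cox2`, reconstructed
from a CDS ending in a bare `T`:

```
species	gene	strand	n_codons	start_codon	stop_note
Synthospila speciesA	cox1	+	512	ATT	complete_TAA
Synthospila speciesA	cox2	+	227	ATG	incomplete_T
Synthospila speciesA	atp8	+	52	ATT	complete_TAA
```

`results/neutrality.tsv` holds one GC12~GC3 regression per species; here
species A's slope is indistinguishable from 0 (its CI excludes 1), the
signature of selection decoupling synonymous from non-synonymous sites:

```
species	n_genes	slope	intercept	R2	p_value	ci_low	ci_high	pearson_r	verdict
Synthospila speciesA	13	-0.0628	0.3699	0.0088	0.7605	-0.5050	0.3794	-0.0938	selection-constrained
Synthospila speciesB	13	0.6763	0.1603	0.2213	0.1047	-0.1656	1.5182	0.4704	neutral-compatible
Synthospila speciesC	13	0.3070	0.2363	0.2097	0.1156	-0.0885	0.7024	0.4580	selection-constrained
```

`results/summary_stats.tsv` gives the cohort-level distributions (39 genes
= 13 × 3 species): a mean ENC of 50.3 ± 7.7 with GC3s centred near 0.30,
matching the generator's configured third-position biases:

```
variable	n	mean	sd	cv	min	max	median	skewness	kurtosis
ENC	39	50.3326	7.69523	0.152888	34.7651	61	51.2081	-0.270016	-1.04061
GC3s	39	0.297038	0.108264	0.364479	0.097561	0.5	0.30625	0.00777567	-1.03178
```

The remaining outputs are `enc.tsv` (per-gene ENC, expected ENC and ENC
ratio — plot-ready for an ENC–GC3s figure), `pr2.tsv`, `composition.tsv`,
`rscu_per_gene.tsv`, `rscu_per_species.tsv`, `rscu_matrix.csv`,
`rscu_cluster.nwk`, and `manifest.json` recording config, input checksums
and warnings. Re-running the same command reproduces every file
byte-identically.

The same works on real records: point `mitocub all` at GenBank flat files
of complete annotated mitogenomes.

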