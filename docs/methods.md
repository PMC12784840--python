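# Methods

## Scope and data model

The package analyzes synonymous codon usage in annotated mitochondrial
genomes. The unit of ingestion is a single-record GenBank flat file; the
unit of analysis is the protein-coding gene (PCG), represented as an
ordered codon list on the sense strand with the stop codon removed. The
annotation is trusted: CDS coordinates, strands and `codon_start`
qualifiers are taken as given and no re-annotation is attempted.
Coordinates stay 1-based inclusive at the file boundary and are converted
to 0-based half-open arithmetic internally.

Extraction rules:

* minus-strand CDS are reverse-complemented to sense orientation;
* a trailing TAA/TAG is trimmed and recorded as a complete stop; a frame
  remainder of one trailing `T` or two trailing `TA` is trimmed and
  recorded as an incomplete stop (completed to TAA by polyadenylation in
  vivo, treated as a full stop here);
* after trimming, length must be a multiple of three and no internal stop
  may occur under translation table 5 — violations raise named errors;
* start codons are kept in the codon counts and translated by the table
  (they are not forced to Met), since atypical starts (ATT/ATA/TTG) are a
  genuine feature of these genomes;
* genes containing ambiguity codes are dropped from statistics with a
  logged warning rather than guessed;
* gene labels are normalized through a fixed synonym table
  (COI/COX1→cox1, ND4L→nad4L, COB/CYTB→cytb, …) because submitter
  labelling varies.

## Genetic code conventions

Translation table 5 (invertebrate mitochondrial) is used throughout:
AGA/AGG→Ser, ATA→Met, TGA→Trp, stops {TAA, TAG}. The derived family
structure for synonymous-site statistics: Ile is 2-fold (ATT/ATC), Ser is
one 8-fold family (TCN + AGN), Leu 6-fold, Arg the 4-fold CGN family.
Met and Trp each have two codons under this table but are excluded from
every synonymous-site statistic (RSCU, GC3s, A3s/T3s/G3s/C3s, ENC
families), following the near-universal convention of mitochondrial
codon-bias studies; their codons still count toward GC1/GC2/GC3 and
codon totals. This leaves 58 analyzed codons (64 − 2 stops − 4 Met/Trp
codons), which fixes the column set of the RSCU matrix.

## RSCU

`RSCU(c) = count(c) · n(F) / N(F)`. Species-level profiles pool all PCGs
of a species (the reporting unit used for cross-species comparisons);
gene-level profiles are also available. A family with zero observations
yields *missing* (never 0): an unused codon in a present family is
RSCU = 0, a codon of an absent family carries no information. Preference
classes: preferred above 1.6, rare below 0.6, neutral in the closed
interval between — the boundary values themselves are neutral.

## ENC

Per amino acid with n ≥ 2 observed codons, homozygosity
`F̂ = (n·Σp² − 1)/(n − 1)`; class means over the degeneracy classes
(N₂ = 10, N₄ = 6, N₆ = 1 for Leu, N₈ = 1 for Ser);
`ENC = 2 + Σ N_k/F̂_k`, the leading 2 counting Met and Trp.

Numerical choices:

* amino acids with n < 2 are omitted from their class mean (the estimator
  divides by n − 1);
* F̂ = 0 (a perfectly even, tiny family — e.g. four fourfold codons seen
  once each) is likewise treated as missing, since N/F̂ diverges;
* a class with no computable F̂ is imputed with the mean of the available
  class means — a deterministic, documented rule; the result records which
  classes were imputed;
* ENC is clipped to a ceiling of 61.00 (the conventional maximum and the
  denominator anchor of the ENC ratio), with a switch to disable clipping.

The expected-ENC curve is `2 + s + 29/(s² + (1 − s)²)` for s = GC3s
(60.5 at s = 0.5, 31 at s = 0, 32 at s = 1), and
`ENC ratio = (ENC_obs − ENC_exp)/(61 − ENC_exp)`, undefined when
ENC_exp = 61 (signalled, not silently returned).

## Neutrality regression

Per species, ordinary least squares of GC12 on GC3 over its genes
(≥ 3 required; zero GC3 variance is a signalled degenerate fit). Reported:
slope, intercept, R², two-sided t-test p for slope ≠ 0, 95% CI via the t
distribution with n − 2 df, and Pearson r (R² = r² for the simple
regression). The verdict compares the CI with the neutral slope of 1:
containing 1 → neutral-compatible; entirely below → selection-constrained;
entirely above → positive/relaxed. No multiple-testing correction is
applied across species; per-species p-values are reported raw.

## PR2

Per gene, `A3/(A3+T3)` and `G3/(G3+C3)` over third positions of the
fourfold-degenerate families only (Val, Pro, Thr, Ala, Gly, Arg), where
parity rule 2 applies without interference from amino-acid composition;
a switch widens this to all synonymous third positions for sensitivity
analysis. Zero denominators flag the coordinate as undefined and exclude
the gene from species means. Both coordinates are emitted; axis
assignment is left to the plotting layer.

## Summaries and clustering

Descriptive statistics use the population-moment shape definitions
(g1 = m3/m2^{3/2}, excess g2 = m4/m2² − 3) and the sample (n − 1)
standard deviation — the simplest documented choice for "mean ± sd"
style reporting. The RSCU matrix aligns profiles over the 58 analyzed
codons (grouped by amino acid, lexicographic within family); missing
cells are imputed as 0 for clustering only, never in statistics.
Clustering is agglomerative complete linkage under Euclidean distance
(monotone merge heights), with rows pre-sorted by label so ties break
deterministically; the tree is exported as Newick for heatmap row
ordering. Clustering can run over species (default) or codons
(transpose).

## Synthetic mitogenomes

The generator emulates the properties of AT-rich invertebrate
mitogenomes that the pipeline depends on, not their biology in full. One
circular record carries 13 CDS with realistic lengths (52–551 codons),
mixed strands (nad1/nad4/nad4L/nad5 on the minus strand), table-5
qualifiers, atypical starts, incomplete stops on cox2 (T) and nad4 (TA),
and random A/T intergenic spacers. The GenBank writer emits the minimal
legal dialect (LOCUS/FEATURES/ORIGIN, 60-base lines); round-tripping
through the parser is its contract, not full format fidelity.

Codons are sampled i.i.d.: amino acid from a composition vector, codon
within family with weight θ for G/C-ending and 1 − θ for A/T-ending
codons. Defaults: an AT-rich composition with elevated Leu/Ile/Phe/Ser/Met
(the profile typical of arthropod mitochondrial proteomes), and θ = 0.265,
placing synthetic GC3s in the band observed for mygalomorph mitogenomes.
Because every table-5 family contains equally many G/C- and A/T-ending
codons, the implied GC3s equals θ exactly and the implied RSCU is
n(F)·w(c|F) — closed forms used as ground truth in recovery tests.
A seven-species default cohort spans θ = 0.18…0.42. Explicit per-family
weight vectors override θ when exact usage patterns are needed.

Two scenario samplers support neutrality-plot validation: a pure
mutation-pressure model (codons i.i.d. over all 62 sense codons with the
same GC weight at all three positions) yields regression slopes near 1;
varying θ alone with a fixed amino-acid composition leaves GC12 flat in
expectation (every table-5 family's first/second-position GC is
θ-independent under the weight rule) and yields slopes near 0.

What the generator does **not** emulate: codon autocorrelation along
genes, strand-asymmetric mutation (its PR2 clouds centre on (0.5, 0.5)
rather than the G-over-C / T-over-A bias of real mitogenomes), tRNA/rRNA
content, gene overlap, and among-site rate variation. Tests passing on
synthetic data therefore demonstrate correctness of the estimators and
the ingestion contract, not biological realism of any particular value.

## Statistical test design

Stochastic checks fix their seeds. Two tolerance choices deserve note:

* The uniform-usage RSCU recovery check uses one species of 13 genes of
  10,000 codons each with composition proportional to family size; at
  that depth the 0.15 error band is an ≈ 8σ statement. For a single
  10,000-codon gene the same band is only ≈ 2.3σ — a coin-flip per seed —
  so the species-pooled design is what makes the test informative about
  the estimator.
* The RSCU-convergence check at 20,000 codons per species bounds each
  codon's error at max(0.1, 4 binomial SE): under a realistic composition
  the rarest amino acids (Arg ≈ 2%, Cys ≈ 1%) receive only a few hundred
  codons, where 0.1 is below one standard error of a single RSCU value.

Regression CI calibration is checked by simulation (1000 replicates per
true slope in {0, 0.5, 1}, 13 genes each, Gaussian noise), requiring
93–97% coverage — a ±3σ binomial band around the nominal 95%.

## Problem sizes

The default test suite and the acceptance script run entirely on
synthetic data: cohorts of 3–7 species × 13 genes (≈ 3,600 codons per
species) for pipeline checks, single genes of 10,000–20,000 codons for
estimator-convergence checks, and 3,000 regressions for CI calibration.
The full suite completes in a few seconds on one CPU.

## Known limitations

* ENC degeneracy layout follows table 5; published values computed with
  standard-code tools (Ile 3-fold, Ser 6-fold + AGY 2-fold, Arg 6-fold)
  can differ by up to ~1 ENC unit for short genes.
* The reference-genome checks require the real GenBank records on disk;
  the repository ships only the fetch helper, not the records.
* Chi-square tests of categorical codon-class comparisons, codon
  adaptation indices, tRNA-abundance weighting and any figure rendering
  are out of scope; outputs are plot-ready tables.
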