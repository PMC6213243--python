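# Methods

This note records the statistical definitions cubkit implements, the
choices made where conventions genuinely diverge, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Codon counting and the genetic code

The standard genetic code is used throughout (the plastid code is the
standard code), represented in the RNA alphabet; DNA input is converted on
ingestion. Counting covers every in-frame codon including the terminal
stop. Codons containing an ambiguous base (N or another IUPAC letter) are
excluded per codon rather than failing the gene, so draft annotations stay
usable; exclusions are counted. A CDS whose length is not a multiple of
three is a hard error at ingestion (GenBank CDS with that property are
routed to a rejection log instead of aborting the genome). Internal stop
codons are flagged, not fatal: the protein-level indices average over
residues and a single misannotated stop should not void a gene.

## Composition statistics

* GC_cds is the GC fraction over every base of every counted codon.
* P1 and P2 exclude only the single-codon families AUG (Met) and UGG
  (Trp), whose usage carries no synonymous information.
* P3 additionally excludes the three stop codons and the three isoleucine
  codons, whose third position does not follow the regular 2-/4-fold
  substitution pattern. A configuration switch (`exclude_all_positions`)
  extends the stop/Ile exclusion to P1/P2 for users who prefer a single
  universe; the default keeps the asymmetric convention because P1/P2 are
  meant to reflect the whole protein-coding signal.
* P12 = (P1+P2)/2 exactly.
* PR2 biases G3/(G3+C3) and A3/(A3+U3) are computed over the same
  third-position universe as P3, since they are functions of the same
  A3/U3/G3/C3 quantities. (A variant restricted to 4-fold families exists
  in the literature; it is intentionally not the default because the
  composition module defines one third-position universe.)
* Any statistic whose denominator is empty is reported as missing
  (`None` in the API, `.` in TSV reports) — never as 0.

Fractions are kept in [0, 1]; rendering as percentages is left to
presentation code.

## Indices

**RSCU.** count(c) / (family total / family size). Families with zero
total are flagged undefined rather than given a value. The stop family is
included as an ordinary 3-codon family so pooled tables can report it.

**ENc.** Wright's estimator. Per-family homozygosity
F̂ = (n·Σp̂² − 1)/(n − 1) for families with n ≥ 2; families with F̂ ≤ 0 are
treated as uninformative and skipped. Class averages over the nine 2-fold,
one 3-fold (Ile), five 4-fold and three 6-fold families (Leu, Ser, Arg
counted as single 6-fold families) combine as
ENc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6. A missing Ile average is imputed
as (F̄2 + F̄4)/2, the standard fallback for short genes; any other missing
class makes ENc undefined. The value is capped at 61; values below 20 are
impossible under the estimator, so no floor is applied. Because F̂ carries
an O(1/n) finite-sample term, ENc is scale-invariant only in the large-n
limit; the suite checks invariance at family counts in the thousands.

**CAI.** Relative adaptiveness w(c) = RSCU(c)/max RSCU within the family,
computed from a reference count table; codons absent from the reference
get a floor of 0.01 (configurable) so one missing codon does not zero the
geometric mean of every gene using it. Met, Trp and stop codons carry no
w. A gene's CAI is the count-weighted geometric mean of w over its
scorable codons; genes with none are reported missing. The reference may
be a single gene (the pipeline default looks for *psbA* by id or product),
a pooled set, or a w table loaded from a two-column TSV.

**GC3s** uses the synonymous universe: all sense codons of multi-codon
families — Ile included, which distinguishes it from P3.

**Gravy** is the mean Kyte–Doolittle hydropathy (table taken from
Biopython); **Aromo** the fraction of Phe/Tyr/Trp residues.

## Gene filtering and classification

CDS shorter than 300 nt are excluded by default (inclusive boundary: a
300 nt CDS is retained); threshold configurable. Functional categories
(Photo / Genet / Other) are assigned by ordered, case-insensitive
substring rules over the `product` annotation, first match wins,
no match → Unassigned. The shipped vocabulary covers the standard
chloroplast product names (photosystems, NADH-plastoquinone
oxidoreductase, ATP synthase, cytochrome complexes, RuBisCO, Ycf3/Ycf4,
acetyl-CoA carboxylase → Photo; ribosomal proteins, RNA polymerase,
maturase → Genet; hypothetical RF1/RF2, Ycf1/Ycf2, envelope membrane
protein, Clp protease → Other) and can be replaced from a TSV. Keyword
matching on free text is inherently annotation-dependent; category-level
results should be read with the annotation source in mind.

## Codon catalogs

Preferred: RSCU > 1 (strict). Rare: RSCU < 0.1 (strict; unused codons of
populated families, RSCU = 0, are rare). Optimal codons: genes ranked by
CAI; upper and lower tails of ceil(fraction·N) genes each (default 5%,
minimum one, ties broken by gene id); usage pooled per tail as counts. For
each sense codon of a multi-codon family present in both tails, a 2×2
Pearson chi-squared test without continuity correction (df = 1) on
[codon, rest of family] × [high, low]. A call requires higher relative
usage in the high tail (directionality) and p below the tier threshold
(0.01 strong, 0.05 moderate). Expected cell counts below 5 set a
small-sample flag rather than switching tests automatically. No
multiple-testing correction is applied by default — the per-codon calls
mirror long-standing practice in this literature — and the chi-squared is
computed closed-form to remain defined when a codon is absent from both
tails. Requiring RSCU > 1 in the high tail is available as an option, off
by default.

## Trend analyses

The neutrality plot regresses P12 on P3 by ordinary least squares across
genes and reports the slope, "relative neutrality" = slope × 100 (the
standard reading: the fraction of third-position compositional drift that
carries through to all positions), plus the Spearman rank correlation with
a two-sided p. Degenerate inputs (fewer than three genes, or zero P3
variance) yield missing values. The ENc–GC3s expectation is the closed
form 2 + GC3s + 29/[GC3s² + (1−GC3s)²], evaluated with a warning at the
endpoints where it is formally finite but meaningless; per-gene deviation
is (expected − observed)/expected. Correlation matrices are Spearman by
default with Pearson as an option.

## Correspondence analysis

Classical CA of the gene × codon RSCU matrix (the informative universe:
61 sense codons minus AUG and UGG = 59 columns; 59 − 18 multi-codon
families = 41 degrees of freedom). Codons of families absent from a gene
are filled with 0. The correspondence matrix is centred by the outer
product of row and column masses, standardised by the chi-square metric
and factored by SVD; row and column principal coordinates are returned
for min(4, rank) axes and the inertia spectrum for all positive axes
(fractions sum to 1). Zero-mass columns (codons unused everywhere) carry
no inertia and score 0. SVD signs are arbitrary, so axes are oriented
deterministically: non-negative Spearman correlation with a caller-given
covariate (the pipeline passes GC3s), falling back to a positive first
nonzero column score. A raw-count CA is available by passing counts
instead of RSCU. The implementation is cross-checked in the test suite
against scikit-bio's independent CA.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
not chloroplast biology: no phylogeny, no gene order, no RNA editing, no
inverted repeats, and amino-acid composition is a free parameter rather
than a protein-structure consequence. Passing tests therefore demonstrate
that each method recovers the structure it targets under its own model
assumptions — not that real plastid data satisfy those assumptions.

Defaults mirror the scale of one plastid coding complement: 57 genes of
430 codons, categories assigned from the chloroplast product vocabulary
at roughly 31/21/5 (Photo/Genet/Other). Three regimes:

* **mixed** — amino acids drawn from a weight vector; within each family,
  codon probability ∝ (gc3_pressure if the third base is G/C else
  1 − gc3_pressure) × (1 + selection_strength × expression) for designated
  preferred codons × purine3_skew for A/G-ending codons. Start AUG and a
  stop are appended. The default amino-acid weights are PR2-balanced:
  because six 2-fold families end in U/C but only three in A/G, uniform
  weights would park the unbiased PR2 point near (0.42, 0.42); upweighting
  Gln/Lys/Glu by 17/9 (derived analytically from the family structure)
  zeroes the aggregate third-base imbalance so that PR2 departures in
  simulated data reflect requested skew or selection only.
* **mutation** — bases drawn directly, GC probability q3 per gene at the
  third position (uniform over gc3_range) and q12 = 0.20 + 0.50·q3 +
  N(0, 0.02) at positions 1+2; stop codons rejected. Mutational pressure
  thereby couples all positions and the neutrality regression should
  recover the generating slope 0.50.
* **selection** — q12 drawn independently in the narrow band (0.38, 0.52)
  that protein-level conservation allows (matching per-gene P12 spreads
  around 0.04 seen in plastid data), while the third position tracks
  expression-linked selection, q3 = gc3_pressure + 0.3·(expression − ½),
  independent of q12. The neutrality slope is then ≈ 0 with a small
  standard error. (A literal "third position held constant" design was
  rejected: with P3 variance reduced to binomial noise the OLS slope
  estimate is dominated by sampling error and near-zero slopes cannot be
  demonstrated at any reasonable gene count.)

Determinism: each gene's random stream is spawned from the dataset seed
and the gene index, so the same seed reproduces the dataset byte for byte
and any prefix of it. Expression levels are a shuffled uniform grid on
[0, 1] by default (lognormal optional, scaled to [0, 1]).

Residual coupling: in the selection regime the q12 draws and the
expression levels come from independent streams, so their sample
correlation is O(1/√n); at a few hundred genes this can produce transient
neutrality slopes of several percent for particular seeds. The property
tests use 500 genes, where the effect is within the stated ±5% band.

## Problem sizes and tolerances

Simulation-based tests use 200–500 genes of 300 codons (seconds each);
the PR2 concentration check pools ≈ 10^5 codons. Tolerances: ±0.05 on the
recovered neutrality slope, ±0.03 on PR2 coordinates, ±0.1 on pooled RSCU
under even usage, 90% sensitivity/precision for optimal-codon recovery at
odds-doubling selection — all at fixed seeds chosen in advance. Numerical
tie-breaks: CAI tails order by (CAI, gene id); CA axis orientation as
above; singular values below max-dimension × machine-epsilon × σ₁ are
treated as zero rank.

## Limitations

* Classification quality is bounded by annotation free text.
* The optimal-codon test is asymptotic; small tails trigger a flag, not
  an exact test.
* ENc is undefined for genes missing a whole degeneracy class (beyond the
  Ile imputation); very short genes therefore report missing rather than
  a guessed value.
* The CAI reference floor (0.01) is a convention; CAI values for genes
  rich in reference-absent codons depend on it.
* GenBank ingestion trusts the annotation: duplicated inverted-repeat CDS
  are kept as separate records and pseudo-genes are not detected.
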