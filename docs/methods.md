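# Methods

## Scope and data model

The package analyses a set of candidate coding sequences (one nucleotide CDS
per gene, standard nuclear genetic code) together with optional per-gene
expression values (FPKM-like) and category labels. It does not predict ORFs,
align reads or assemble transcripts: screening starts from extracted CDS.
Internally all sequences are DNA-alphabet (U normalized to T); RNA spelling
appears only in output tables.

## Screening

Rules are applied in a fixed order — minimum length (default 300 bp, the
conventional cutoff below which index estimates are noise-dominated),
multiple-of-3, no non-ACGT character, no internal stop, ATG start (on by
default), terminal stop (off by default) — and the first failure is the
recorded rejection reason, so the screen is deterministic and auditable.
Any non-ACGT character counts as ambiguity; there is no attempt to interpret
IUPAC codes, since a single ambiguous base already corrupts codon counts.

## Usage indices

*GC by position.* GC1/GC2/GC3 are computed over all sense codons; GC3s
restricts the third position to the 59 synonymous codons, excluding the
invariant third positions of ATG and TGG. Both are always reported: GC3
matches how composition plots are usually drawn, GC3s is the argument of the
expected-ENC curve (which models synonymous positions only).

*ENC.* Wright's estimator with these conventions for sparse genes: families
with ≤ 1 observed codon are excluded from their degeneracy-class average;
a family F of exactly 0 (possible at tiny counts) is likewise excluded; a
missing three-fold class (isoleucine unobserved) is imputed as the mean of
the two- and four-fold class averages; if any other class average is still
undefined the gene's ENC is missing rather than guessed. The reported value
is clamped to the theoretical range [20, 61]; the raw value is kept in a
diagnostic column (`enc_raw`) because finite uniform counts legitimately
produce raw values above 61 (F underestimates 1/k at finite n).

*RSCU.* A family with zero observations yields missing values, not zeros —
an absent amino acid says nothing about codon preference. This matters for
the correspondence analysis (below).

*CAI.* Sharp–Li weights are built from pooled reference counts with zero
counts floored at 0.5 pseudo-counts (so no weight is 0 and the geometric
mean is defined); a family absent from the reference gets uninformative
weights of 1. CAI is retained even where expression data replace it as the
expression proxy, so CAI-vs-FPKM correlation experiments are reproducible.

*PR2.* Third-position base counts are restricted to the eight four-codon
families (Ala, Gly, Pro, Thr, Val, and the four-fold halves of Arg/Leu/Ser);
x = G3/(G3+C3), y = A3/(A3+T3). A zero denominator flags the coordinate as
undefined rather than inventing 0.5.

## Mutation-vs-selection diagnostics

*Neutrality plot.* GC12 is regressed on GC3 by ordinary least squares —
the slope is then directly interpretable as the mutation-pressure share
(slope × 100%) — while the correlation coefficient reported alongside is
Spearman's rank, the convention in this literature. The two choices are
independent and both are stated in the output.

*ENC deviation.* (ENCexp − ENCobs)/ENCexp per gene, histogrammed in
0.05-wide bins half-open on the left, so the interval labels
("−0.05 to 0.00", "0.00–0.05") are unambiguous and a gene exactly on the
expected curve falls in the [0.00, 0.05) bin.

*Optimal codons.* "Significantly different usage between expression strata"
is operationalized as, per codon, a 2×2 chi-square test of independence
(codon vs rest-of-family × high vs low stratum, no continuity correction).
Significance alone would flag depletion as well as enrichment, so a codon is
called optimal only when additionally RSCU_high > 1 and
RSCU_high − RSCU_low ≥ 0.08 (the conventional ΔRSCU cutoff); both thresholds
and the α = 0.01 level are parameters. No multiple-testing correction is
applied by default, matching standard practice for this protocol;
Benjamini–Hochberg is available behind a flag. Strata are defined after
excluding genes with expression < 1.0 (low FPKM is quantification noise),
either as a fraction of the filtered set (default 5%) or as a fixed count
per stratum (e.g. 1,500) — two presets because both appear in published
practice; ties in expression are broken by gene id for determinism.

## Correspondence analysis

Implemented directly rather than delegated: the table is normalized to
P = X/n, standardized residuals S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2} are
decomposed by SVD, axis inertias are the squared singular values (their sum
equals the Pearson χ²/n of the table — this identity is the test oracle),
and rows and columns get principal coordinates, making gene and codon maps
super-imposable. The RSCU matrix is treated as quasi-contingency input (the
CodonW convention for "COA on RSCU"). Missing RSCU entries are imputed at
the neutral value 1.0 — imputing 0 would read absence of an amino acid as
avoidance of all its codons — and genes with more than half their families
missing are dropped instead. Axis signs are fixed by forcing the
alphabetically first column with nonzero loading to a nonnegative
coordinate, so output is platform-independent. A genes × 20 amino-acid
frequency table has at most 19 informative axes; no null axis is emulated.

## Group comparisons and clustering

Stratum and category contrasts use Welch's t-test (unequal variances) on
GC1/GC2/GC3/ENC — safer than Student's when stratum variances differ, which
is the rule for GC3. Category dispersion is the SD across category means,
with categories under 10 genes summarized but flagged and excluded from the
dispersion (tiny categories produce degenerate SDs). Species clustering is
agglomerative (UPGMA default; complete/single available) on Euclidean
distance over the species feature vector — by default the scalar mean GC3,
optionally richer profiles — with species pre-sorted by name so distance
ties resolve deterministically, serialized as Newick with branch lengths
equal to merge-height differences (leaves at height 0).

## Synthetic data

The generator is the test bed for the whole pipeline and encodes the study
conditions the analysis assumes:

- **Gene lengths** uniform over multiples of 3 in [300, 1800] bp (ATG
  included), matching the screening minimum.
- **Mutation regime**: per gene, p_GC is drawn uniformly (default range
  (0.22, 0.68), centering genome GC near 45% with a ~29–68% per-gene
  spread); every base is then iid G/C with probability p_GC, A/T otherwise,
  with even splits. In-frame stop codons are resampled by redrawing only the
  third base: this keeps first/second-position base probabilities exactly
  iid, which the slope-recovery analysis relies on (redrawing whole codons
  depletes first-position T and measurably compresses the GC12 response).
  The residual third-position distortion is confined to TGA→TGx redraws and
  is negligible at these lengths.
- **Selection regime**: the amino-acid sequence is sampled first (uniform
  over the 18 degenerate-family amino acids, Met/Trp at weight 0.2), then
  synonymous codons are chosen with a per-gene G/C-ending preference drawn
  independently of the amino-acid composition.
- **Expression**: log-normal (default μ = 2.0, σ = 1.5 on the log scale,
  median ≈ 7.4), rank-coupled to GC3 through a Gaussian copula (the target
  Spearman is converted to the equivalent normal-scores Pearson), with 10%
  of genes overwritten by Uniform(0, 1) values to exercise the FPKM < 1
  exclusion.
- **Categories**: labels are assigned round-robin with planted p_GC offsets;
  genes at the same within-category position share the underlying uniform
  draw (common random numbers), so a planted GC3 offset between categories
  is recoverable at a few hundred genes per category.

What the generator does *not* emulate: assembly artifacts (chimeras,
fragmentation, redundant isoforms), codon autocorrelation along a gene,
amino-acid composition differences between expression strata, and
length–bias correlations. Passing tests therefore demonstrate correctness of
the estimators and the diagnostics' behaviour under their own model
assumptions, not robustness to real transcriptome pathologies.

Even under the pure-mutation regime the fitted neutrality slope is expected
slightly below 1 (≈ 0.96–0.97 at 2,000 genes): per-gene GC3 estimates carry
finite-length sampling noise, and regressing on a noisy covariate attenuates
the slope (errors-in-variables). The recovery band of ±0.05 around 1 covers
this attenuation; it is a property of the regression design, not an
estimator bug.

## Problem sizes and determinism

Default test and reproduction runs use 2,000 genes for slope recovery, 1,000
replicates at n = 100 per stratum for the Welch type-I calibration, and a
few hundred genes for end-to-end pipeline checks — sizes at which the
Monte-Carlo error is an order of magnitude below the tolerances being
checked. Every stochastic step descends from a single integer seed via
deterministic per-gene sub-streams; identical seeds give byte-identical
FASTA/TSV/JSON outputs, and the pipeline manifest records parameters, input
checksums and per-stage counts so any run can be audited.

## Known limitations

- Only the standard nuclear genetic code is wired in; the degeneracy
  partition is a module-level constant rather than a pluggable table.
- ENC conventions for sparse genes differ between published tools; ours
  (documented above) is one defensible choice, so ENC values for very short
  genes may differ from other software by a fraction of a unit.
- The optimal-codon call depends on pooled stratum counts, so a handful of
  very long genes can dominate a stratum; no per-gene weighting is applied.
- The neutrality partition is a regression slope, not a likelihood-based
  decomposition; it quantifies association, not cause.
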