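# codonscape

Codon-usage-bias analysis for sets of coding sequences, built for the kind of
transcriptome-wide study done on non-model plants (the motivating case is a
gymnosperm seed transcriptome): given CDS FASTA, an FPKM-like expression
table and optional functional annotation, the package screens the genes,
computes the standard usage indices, and asks the central question of the
field — *is synonymous codon choice shaped mainly by directional mutation
pressure or by natural selection?*

## What it computes

For each screened gene *g* with codon counts *x*:

- **Positional GC** — GC1, GC2, GC3 (G+C fraction at each codon position over
  sense codons), GC3s (third position over the 59 synonymous codons only) and
  GC12 = (GC1+GC2)/2.
- **RSCU** — for codon *j* of amino acid *i*,
  RSCU<sub>ij</sub> = x<sub>ij</sub> / ( (1/n<sub>i</sub>) Σ<sub>j</sub> x<sub>ij</sub> );
  1.0 means no preference, and each family's values sum to its degeneracy.
- **ENC** (Wright's effective number of codons) — per family
  F = (nΣp<sub>i</sub>² − 1)/(n − 1), then
  ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clamped to [20, 61]
  (20 = one codon per amino acid, 61 = all synonyms equal), with the
  mutation-only expectation ENC<sub>exp</sub> = 2 + s + 29/(s² + (1−s)²)
  at s = GC3s.
- **GRAVY / Aromo** — Kyte–Doolittle hydropathy mean and aromatic-residue
  fraction of the translated product.
- **CAI** — Sharp–Li geometric mean of relative-adaptiveness weights from a
  reference gene set.
- **PR2 coordinates** — G3/(G3+C3) vs A3/(A3+T3) over the eight four-fold
  degenerate families; (0.5, 0.5) under strand-symmetric neutral mutation.

At the gene-set level: the **neutrality regression** of GC12 on GC3 (slope 1 =
pure mutation pressure, slope 0 = selection/other forces; slope × 100 is
reported as the mutation-pressure percentage), the **(ENCexp − ENCobs)/ENCexp**
deviation histogram, **preferred codons** (pooled RSCU > 1), **optimal
codons** (per-codon 2×2 chi-square between high/low expression strata with
RSCU-difference and enrichment conditions), **correspondence analysis** of the
genes × RSCU and genes × amino-acid-frequency matrices (chi-square-residual
SVD, implemented from first principles), and grouped contrasts (expression
strata, functional categories, pathway position, cross-species GC3/UPGMA
clustering).

A seeded synthetic-sequence generator produces gene sets under a *mutation*
regime (iid bases at a per-gene G+C probability — true slope 1), a
*selection* regime (amino-acid sequence fixed first, synonymous codons chosen
by a per-gene G/C-ending preference — true slope 0) or a mixture, so every
stage is testable with known ground truth.

## Worked example

Simulate 500 genes under a 50/50 mutation/selection mixture with expression
rank-coupled to GC3 (Spearman 0.3), then run the full pipeline:

```bash
codonscape simulate --regime mixed --n 500 --seed 42 --coupling 0.3 --out-dir demo/sim
cat > demo/demo.yaml <<EOF
fasta: demo/sim/genes.fa
expression: demo/sim/expression.tsv
out_dir: demo/out
strata_size: 0.05
EOF
codonscape run --config demo/demo.yaml
```

The run prints a stage summary:

```json
{
 "screen":  {"input": 500, "kept": 500, "rejected": 0},
 "indices": {"genes": 500},
 "bias":    {"slope": 0.39183440989036145, "n_preferred": 26,
             "AU_ending": 19, "GC_ending": 7},
 "optimal": {"stratum_size": 20, "n_optimal": 22},
 "coa":     {"n_axes": 4, "pct_axis1": 29.177815845434143}
}
```

Read this as: all 500 genes pass screening (the generator honours the screen's
rules); the neutrality slope of 0.392 sits between the two regime endpoints,
i.e. mutation pressure explains ~39% of the codon-usage variation and
selection/other forces the remaining ~61% (`demo/out/neutrality.tsv` has the
intercept, Spearman r = 0.532 and p); 26 codons are preferred genome-wide, 19
of them A/U-ending; and 22 codons are significantly enriched in the top-5%
expression stratum — predominantly G/C-ending (UUC, CUC, CUG, UGC, …), the
signature induced by the positive GC3–expression coupling. Axis 1 of the
correspondence analysis carries 29.2% of the total inertia, the GC3 gradient
the mixture plants.

Per-gene tables (`indices.tsv`, `rscu.tsv`), the optimal-codon report, CA
coordinates and group summaries are written next to the manifest in
`demo/out/`.

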