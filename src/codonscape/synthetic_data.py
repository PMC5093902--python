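"""Synthetic coding-sequence generator with known mutation/selection ground truth.

Emulates the statistical structure a transcriptome-wide codon-usage study
assumes: genes of 300-1,800 bp with a broad per-gene GC spread (mean ~45%,
range roughly 29-68%), a log-skewed FPKM-like expression distribution with
a point mass below 1.0, optional functional-category labels with planted
GC3 offsets, and — critically — two base-composition regimes with known
neutrality-plot behaviour:

* ``mutation`` — every base of a gene is drawn independently with a
  per-gene G+C probability (A/T and G/C split evenly; in-frame stop codons
  resampled; ATG prepended). GC1, GC2 and GC3 then share the same expectation,
  so the GC12-on-GC3 regression slope tends to 1 (complete neutrality).
* ``selection`` — the amino-acid sequence is fixed first (sampled from a
  frequency table), then synonymous codons are chosen with a per-gene
  G/C-ending preference drawn independently of amino-acid composition:
  GC3 varies widely while GC12 is amino-acid-constrained, so the slope
  tends to 0.
* ``mixed`` — each gene takes the mutation path with probability ``m``.

A single integer seed makes every output byte-identical across runs;
per-gene sub-streams are derived deterministically so the generator is
order-independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .codon_core import STOP_CODONS, SYNONYMOUS_FAMILIES
from .sequence_qc import CdsRecord, write_fasta


@dataclass
class SyntheticConfig:
    """Generator settings; ``seed`` is mandatory, everything else has defaults.

    ``gc_bias`` is the per-gene p_GC range for the mutation path; the default
    (0.22, 0.68) centers genome GC near 45% with a ~29-68% per-gene spread,
    the composition profile typical of a gymnosperm transcriptome.
    ``selection_gc3_range`` is the per-gene G/C-ending preference range for
    the selection path. ``categories`` maps label -> planted p_GC (hence GC3)
    offset; genes are assigned round-robin and matched across categories by
    a shared base draw, so planted offsets are recoverable at modest n.
    """

    seed: int
    n_genes: int = 2000
    length_range: tuple[int, int] = (300, 1800)
    regime: str = "mutation"  # mutation | selection | mixed
    mixing_weight: float = 0.5
    gc_bias: tuple[float, float] = (0.22, 0.68)
    selection_gc3_range: tuple[float, float] = (0.25, 0.75)
    aa_weights: dict[str, float] | None = None
    expression_mu: float = 2.0
    expression_sigma: float = 1.5
    zero_inflation: float = 0.1
    expression_coupling: float = 0.0
    categories: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.regime not in ("mutation", "selection", "mixed"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 <= self.mixing_weight <= 1:
            raise ValueError("mixing_weight must be in [0, 1]")
        lo, hi = self.length_range
        if lo > hi or lo < 3:
            raise ValueError(f"bad length_range {self.length_range}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class SyntheticDataset:
    """Everything one generator call produced, plus the ground truth."""

    records: list[CdsRecord]
    expression: dict[str, float]
    annotation: dict[str, str]
    truth: dict = field(default_factory=dict)


def _default_aa_weights() -> dict[str, float]:
    # uniform over the 18 degenerate-family amino acids, Met/Trp at low weight
    w = {aa: 1.0 for aa in SYNONYMOUS_FAMILIES}
    w["M"] = 0.2
    w["W"] = 0.2
    return w


def _mutation_gene(rng: np.random.Generator, n_codons: int, p_gc: float) -> str:
    """ATG + (n_codons - 1) codons of iid bases; stops resampled in frame.

    Only the third base of an in-frame stop is redrawn: first/second-position
    base probabilities then stay exactly iid at the per-gene composition,
    which is what the neutrality slope-recovery math relies on (the residual
    third-position distortion is confined to TGA and is negligible).
    """
    probs = np.array([p_gc / 2, p_gc / 2, (1 - p_gc) / 2, (1 - p_gc) / 2])
    bases = np.array(list("GCAT"))
    codons = []
    need = n_codons - 1
    draw = bases[rng.choice(4, size=(need, 3), p=probs)]
    for row in draw:
        codon = "".join(row)
        while codon in STOP_CODONS:
            codon = codon[:2] + bases[rng.choice(4, p=probs)]
        codons.append(codon)
    return "ATG" + "".join(codons)


def _selection_gene(
    rng: np.random.Generator,
    n_codons: int,
    gc3_pref: float,
    aa_names: list[str],
    aa_probs: np.ndarray,
) -> str:
    """ATG + codons for a sampled protein, synonyms picked by G/C-ending preference."""
    aas = rng.choice(len(aa_names), size=n_codons - 1, p=aa_probs)
    codons = []
    for ai in aas:
        aa = aa_names[ai]
        if aa == "M":
            codons.append("ATG")
            continue
        if aa == "W":
            codons.append("TGG")
            continue
        family = SYNONYMOUS_FAMILIES[aa]
        gc_end = [c for c in family if c[2] in "GC"]
        at_end = [c for c in family if c[2] in "AT"]
        w = np.array(
            [gc3_pref / len(gc_end) if c[2] in "GC" else (1 - gc3_pref) / len(at_end) for c in family]
        )
        codons.append(family[rng.choice(len(family), p=w / w.sum())])
    return "ATG" + "".join(codons)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset described by ``config``.

    Per-gene parameters (length, regime path, p_GC or G/C-ending preference)
    are stored in the truth record so parameter-recovery tests can compare
    estimates with what was planted.
    """
    lo_c = (config.length_range[0] + 2) // 3
    hi_c = config.length_range[1] // 3
    if lo_c > hi_c:
        raise ValueError("length_range admits no multiple-of-3 length")

    cats = sorted(config.categories) if config.categories else []
    aa_w = config.aa_weights or _default_aa_weights()
    aa_names = sorted(aa_w)
    aa_probs = np.array([aa_w[a] for a in aa_names], dtype=float)
    aa_probs /= aa_probs.sum()

    records: list[CdsRecord] = []
    annotation: dict[str, str] = {}
    per_gene: list[dict] = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        rng = np.random.default_rng([config.seed, 2, i])
        gid = f"gene{i + 1:0{width}d}"
        n_codons = int(rng.integers(lo_c, hi_c + 1))

        category = None
        offset = 0.0
        if cats:
            category = cats[i % len(cats)]
            offset = config.categories[category]
            # matched base draw: gene j of every category shares its uniform
            base_u = float(np.random.default_rng([config.seed, 1, i // len(cats)]).uniform())
        else:
            base_u = float(np.random.default_rng([config.seed, 1, i]).uniform())

        if config.regime == "mixed":
            path = "mutation" if rng.uniform() < config.mixing_weight else "selection"
        else:
            path = config.regime

        if path == "mutation":
            lo, hi = config.gc_bias
            p_gc = min(max(lo + base_u * (hi - lo) + offset, 0.01), 0.99)
            seq = _mutation_gene(rng, n_codons, p_gc)
            per_gene.append({"id": gid, "path": path, "p_gc": p_gc, "category": category})
        else:
            lo, hi = config.selection_gc3_range
            pref = min(max(lo + base_u * (hi - lo) + offset, 0.01), 0.99)
            seq = _selection_gene(rng, n_codons, pref, aa_names, aa_probs)
            per_gene.append({"id": gid, "path": path, "gc3_pref": pref, "category": category})

        records.append(CdsRecord(id=gid, seq=seq, category=category))
        if category is not None:
            annotation[gid] = category

    gc3 = np.array([_gc3(r.seq) for r in records])
    expression = generate_expression(config, gc3, config.expression_coupling)
    for rec, (gid, fpkm) in zip(records, expression.items()):
        rec.expression = fpkm

    truth = {
        "regime": config.regime,
        "mixing_weight": config.mixing_weight,
        "seed": config.seed,
        "n_genes": config.n_genes,
        "genes": per_gene,
    }
    return SyntheticDataset(records, expression, annotation, truth)


def _gc3(seq: str) -> float:
    thirds = seq[2::3]
    return sum(1 for b in thirds if b in "GC") / len(thirds)


def generate_expression(
    config: SyntheticConfig, gene_gc3: np.ndarray, coupling: float = 0.0
) -> dict[str, float]:
    """Log-normal FPKM-like values, rank-coupled to GC3 via a Gaussian copula.

    ``coupling`` is the target Spearman correlation with GC3 (converted to
    the equivalent Pearson correlation of the underlying normals). A
    ``zero_inflation`` fraction of genes is overwritten with values below
    1.0 to exercise the minimum-expression filter.
    """
    if not -1 <= coupling <= 1:
        raise ValueError("coupling must be in [-1, 1]")
    rng = np.random.default_rng([config.seed, 3])
    gene_gc3 = np.asarray(gene_gc3, dtype=float)
    n = len(gene_gc3)
    rho = 2 * math.sin(math.pi * coupling / 6)  # Spearman -> Pearson on normals
    ranks = stats.rankdata(gene_gc3, method="average")
    z_gc3 = stats.norm.ppf(ranks / (n + 1))
    z = rho * z_gc3 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    expr = np.exp(config.expression_mu + config.expression_sigma * z)
    k = int(round(config.zero_inflation * n))
    if k:
        idx = rng.choice(n, size=k, replace=False)
        expr[idx] = rng.uniform(0.0, 1.0, size=k)
    width = len(str(n))
    return {f"gene{i + 1:0{width}d}": float(expr[i]) for i in range(n)}


def write_outputs(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write FASTA, expression TSV, annotation TSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.records, out / "genes.fa")
    with open(out / "expression.tsv", "w") as fh:
        fh.write("id\tfpkm\n")
        for gid, v in dataset.expression.items():
            fh.write(f"{gid}\t{v:.6g}\n")
    with open(out / "annotation.tsv", "w") as fh:
        fh.write("id\tcategory\n")
        for gid, cat in dataset.annotation.items():
            fh.write(f"{gid}\t{cat}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=1)
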