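"""Per-gene codon counting and codon-usage indices.

Implements the scalar and vector indices used throughout codon-usage-bias
studies: positional GC contents (GC, GC1/GC2/GC3 and synonymous-only GC3s),
relative synonymous codon usage (RSCU), Wright's effective number of codons
(ENC) with its mutation-only expectation, the Kyte-Doolittle GRAVY score,
aromaticity, the codon adaptation index (CAI) with reference-set weight
construction, and parity-rule-2 (PR2) coordinates over the four-fold
degenerate codon families.

All codon arithmetic is DNA-alphabet internally (T, not U); RNA spelling is a
reporting concern (see :func:`to_rna`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_qc import CdsRecord, translate

# ---------------------------------------------------------------------------
# Standard genetic code and degeneracy classes
# ---------------------------------------------------------------------------

BASES = "TCAG"

#: codon -> one-letter amino acid, '*' for stop (standard nuclear code)
STANDARD_CODE: dict[str, str] = {
    f + s + t: aa
    for f, s, t, aa in zip(
        (b for b in BASES for _ in range(16)),
        (b for _ in range(4) for b in BASES for _ in range(4)),
        BASES * 16,
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
}

STOP_CODONS = frozenset(c for c, aa in STANDARD_CODE.items() if aa == "*")
SENSE_CODONS = tuple(c for c in STANDARD_CODE if c not in STOP_CODONS)  # 61

#: the 59 informative codons: sense codons minus the non-degenerate ATG/TGG
INFORMATIVE_CODONS = tuple(c for c in SENSE_CODONS if c not in ("ATG", "TGG"))

#: amino acid -> tuple of synonymous codons, degenerate families only (18 aas)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in INFORMATIVE_CODONS:
    SYNONYMOUS_FAMILIES.setdefault(STANDARD_CODE[_codon], ())
for _codon in INFORMATIVE_CODONS:
    _aa = STANDARD_CODE[_codon]
    SYNONYMOUS_FAMILIES[_aa] = SYNONYMOUS_FAMILIES[_aa] + (_codon,)

#: degeneracy class -> amino acids (2-, 3-, 4-, 6-fold under the standard code)
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _codons in SYNONYMOUS_FAMILIES.items():
    DEGENERACY_CLASSES.setdefault(len(_codons), ())
    DEGENERACY_CLASSES[len(_codons)] = DEGENERACY_CLASSES[len(_codons)] + (_aa,)

# Eight four-codon families of the PR2 plot: Ala Gly Pro Thr Val plus the
# four-fold halves of Arg (CGN), Leu (CTN) and Ser (TCN).
PR2_FAMILIES: tuple[tuple[str, ...], ...] = tuple(
    tuple(b1 + b2 + t for t in BASES)
    for b1, b2 in ("GC", "GG", "CC", "AC", "GT", "CG", "CT", "TC")
)

#: Kyte-Doolittle hydropathy indices
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

AROMATIC = frozenset("FYW")


def to_rna(codon: str) -> str:
    """DNA codon spelling -> RNA spelling (T -> U) for reporting."""
    return codon.replace("T", "U")


# ---------------------------------------------------------------------------
# Codon counting
# ---------------------------------------------------------------------------


@dataclass
class CodonCountTable:
    """Counts over the 64 codons for one gene or a pooled gene set.

    ``n_codons`` is the number of sense codons (stops excluded).
    """

    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_codons(self) -> int:
        return sum(v for c, v in self.counts.items() if c not in STOP_CODONS)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = dict(self.counts)
        for c, v in other.counts.items():
            merged[c] = merged.get(c, 0) + v
        return CodonCountTable("pooled", merged)


def count_codons(record: CdsRecord) -> CodonCountTable:
    """Count non-overlapping in-frame codons of a screened CDS.

    The terminal stop codon, if present, is recorded but never enters
    ``n_codons``. Raises ``ValueError`` on out-of-frame input or on a
    sequence with no sense codons.
    """
    seq = record.seq
    if len(seq) % 3 != 0:
        raise ValueError(f"{record.id}: length {len(seq)} not a multiple of 3")
    counts: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        counts[codon] = counts.get(codon, 0) + 1
    table = CodonCountTable(record.id, counts)
    if table.n_codons == 0:
        raise ValueError(f"{record.id}: no sense codons")
    return table


def pool_counts(tables: list[CodonCountTable]) -> CodonCountTable:
    """Sum codon counts over a gene set into one pooled table."""
    pooled = CodonCountTable("pooled", {})
    for t in tables:
        pooled = pooled + t
    return pooled


# ---------------------------------------------------------------------------
# GC content by codon position
# ---------------------------------------------------------------------------


def gc_by_position(counts: CodonCountTable) -> tuple[float, float, float, float, float]:
    """Return (gc, gc1, gc2, gc3, gc3s).

    gc1/gc2/gc3 are G+C fractions at each codon position over all sense
    codons; gc is their mean (the overall G+C fraction of the sense codons);
    gc3s restricts the third position to the 59 informative codons, so the
    invariant third positions of ATG and TGG never contribute.
    """
    n = counts.n_codons
    if n == 0:
        raise ValueError("zero sense codons")
    pos_gc = [0, 0, 0]
    syn3_gc = 0
    n_syn = 0
    for codon, x in counts.counts.items():
        if codon in STOP_CODONS:
            continue
        for k in range(3):
            if codon[k] in "GC":
                pos_gc[k] += x
        if codon in ("ATG", "TGG"):
            continue
        n_syn += x
        if codon[2] in "GC":
            syn3_gc += x
    gc1, gc2, gc3 = (p / n for p in pos_gc)
    gc3s = syn3_gc / n_syn if n_syn else float("nan")
    return ((gc1 + gc2 + gc3) / 3, gc1, gc2, gc3, gc3s)


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


def rscu(counts: CodonCountTable) -> dict[str, float]:
    """Relative synonymous codon usage over the 59 informative codons.

    RSCU_ij = x_ij / mean(x over the family), so values are 1.0 under
    uniform synonymous usage and sum to the family degeneracy. Families with
    zero total are reported as NaN (missing), not 0: an absent amino acid
    carries no information about codon preference.
    """
    out: dict[str, float] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        total = sum(counts.counts.get(c, 0) for c in family)
        if total == 0:
            for c in family:
                out[c] = float("nan")
        else:
            for c in family:
                out[c] = counts.counts.get(c, 0) * len(family) / total
    return out


# ---------------------------------------------------------------------------
# ENC (Wright's effective number of codons)
# ---------------------------------------------------------------------------


def enc(counts: CodonCountTable) -> tuple[float, float]:
    """Wright's ENC of one gene: ``(clamped, raw)``.

    Per degenerate family with n codons observed and usage fractions p_i,
    F = (n * sum(p_i^2) - 1) / (n - 1); F_km averages F over the observed
    families of degeneracy k, and

        ENC = 2 + 9/F2m + 1/F3m + 5/F4m + 3/F6m.

    Families with n <= 1 or F = 0 are excluded from their class average
    (they carry no or degenerate information). A missing 3-fold class
    (Ile unobserved) is imputed as the mean of F2m and F4m, Wright's
    convention. If any other class average is undefined the gene's ENC is
    NaN. The first element is clamped to the theoretical range [20, 61];
    the second is the raw value.
    """
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        n = sum(counts.counts.get(c, 0) for c in family)
        if n <= 1:
            continue
        sum_p2 = sum((counts.counts.get(c, 0) / n) ** 2 for c in family)
        f = (n * sum_p2 - 1) / (n - 1)
        if f > 0:
            f_by_class[len(family)].append(f)

    f_mean = {k: (np.mean(v) if v else None) for k, v in f_by_class.items()}
    if f_mean[3] is None and f_mean[2] is not None and f_mean[4] is not None:
        f_mean[3] = (f_mean[2] + f_mean[4]) / 2
    if any(f_mean[k] is None for k in (2, 3, 4, 6)):
        return float("nan"), float("nan")

    raw = 2 + 9 / f_mean[2] + 1 / f_mean[3] + 5 / f_mean[4] + 3 / f_mean[6]
    return min(max(raw, 20.0), 61.0), raw


def expected_enc(gc3s: float) -> float:
    """Mutation-pressure-only expectation of ENC at synonymous GC3 = s:

    ENCexp = 2 + s + 29 / (s^2 + (1 - s)^2).
    """
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must be in [0, 1], got {gc3s}")
    return 2 + gc3s + 29 / (gc3s**2 + (1 - gc3s) ** 2)


# ---------------------------------------------------------------------------
# Protein-level indices
# ---------------------------------------------------------------------------


def gravy(protein: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle index per residue."""
    if not protein:
        raise ValueError("empty protein")
    try:
        return sum(KYTE_DOOLITTLE[aa] for aa in protein) / len(protein)
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r}") from None


def aromaticity(protein: str) -> float:
    """Fraction of aromatic residues (Phe, Tyr, Trp)."""
    if not protein:
        raise ValueError("empty protein")
    unknown = set(protein) - set(KYTE_DOOLITTLE)
    if unknown:
        raise ValueError(f"unknown residues {sorted(unknown)}")
    return sum(1 for aa in protein if aa in AROMATIC) / len(protein)


# ---------------------------------------------------------------------------
# CAI (Sharp & Li)
# ---------------------------------------------------------------------------


def build_cai_weights(
    reference: list[CodonCountTable], pseudo_count: float = 0.5
) -> dict[str, float]:
    """Relative-adaptiveness weights from a (highly expressed) reference set.

    Within each synonymous family, w_j = x_j / max_j x_j on pooled counts;
    zero counts are floored to ``pseudo_count`` so no weight is 0. A family
    entirely absent from the reference gets weights of 1 (uninformative).
    """
    if not reference:
        raise ValueError("empty reference set")
    pooled = pool_counts(reference)
    weights: dict[str, float] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        xs = {c: float(pooled.counts.get(c, 0)) for c in family}
        if max(xs.values()) == 0:
            weights.update({c: 1.0 for c in family})
            continue
        xs = {c: max(x, pseudo_count) for c, x in xs.items()}
        top = max(xs.values())
        weights.update({c: x / top for c, x in xs.items()})
    return weights


def cai(counts: CodonCountTable, weights: dict[str, float]) -> float:
    """Codon adaptation index: geometric mean of w over informative codons."""
    log_sum = 0.0
    n = 0
    for codon, x in counts.counts.items():
        if codon not in INFORMATIVE_CODONS or x == 0:
            continue
        w = weights[codon]
        if w <= 0:
            raise ValueError(f"nonpositive weight for {codon}")
        log_sum += x * math.log(w)
        n += x
    if n == 0:
        raise ValueError("no informative codons")
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# PR2 coordinates
# ---------------------------------------------------------------------------


def pr2_coordinates(counts: CodonCountTable) -> tuple[float, float]:
    """Parity-rule-2 coordinates ``(x, y)`` over four-fold degenerate codons.

    x = G3/(G3+C3), y = A3/(A3+T3), with third-position base counts
    restricted to the eight four-codon families. Under strand-symmetric
    mutation with no selection both coordinates sit at 0.5. A zero
    denominator yields NaN for that coordinate.
    """
    base3 = {b: 0 for b in "ACGT"}
    for family in PR2_FAMILIES:
        for codon in family:
            base3[codon[2]] += counts.counts.get(codon, 0)
    if sum(base3.values()) == 0:
        raise ValueError("no four-fold degenerate codons present")
    gc = base3["G"] + base3["C"]
    at = base3["A"] + base3["T"]
    x = base3["G"] / gc if gc else float("nan")
    y = base3["A"] / at if at else float("nan")
    return x, y


# ---------------------------------------------------------------------------
# Per-gene index bundle
# ---------------------------------------------------------------------------


@dataclass
class UsageIndices:
    """All per-gene usage indices for one screened CDS."""

    gene_id: str
    n_codons: int
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    enc_obs: float
    enc_raw: float
    enc_exp: float
    gravy: float
    aromo: float
    pr2_x: float
    pr2_y: float
    cai: float | None = None
    expression: float | None = None
    protein_length: int = 0
    rscu: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2


def compute_indices(
    record: CdsRecord, cai_weights: dict[str, float] | None = None
) -> UsageIndices:
    """Compute the full :class:`UsageIndices` bundle for one screened CDS."""
    counts = count_codons(record)
    gc, gc1, gc2, gc3, gc3s = gc_by_position(counts)
    enc_clamped, enc_raw = enc(counts)
    protein = translate(record)
    try:
        x, y = pr2_coordinates(counts)
    except ValueError:
        x = y = float("nan")
    return UsageIndices(
        gene_id=record.id,
        n_codons=counts.n_codons,
        gc=gc,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc3s=gc3s,
        enc_obs=enc_clamped,
        enc_raw=enc_raw,
        enc_exp=expected_enc(gc3s) if not math.isnan(gc3s) else float("nan"),
        gravy=gravy(protein),
        aromo=aromaticity(protein),
        pr2_x=x,
        pr2_y=y,
        cai=cai(counts, cai_weights) if cai_weights else None,
        expression=record.expression,
        protein_length=len(protein),
        rscu=rscu(counts),
    )


INDEX_COLUMNS = (
    "n_codons gc gc1 gc2 gc3 gc3s gc12 enc_obs enc_raw enc_exp "
    "gravy aromo cai pr2_x pr2_y expression protein_length"
).split()


def indices_table(indices: list[UsageIndices]) -> pd.DataFrame:
    """Per-gene indices as a DataFrame indexed by gene id."""
    rows = {
        ix.gene_id: [
            ix.n_codons, ix.gc, ix.gc1, ix.gc2, ix.gc3, ix.gc3s, ix.gc12,
            ix.enc_obs, ix.enc_raw, ix.enc_exp, ix.gravy, ix.aromo,
            np.nan if ix.cai is None else ix.cai, ix.pr2_x, ix.pr2_y,
            np.nan if ix.expression is None else ix.expression,
            ix.protein_length,
        ]
        for ix in indices
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=INDEX_COLUMNS)
    df.index.name = "id"
    return df


def rscu_matrix(indices: list[UsageIndices], rna: bool = True) -> pd.DataFrame:
    """Genes x 59-codon RSCU matrix (RNA spelling by default)."""
    cols = list(INFORMATIVE_CODONS)
    data = {ix.gene_id: [ix.rscu.get(c, np.nan) for c in cols] for ix in indices}
    names = [to_rna(c) if rna else c for c in cols]
    df = pd.DataFrame.from_dict(data, orient="index", columns=names)
    df.index.name = "id"
    return df
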