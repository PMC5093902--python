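"""Gene-set diagnostics separating mutation pressure from selection.

Four complementary diagnostics over a screened gene set:

* ENC deviation — per-gene (ENCexp - ENCobs)/ENCexp with the conventional
  0.05-wide histogram; mass near zero means observed bias is explained by
  base composition alone.
* Neutrality regression — OLS of GC12 on GC3 across genes; a slope of 1
  means codon usage is fully determined by directional mutation pressure,
  a slope of 0 means third positions vary free of first/second-position
  constraint (selection or other forces). The slope x 100 is reported as
  the mutation-pressure percentage.
* Preferred codons — pooled RSCU > 1.0.
* Optimal codons — codons significantly enriched in highly expressed genes,
  from per-codon 2x2 chi-square tests between expression strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import (
    INFORMATIVE_CODONS,
    SYNONYMOUS_FAMILIES,
    CodonCountTable,
    UsageIndices,
    rscu,
    to_rna,
)
from .sequence_qc import CdsRecord

# ---------------------------------------------------------------------------
# ENC deviation
# ---------------------------------------------------------------------------


@dataclass
class EncDeviation:
    """Per-gene (ENCexp - ENCobs)/ENCexp values and their histogram.

    Bins are half-open on the left: [k*w, (k+1)*w).
    """

    values: pd.Series
    bin_edges: np.ndarray
    bin_counts: np.ndarray


def enc_deviation(indices: list[UsageIndices], bin_width: float = 0.05) -> EncDeviation:
    """Relative deviation of observed ENC from its mutation-only expectation."""
    vals = {}
    for ix in indices:
        if math.isnan(ix.enc_obs) or math.isnan(ix.enc_exp) or ix.enc_exp <= 0:
            continue
        vals[ix.gene_id] = (ix.enc_exp - ix.enc_obs) / ix.enc_exp
    values = pd.Series(vals, name="enc_deviation")
    if values.empty:
        return EncDeviation(values, np.array([]), np.array([]))
    lo = math.floor(values.min() / bin_width)
    hi = math.floor(values.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    # np.histogram closes the last bin on the right; widen it so every bin
    # stays half-open [k*w, (k+1)*w) as the interval labels promise.
    counts, _ = np.histogram(values.values, bins=np.append(edges[:-1], edges[-1] + bin_width / 2))
    return EncDeviation(values, edges, counts)


# ---------------------------------------------------------------------------
# Neutrality plot
# ---------------------------------------------------------------------------


@dataclass
class NeutralityFit:
    """OLS fit of GC12 on GC3 with Spearman correlation.

    ``pct_mutation`` = slope x 100 is the share of codon usage attributed to
    directional mutation pressure; the remainder is selection plus other
    forces.
    """

    slope: float
    intercept: float
    spearman_r: float
    p_value: float
    n_genes: int

    @property
    def pct_mutation(self) -> float:
        return self.slope * 100

    @property
    def pct_other(self) -> float:
        return 100 - self.pct_mutation


def neutrality_fit(gc12: np.ndarray, gc3: np.ndarray) -> NeutralityFit:
    """Fit GC12 on GC3 by ordinary least squares; Spearman rho for correlation."""
    gc12 = np.asarray(gc12, dtype=float)
    gc3 = np.asarray(gc3, dtype=float)
    if gc12.shape != gc3.shape or gc12.ndim != 1:
        raise ValueError("gc12 and gc3 must be aligned 1-D vectors")
    if len(gc12) < 3:
        raise ValueError("need at least 3 genes")
    if np.ptp(gc3) == 0:
        raise ValueError("zero variance in GC3: fit undefined")
    ols = stats.linregress(gc3, gc12)
    if np.ptp(gc12) == 0:
        rho, p = float("nan"), float("nan")  # rank correlation undefined
    else:
        rho, p = stats.spearmanr(gc3, gc12)
    return NeutralityFit(
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        spearman_r=float(rho),
        p_value=float(p),
        n_genes=len(gc12),
    )


# ---------------------------------------------------------------------------
# Preferred codons
# ---------------------------------------------------------------------------


def preferred_codons(pooled: CodonCountTable) -> dict[str, float]:
    """Codons with pooled RSCU > 1.0, as {DNA codon: pooled RSCU}."""
    pooled_rscu = rscu(pooled)
    return {c: v for c, v in pooled_rscu.items() if not math.isnan(v) and v > 1.0}


def ending_base_tally(codons: set[str] | dict[str, float]) -> dict[str, int]:
    """Partition a codon set by ending base class: A/T(U) vs G/C."""
    at = sum(1 for c in codons if c[2] in "AT")
    return {"AU_ending": at, "GC_ending": len(codons) - at}


# ---------------------------------------------------------------------------
# Expression stratification
# ---------------------------------------------------------------------------


def stratify_by_expression(
    records: list[CdsRecord],
    mode: str = "fraction",
    size: float | int = 0.05,
    min_expression: float = 1.0,
) -> tuple[list[CdsRecord], list[CdsRecord]]:
    """Split records into (high, low) expression strata.

    Genes with expression below ``min_expression`` (or missing) are excluded
    first — low FPKM values are dominated by quantification noise. ``mode``
    'fraction' takes ``size`` as a fraction of the filtered set, 'count' as
    an absolute number per stratum. Ties broken by id for determinism.
    """
    eligible = [r for r in records if r.expression is not None and r.expression >= min_expression]
    if mode == "fraction":
        if not 0 < size <= 0.5:
            raise ValueError("fraction must be in (0, 0.5]")
        k = int(len(eligible) * size)
    elif mode == "count":
        k = int(size)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if k < 1 or 2 * k > len(eligible):
        raise ValueError(
            f"need >= {2 * max(k, 1)} genes with expression >= {min_expression}, "
            f"have {len(eligible)}"
        )
    ranked = sorted(eligible, key=lambda r: (-r.expression, r.id))
    return ranked[:k], ranked[-k:]


# ---------------------------------------------------------------------------
# Optimal codons
# ---------------------------------------------------------------------------

OPTIMAL_REPORT_COLUMNS = [
    "codon", "amino_acid", "rscu_high", "rscu_low", "delta_rscu",
    "chi2", "p_value", "preferred", "optimal", "testable",
]


def optimal_codons(
    high: CodonCountTable,
    low: CodonCountTable,
    alpha: float = 0.01,
    delta_min: float = 0.08,
    pooled: CodonCountTable | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-codon chi-square contrast of high- vs low-expression strata.

    For each informative codon a 2x2 table [codon vs rest-of-family] x
    [high vs low] is tested for independence (no continuity correction).
    A codon is *optimal* when p < ``alpha``, its RSCU in the high stratum
    exceeds 1, and the RSCU difference (high - low) is at least
    ``delta_min`` — i.e. it is significantly and materially enriched in
    highly expressed genes. ``preferred`` flags pooled RSCU > 1 (pooled
    defaults to high + low). ``fdr`` applies Benjamini-Hochberg to the
    p-values before flagging.
    """
    rscu_h = rscu(high)
    rscu_l = rscu(low)
    rscu_p = rscu(pooled if pooled is not None else high + low)

    rows = []
    for aa, family in SYNONYMOUS_FAMILIES.items():
        tot_h = sum(high.counts.get(c, 0) for c in family)
        tot_l = sum(low.counts.get(c, 0) for c in family)
        for codon in family:
            xh = high.counts.get(codon, 0)
            xl = low.counts.get(codon, 0)
            testable = tot_h > 0 and tot_l > 0
            chi2 = p = float("nan")
            if testable:
                table = np.array([[xh, tot_h - xh], [xl, tot_l - xl]])
                # chi2_contingency rejects tables with a zero margin; a codon
                # absent (or fixed) in both strata has chi2 identically 0.
                if table.sum(axis=0).min() == 0:
                    chi2, p = 0.0, 1.0
                else:
                    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": aa,
                    "rscu_high": rscu_h[codon],
                    "rscu_low": rscu_l[codon],
                    "delta_rscu": rscu_h[codon] - rscu_l[codon],
                    "chi2": chi2,
                    "p_value": p,
                    "preferred": bool(rscu_p[codon] > 1.0)
                    if not math.isnan(rscu_p[codon])
                    else False,
                    "testable": testable,
                }
            )
    df = pd.DataFrame(rows)
    p_eff = df["p_value"].copy()
    if fdr:
        mask = df["testable"] & df["p_value"].notna()
        p_eff.loc[mask] = _benjamini_hochberg(df.loc[mask, "p_value"].values)
    df["optimal"] = (
        df["testable"]
        & (p_eff < alpha)
        & (df["rscu_high"] > 1.0)
        & (df["delta_rscu"] >= delta_min)
    )
    df = df[OPTIMAL_REPORT_COLUMNS]
    # stable codon order: by amino acid then codon, matching family listing
    assert len(df) == len(INFORMATIVE_CODONS)
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def optimal_report_rna(df: pd.DataFrame) -> pd.DataFrame:
    """Optimal-codon report with RNA codon spelling, for output tables."""
    out = df.copy()
    out["codon"] = out["codon"].map(to_rna)
    return out
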