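"""Correspondence analysis of codon-usage tables.

Classical (chi-square metric) correspondence analysis, implemented directly:
the table is converted to a correspondence matrix P, standardized residuals
S_ij = (P_ij - r_i c_j) / sqrt(r_i c_j) are decomposed by SVD, squared
singular values are the axis inertias, and rows/columns get principal
coordinates (scaled by the singular values) so gene and codon ordinations
are super-imposable. Total inertia equals the Pearson chi-square statistic
of the table divided by its grand total.

Applied here to the genes x 59-codon RSCU matrix (quasi-contingency input,
the CodonW convention) and to genes x 20 amino-acid frequency tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon_core import UsageIndices


@dataclass
class CoaResult:
    """Correspondence-analysis decomposition.

    ``inertia`` holds the eigenvalues (squared singular values) of every
    nonzero axis; percentages are relative to their sum. Row and column
    coordinates are principal coordinates on the retained axes.
    """

    inertia: np.ndarray
    total_inertia: float
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    n_axes: int
    dropped_rows: list[str]
    dropped_cols: list[str]

    @property
    def pct_inertia(self) -> np.ndarray:
        if self.total_inertia == 0:
            return np.zeros_like(self.inertia)
        return 100 * self.inertia / self.total_inertia


_SV_TOL = 1e-10


def correspondence_analysis(matrix: pd.DataFrame, n_axes: int = 4) -> CoaResult:
    """Classical CA of a nonnegative table; retains up to ``n_axes`` axes.

    All-zero rows/columns are dropped (they have no profile). The axis sign
    is fixed by forcing the column coordinate of the alphabetically first
    column with nonzero loading to be nonnegative on each axis, so output
    is deterministic across platforms.
    """
    m = matrix.astype(float)
    if (m.values < 0).any():
        raise ValueError("correspondence analysis requires a nonnegative table")
    dropped_rows = list(m.index[m.sum(axis=1) == 0])
    dropped_cols = list(m.columns[m.sum(axis=0) == 0])
    m = m.loc[m.sum(axis=1) > 0, m.sum(axis=0) > 0]
    if m.empty:
        raise ValueError("empty table after dropping zero rows/columns")

    grand = m.values.sum()
    P = m.values / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    nonzero = sv > _SV_TOL
    sv = sv[nonzero]
    U = U[:, nonzero]
    Vt = Vt[nonzero, :]
    k = min(n_axes, len(sv))

    # principal coordinates: F = D_r^{-1/2} U S, G = D_c^{-1/2} V S
    row = (U[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
    col = (Vt[:k, :].T * sv[:k]) / np.sqrt(c)[:, None]

    # deterministic sign: first column (alphabetically) with nonzero loading
    # gets a nonnegative coordinate on each axis
    col_order = np.argsort(np.asarray(m.columns, dtype=str))
    for axis in range(k):
        for j in col_order:
            if abs(col[j, axis]) > _SV_TOL:
                if col[j, axis] < 0:
                    row[:, axis] *= -1
                    col[:, axis] *= -1
                break

    axes = [f"axis{i + 1}" for i in range(k)]
    return CoaResult(
        inertia=sv**2,
        total_inertia=float((sv**2).sum()),
        row_coords=pd.DataFrame(row, index=m.index, columns=axes),
        col_coords=pd.DataFrame(col, index=m.columns, columns=axes),
        n_axes=k,
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
    )


def coa_on_rscu(
    rscu_matrix: pd.DataFrame, n_axes: int = 4, max_missing: float = 0.5
) -> CoaResult:
    """CA of a genes x 59 RSCU matrix.

    Missing entries (families unobserved in a gene) are imputed with the
    neutral RSCU of 1.0 — absence of an amino acid is not avoidance of its
    codons. Genes missing more than ``max_missing`` of their families are
    dropped instead.
    """
    frac_missing = rscu_matrix.isna().mean(axis=1)
    kept = rscu_matrix.loc[frac_missing <= max_missing].fillna(1.0)
    if kept.empty:
        raise ValueError("no genes with enough observed families")
    return correspondence_analysis(kept, n_axes=n_axes)


def coa_on_aa_usage(freq_matrix: pd.DataFrame, n_axes: int = 4) -> CoaResult:
    """CA of a genes x 20 amino-acid frequency matrix (rows sum to 1)."""
    return correspondence_analysis(freq_matrix, n_axes=n_axes)


def aa_frequency_matrix(proteins: dict[str, str]) -> pd.DataFrame:
    """Per-gene amino-acid frequency table from translated proteins."""
    from .codon_core import KYTE_DOOLITTLE

    aas = sorted(KYTE_DOOLITTLE)
    rows = {}
    for gid, protein in proteins.items():
        n = len(protein)
        rows[gid] = [protein.count(aa) / n for aa in aas] if n else [0.0] * 20
    df = pd.DataFrame.from_dict(rows, orient="index", columns=aas)
    df.index.name = "id"
    return df


def axis_correlations(
    coords: pd.DataFrame,
    indices: list[UsageIndices],
    axes: tuple[str, ...] = ("axis1", "axis2"),
) -> pd.DataFrame:
    """Spearman rho/p of gene axis coordinates against usage indices.

    Tested indices: ENC, GC3, GRAVY, aromaticity, expression (where present)
    and protein length. Genes are aligned by id; needs >= 3 shared genes.
    """
    by_id = {ix.gene_id: ix for ix in indices}
    shared = [g for g in coords.index if g in by_id]
    if len(shared) < 3:
        raise ValueError("need >= 3 genes shared between coordinates and indices")
    variables = {
        "enc": [by_id[g].enc_obs for g in shared],
        "gc3": [by_id[g].gc3 for g in shared],
        "gravy": [by_id[g].gravy for g in shared],
        "aromo": [by_id[g].aromo for g in shared],
        "expression": [
            np.nan if by_id[g].expression is None else by_id[g].expression
            for g in shared
        ],
        "protein_length": [by_id[g].protein_length for g in shared],
    }
    rows = []
    for axis in axes:
        if axis not in coords.columns:
            continue
        x = coords.loc[shared, axis].values
        for name, vals in variables.items():
            v = np.asarray(vals, dtype=float)
            ok = ~np.isnan(v) & ~np.isnan(x)
            if ok.sum() < 3 or np.ptp(v[ok]) == 0 or np.ptp(x[ok]) == 0:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(x[ok], v[ok])
            rows.append({"axis": axis, "variable": name, "spearman_r": rho, "p_value": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def gc_class_labels(indices: list[UsageIndices]) -> pd.Series:
    """Gene GC-content band labels (<45%, 45-60%, >60%) for plot coloring."""
    def band(gc: float) -> str:
        if gc < 0.45:
            return "<45%"
        if gc <= 0.60:
            return "45-60%"
        return ">60%"

    return pd.Series({ix.gene_id: band(ix.gc) for ix in indices}, name="gc_class")
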