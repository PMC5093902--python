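"""Grouped comparisons: expression strata, functional categories, pathways, species.

Summaries are means/SDs of the positional GC contents and ENC per group,
with Welch two-sample t-tests for pairwise contrasts, plus agglomerative
clustering of species-level composition profiles (UPGMA by default, Newick
output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

CONTRAST_INDICES = ("gc1", "gc2", "gc3", "enc_obs")


@dataclass
class GroupSummary:
    """Mean/SD of the usage indices for one labeled gene group."""

    label: str
    n: int
    mean: dict[str, float]
    sd: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    flagged_small: bool = False


def _summary(label: str, df: pd.DataFrame, cols=CONTRAST_INDICES) -> GroupSummary:
    return GroupSummary(
        label=label,
        n=len(df),
        mean={c: float(df[c].mean()) for c in cols},
        sd={c: float(df[c].std(ddof=1)) if len(df) > 1 else 0.0 for c in cols},
    )


def compare_strata(
    high: pd.DataFrame,
    low: pd.DataFrame,
    labels: tuple[str, str] = ("high", "low"),
) -> tuple[GroupSummary, GroupSummary, pd.DataFrame]:
    """Contrast two gene strata on GC1/GC2/GC3/ENC with Welch t-tests.

    ``high``/``low`` are per-gene index tables (rows = genes, columns as in
    ``codon_core.indices_table``). Returns the two summaries and a tidy test
    table (index, t statistic, p-value). Identical strata give t = 0, p = 1.
    """
    s_high = _summary(labels[0], high)
    s_low = _summary(labels[1], low)
    rows = []
    for col in CONTRAST_INDICES:
        a = high[col].dropna().values
        b = low[col].dropna().values
        if len(a) < 2 or len(b) < 2:
            t, p = float("nan"), float("nan")
        elif np.array_equal(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"index": col, "t": float(t), "p_value": float(p)})
        s_high.p_values[col] = float(p)
    tests = pd.DataFrame(rows)
    return s_high, s_low, tests


def category_summary(
    genes: pd.DataFrame,
    annotation: dict[str, str],
    min_genes: int = 10,
) -> tuple[list[GroupSummary], pd.DataFrame]:
    """Per-category means plus across-category dispersion of those means.

    The dispersion table gives, for each index, the SD across category mean
    values — large GC3/ENC dispersion with flat GC1/GC2 indicates
    third-position (synonymous) divergence between functional classes.
    Categories with fewer than ``min_genes`` genes are summarized but
    flagged, and excluded from the dispersion calculation.
    """
    if not annotation:
        raise ValueError("empty annotation")
    labeled = genes.loc[genes.index.isin(annotation)]
    cats = pd.Series({g: annotation[g] for g in labeled.index}, name="category")
    summaries: list[GroupSummary] = []
    for cat in sorted(cats.unique()):
        sub = labeled.loc[cats[cats == cat].index]
        s = _summary(cat, sub)
        s.flagged_small = len(sub) < min_genes
        summaries.append(s)
    big = [s for s in summaries if not s.flagged_small]
    disp = pd.DataFrame(
        {
            "index": list(CONTRAST_INDICES),
            "sd_of_category_means": [
                float(np.std([s.mean[c] for s in big], ddof=1)) if len(big) > 1 else 0.0
                for c in CONTRAST_INDICES
            ],
        }
    )
    return summaries, disp


def pathway_updown_contrast(
    upstream: pd.DataFrame, downstream: pd.DataFrame
) -> tuple[GroupSummary, GroupSummary, pd.DataFrame]:
    """Upstream vs downstream pathway contrast (same contract as compare_strata)."""
    return compare_strata(downstream, upstream, labels=("downstream", "upstream"))


def summaries_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Flatten GroupSummary objects into a tidy table for TSV output."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {"group": s.label, "n": s.n, "flagged_small": s.flagged_small}
        for c in CONTRAST_INDICES:
            row[f"{c}_mean"] = s.mean[c]
            row[f"{c}_sd"] = s.sd[c]
            if c in s.p_values:
                row[f"{c}_p"] = s.p_values[c]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Species clustering
# ---------------------------------------------------------------------------


@dataclass
class SpeciesProfile:
    """Species-level feature vector (default: mean GC3, optionally more)."""

    name: str
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"{self.name}: non-finite features")


_LINKAGE = {"UPGMA": "average", "complete": "complete", "single": "single"}


def species_clustering(
    profiles: list[SpeciesProfile], linkage: str = "UPGMA"
) -> tuple[np.ndarray, str]:
    """Agglomerative clustering of species on Euclidean feature distance.

    Returns the scipy linkage matrix and a Newick serialization in which
    each branch length is the difference between child and parent merge
    heights (leaves sit at height 0). Species are pre-sorted by name so
    distance ties resolve deterministically.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 species")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names")
    lengths = {len(p.features) for p in profiles}
    if len(lengths) != 1:
        raise ValueError("feature vectors differ in length")
    profiles = sorted(profiles, key=lambda p: p.name)
    X = np.vstack([p.features for p in profiles])
    Z = hierarchy.linkage(pdist(X), method=_LINKAGE.get(linkage, linkage))
    return Z, _newick(Z, [p.name for p in profiles])


def _newick(Z: np.ndarray, names: list[str]) -> str:
    n = len(names)
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: names[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        idx = n + k
        node[idx] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[idx] = h
    return node[n + len(Z) - 1] + ";"
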