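import numpy as np
import pytest

from codonscape import (
    CdsRecord,
    CodonCountTable,
    SYNONYMOUS_FAMILIES,
    SyntheticConfig,
    compute_indices,
    generate,
)


def make_cds(codons: list[str], gene_id: str = "g", **kw) -> CdsRecord:
    """Build a CdsRecord from an explicit codon list."""
    return CdsRecord(id=gene_id, seq="".join(codons), **kw)


def uniform_counts(copies: int = 12) -> CodonCountTable:
    """Every sense codon of every degenerate family with equal counts."""
    counts = {c: copies for fam in SYNONYMOUS_FAMILIES.values() for c in fam}
    return CodonCountTable("uniform", counts)


def one_codon_per_family(copies: int = 50) -> CodonCountTable:
    """Maximal bias: a single codon per degenerate family."""
    return CodonCountTable(
        "biased", {fam[0]: copies for fam in SYNONYMOUS_FAMILIES.values()}
    )


@pytest.fixture(scope="session")
def mutation_dataset():
    """2,000 mutation-regime genes, p_GC ~ U(0.25, 0.75), fixed seed."""
    cfg = SyntheticConfig(seed=11, n_genes=2000, regime="mutation", gc_bias=(0.25, 0.75))
    return generate(cfg)


@pytest.fixture(scope="session")
def selection_dataset():
    cfg = SyntheticConfig(seed=11, n_genes=2000, regime="selection")
    return generate(cfg)


@pytest.fixture(scope="session")
def mutation_indices(mutation_dataset):
    return [compute_indices(r) for r in mutation_dataset.records]


@pytest.fixture(scope="session")
def selection_indices(selection_dataset):
    return [compute_indices(r) for r in selection_dataset.records]


@pytest.fixture(scope="session")
def small_dataset():
    """300 mutation-regime genes with expression, for fast pipeline tests."""
    cfg = SyntheticConfig(seed=5, n_genes=300, regime="mutation")
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
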