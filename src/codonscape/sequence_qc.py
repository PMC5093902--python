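"""CDS screening: validate candidate coding sequences before any index is computed.

Candidate CDS records (e.g. ORFs extracted from an assembled transcriptome)
are kept only if they are long enough, in frame, unambiguous, free of
internal stop codons and (optionally) start with ATG and end with a stop.
Each rejected record carries the first rule it failed, so the screen is an
auditable, deterministic filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Rejection reason codes, in the order the rules are applied.
TOO_SHORT = "TOO_SHORT"
NOT_MULTIPLE_OF_3 = "NOT_MULTIPLE_OF_3"
AMBIGUOUS_BASE = "AMBIGUOUS_BASE"
INTERNAL_STOP = "INTERNAL_STOP"
NO_START = "NO_START"
NO_TERMINAL_STOP = "NO_TERMINAL_STOP"

REASON_ORDER = (
    TOO_SHORT,
    NOT_MULTIPLE_OF_3,
    AMBIGUOUS_BASE,
    INTERNAL_STOP,
    NO_START,
    NO_TERMINAL_STOP,
)


@dataclass
class CdsRecord:
    """One coding sequence with optional expression value and category label.

    The sequence is uppercased and U-normalized to T on construction.
    """

    id: str
    seq: str
    expression: float | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        self.seq = self.seq.upper().replace("U", "T")
        if self.expression is not None and self.expression < 0:
            raise ValueError(f"{self.id}: negative expression")


@dataclass
class ScreenReport:
    """Outcome of screening: kept records plus (id, reason) rejections."""

    kept: list[CdsRecord]
    rejected: list[tuple[str, str]]

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)


def _first_failure(
    seq: str,
    min_length: int,
    require_start: bool,
    require_terminal_stop: bool,
    stop_codons: frozenset[str],
) -> str | None:
    if len(seq) < min_length:
        return TOO_SHORT
    if len(seq) % 3 != 0:
        return NOT_MULTIPLE_OF_3
    if set(seq) - set("ACGT"):
        return AMBIGUOUS_BASE
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if any(c in stop_codons for c in codons[:-1]):
        return INTERNAL_STOP
    if require_start and codons[0] != "ATG":
        return NO_START
    if require_terminal_stop and codons[-1] not in stop_codons:
        return NO_TERMINAL_STOP
    return None


def screen_cds(
    records: list[CdsRecord],
    min_length: int = 300,
    require_start: bool = True,
    require_terminal_stop: bool = False,
) -> ScreenReport:
    """Filter candidate CDS records, logging the first failed rule per rejection.

    Rules, in order: length >= ``min_length``; length divisible by 3; only
    A/C/G/T; no internal stop codon (a terminal stop is always tolerated);
    first codon ATG if ``require_start``; last codon a stop if
    ``require_terminal_stop``.
    """
    from .codon_core import STOP_CODONS

    if not records:
        raise ValueError("no records")
    if min_length < 3:
        raise ValueError(f"min_length must be >= 3, got {min_length}")
    kept: list[CdsRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        reason = _first_failure(
            rec.seq, min_length, require_start, require_terminal_stop, STOP_CODONS
        )
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec.id, reason))
    return ScreenReport(kept=kept, rejected=rejected)


def translate(record: CdsRecord) -> str:
    """Translate a screened CDS 5'->3' under the standard code.

    A terminal stop codon is dropped; an internal stop or ambiguous base is
    an error (such records should not have passed screening).
    """
    from .codon_core import STANDARD_CODE, STOP_CODONS

    seq = record.seq
    if len(seq) % 3 != 0:
        raise ValueError(f"{record.id}: length not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    protein = []
    for i, codon in enumerate(codons):
        aa = STANDARD_CODE.get(codon)
        if aa is None:
            raise ValueError(f"{record.id}: unrecognized codon {codon!r} at {i}")
        if aa == "*":
            raise ValueError(f"{record.id}: internal stop at codon {i}")
        protein.append(aa)
    return "".join(protein)


# -- FASTA / TSV plumbing ----------------------------------------------------


def read_fasta(path: str | Path) -> list[CdsRecord]:
    """Load CDS records from nucleotide FASTA; id = header token before whitespace."""
    return [CdsRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[CdsRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def write_rejection_log(report: ScreenReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\treason\n")
        for gene_id, reason in report.rejected:
            fh.write(f"{gene_id}\t{reason}\n")


def attach_expression(records: list[CdsRecord], table: dict[str, float]) -> None:
    """Attach FPKM-like expression values to records in place (missing -> None)."""
    for rec in records:
        rec.expression = table.get(rec.id)


def attach_categories(records: list[CdsRecord], table: dict[str, str]) -> None:
    for rec in records:
        rec.category = table.get(rec.id)
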