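"""Reading coding sequences and applying quality-control filters.

A usable CDS must look like a real protein-coding gene: unambiguous A/C/G/T
alphabet, a length that is a multiple of three, an ATG start, a single
terminal stop codon, no in-frame internal stops, and a minimum length
(300 nt by default, matching the common QC threshold for codon-usage work).
Every sequence receives a report listing *all* reasons it failed, so a QC
table can be audited instead of re-run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .genetic_code import START_CODON, STOP_CODONS

logger = logging.getLogger(__name__)

#: rejection codes, in the order they are evaluated
REASON_CODES = (
    "AMBIGUOUS_BASE",
    "GAP",
    "NOT_MULTIPLE_OF_3",
    "NO_START",
    "NO_STOP",
    "INTERNAL_STOP",
    "TOO_SHORT",
    "BLACKLISTED",
)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """One CDS: identifier plus an uppercase DNA sequence (U normalized to T)."""

    id: str
    seq: str

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    def codons(self) -> list[str]:
        """In-frame triplets from position 0 (includes the terminal stop)."""
        return [self.seq[i : i + 3] for i in range(0, len(self.seq) - 2, 3)]


@dataclass(frozen=True)
class QCReport:
    """QC outcome for one sequence; ``passed`` iff ``reasons`` is empty."""

    id: str
    reasons: tuple[str, ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return not self.reasons


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a (multi-record) FASTA file into CodingSequence records.

    Sequences are uppercased and the RNA alphabet is normalized to DNA.
    Record order is preserved. An empty file yields an empty list with a
    logged warning.
    """
    path = Path(path)
    records = [
        CodingSequence(id=rec.id, seq=str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


def _qc_reasons(seq: str, min_length_nt: int) -> tuple[str, ...]:
    reasons: list[str] = []
    bases = set(seq)
    if "-" in bases:
        reasons.append("GAP")
    if bases - _VALID_BASES - {"-"}:
        reasons.append("AMBIGUOUS_BASE")
    if len(seq) % 3 != 0:
        reasons.append("NOT_MULTIPLE_OF_3")
    if not seq.startswith(START_CODON):
        reasons.append("NO_START")
    if seq[-3:] not in STOP_CODONS:
        reasons.append("NO_STOP")
    # in-frame stops strictly before the final full triplet
    for i in range(0, len(seq) - 5, 3):
        if seq[i : i + 3] in STOP_CODONS:
            reasons.append("INTERNAL_STOP")
            break
    if len(seq) < min_length_nt:
        reasons.append("TOO_SHORT")
    return tuple(sorted(reasons, key=REASON_CODES.index))


def qc_filter(
    seqs: Sequence[CodingSequence],
    min_length_nt: int = 300,
    blacklist_ids: Iterable[str] | None = None,
) -> tuple[list[CodingSequence], list[QCReport]]:
    """Partition sequences into QC-passed and rejected, with full reports.

    A sequence passes iff it uses only A/C/G/T, has length a multiple of 3
    and >= ``min_length_nt``, begins with ATG, ends with a stop codon, has
    no internal in-frame stop, and is not blacklisted. Failure reasons are
    enumerated exhaustively, never short-circuited. The terminal stop codon
    counts toward length (GenBank CDS convention).
    """
    blacklist = frozenset(blacklist_ids or ())
    passed: list[CodingSequence] = []
    reports: list[QCReport] = []
    for s in seqs:
        reasons = _qc_reasons(s.seq, min_length_nt)
        if s.id in blacklist:
            reasons = reasons + ("BLACKLISTED",)
        reports.append(QCReport(id=s.id, reasons=reasons))
        if not reasons:
            passed.append(s)
    return passed, reports


def write_qc_report(reports: Sequence[QCReport], path: str | Path) -> None:
    """Write the QC table as TSV with columns id, passed, reasons."""
    with open(path, "w") as fh:
        fh.write("id\tpassed\treasons\n")
        for r in reports:
            fh.write(f"{r.id}\t{str(r.passed).lower()}\t{','.join(r.reasons)}\n")


def read_id_list(path: str | Path) -> list[str]:
    """Read one identifier per line, ignoring blanks and '#' comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
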