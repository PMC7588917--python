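"""Coding-sequence ingestion and validation.

A valid CDS has nucleotide length divisible by 3, no internal stop codons and
no ambiguity codes; a terminal stop codon is stripped and never counted.
Rejections are recorded per record with a reason code so a corpus load is
auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import GeneticCode, standard_code

logger = logging.getLogger(__name__)

#: reason codes used in validation reports
REASON_LENGTH = "length not multiple of 3"
REASON_INTERNAL_STOP = "internal stop"
REASON_AMBIGUOUS = "ambiguous or non-ACGT base"
REASON_EMPTY = "empty after terminal-stop strip"


class CDSFormatError(ValueError):
    pass


@dataclass(frozen=True)
class CodingSequence:
    """A validated CDS: ordered sense codons, terminal stop already stripped."""

    id: str
    codons: tuple[str, ...]

    @property
    def length(self) -> int:
        """Gene length in codifying codons (l_g)."""
        return len(self.codons)

    @property
    def sequence(self) -> str:
        return "".join(self.codons)


@dataclass
class ValidationReport:
    n_input: int = 0
    accepted: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    def summary(self) -> str:
        lines = [f"{self.n_input} records: {self.n_accepted} accepted, {len(self.rejected)} rejected"]
        counts: dict[str, int] = {}
        for _, reason in self.rejected:
            counts[reason] = counts.get(reason, 0) + 1
        lines.extend(f"  {reason}: {n}" for reason, n in sorted(counts.items()))
        return "\n".join(lines)


def validate_record(gene_id: str, seq: str, code: GeneticCode) -> CodingSequence | str:
    """Validate one nucleotide sequence; returns a CodingSequence or a reason code."""
    seq = seq.upper().replace("U", "T")
    if any(b not in "ACGT" for b in seq):
        return REASON_AMBIGUOUS
    if len(seq) % 3 != 0:
        return REASON_LENGTH
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and code.is_stop(codons[-1]):
        codons = codons[:-1]
    if not codons:
        return REASON_EMPTY
    if any(code.is_stop(c) for c in codons):
        return REASON_INTERNAL_STOP
    return CodingSequence(id=gene_id, codons=tuple(codons))


def load_cds(
    source: str | Path | TextIO,
    code: GeneticCode | None = None,
) -> tuple[list[CodingSequence], ValidationReport]:
    """Load a multi-FASTA of coding sequences.

    Parameters
    ----------
    source
        Path or text handle of a FASTA file, one CDS per record.

    Returns
    -------
    (genes, report)
        Accepted :class:`CodingSequence` objects in file order, plus a
        :class:`ValidationReport` listing every rejection with its reason.

    Raises
    ------
    CDSFormatError
        On an empty file or duplicate record ids.
    """
    code = code or standard_code()
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise CDSFormatError("no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CDSFormatError(f"duplicate record ids: {', '.join(dupes)}")

    report = ValidationReport(n_input=len(records))
    genes: list[CodingSequence] = []
    for rec in records:
        result = validate_record(rec.id, str(rec.seq), code)
        if isinstance(result, CodingSequence):
            genes.append(result)
            report.accepted.append(rec.id)
        else:
            report.rejected.append((rec.id, result))
            logger.warning("rejected CDS %s: %s", rec.id, result)
    return genes, report


def write_cds(genes: Iterable[CodingSequence], path: str | Path) -> None:
    """Write coding sequences back out as FASTA (no stop codons re-appended)."""
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genes]
    SeqIO.write(records, str(path), "fasta")
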