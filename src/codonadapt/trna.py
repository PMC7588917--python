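"""tRNA gene-copy table: tRNAscan-SE parsing, summaries, and tGCN derivation.

The parser targets the classic tRNAscan-SE tabular output (sequence name,
tRNA #, begin, end, isotype, anticodon, intron begin/end, score, optional
note). Pseudogene calls and undetermined anticodons are dropped with a
warning; everything retained contributes one gene copy to its anticodon's
tGCN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import pandas as pd

from .genetic_code import GeneticCode, anticodon_to_codon, standard_code

logger = logging.getLogger(__name__)

# three-letter isotype names as printed by tRNAscan-SE, mapped to one-letter
_ISOTYPE_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "SeC": None, "Sup": None, "Undet": None,
    "Pseudo": None, "iMet": "M", "fMet": "M",
}
_ISOTYPE_1TO3 = {v: k for k, v in _ISOTYPE_3TO1.items() if v is not None and len(k) == 3}


class TRNAScanFormatError(ValueError):
    pass


@dataclass(frozen=True)
class TRNAGene:
    scaffold: str
    index: int
    isotype: str  # one-letter amino acid as predicted by the scanner
    anticodon: str
    begin: int = 0
    end: int = 0
    intron_begin: int = 0
    intron_end: int = 0
    score: float = 0.0

    @property
    def has_intron(self) -> bool:
        return not (self.intron_begin == 0 and self.intron_end == 0)

    @property
    def decoded_codon(self) -> str:
        """The Watson–Crick codon read by this gene's anticodon."""
        return anticodon_to_codon(self.anticodon)


@dataclass
class TRNAGeneSet:
    """Retained tRNA genes plus the derived anticodon -> tGCN map."""

    genes: list[TRNAGene]
    warnings: list[str] = field(default_factory=list)
    code: GeneticCode = field(default_factory=standard_code, repr=False)

    @property
    def tgcn(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.genes:
            out[g.anticodon] = out.get(g.anticodon, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.genes)

    def check_isotype_concordance(self) -> list[TRNAGene]:
        """Genes whose scanner isotype disagrees with their anticodon's codon.

        tGCN is anticodon-driven, so discordant genes are kept but reported:
        the anticodon wins for all adaptiveness computations.
        """
        discordant = []
        for g in self.genes:
            codon_aa = self.code.translate(g.decoded_codon)
            if codon_aa != g.isotype:
                discordant.append(g)
        return discordant


def _is_undetermined(anticodon: str) -> bool:
    return anticodon in ("NNN", "???") or any(b not in "ACGT" for b in anticodon)


def parse_trnascan(source: str | Path | TextIO) -> TRNAGeneSet:
    """Parse tRNAscan-SE tabular output into a :class:`TRNAGeneSet`.

    Rows typed ``Pseudo`` (or noted as pseudogenes) and rows whose anticodon is
    undetermined are dropped with a warning. Malformed rows raise with their
    line number. An empty file yields an empty set plus a warning.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()

    genes: list[TRNAGene] = []
    warnings: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        # header block: column-name lines and the dashed separator
        stripped = line.strip()
        if stripped.startswith(("Sequence", "Name", "--")):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            fields = line.split()
        if len(fields) < 9:
            raise TRNAScanFormatError(f"line {lineno}: expected >=9 columns, got {len(fields)}")
        try:
            scaffold = fields[0].strip()
            index = int(fields[1])
            begin, end = int(fields[2]), int(fields[3])
            isotype3 = fields[4].strip()
            anticodon = fields[5].strip().upper().replace("U", "T")
            intron_begin, intron_end = int(fields[6]), int(fields[7])
            score = float(fields[8])
        except ValueError as exc:
            raise TRNAScanFormatError(f"line {lineno}: {exc}") from exc
        note = fields[9].strip().lower() if len(fields) > 9 else ""

        if isotype3 == "Pseudo" or "pseudo" in note:
            warnings.append(f"line {lineno}: dropped pseudogene call ({scaffold} #{index})")
            continue
        if _is_undetermined(anticodon):
            warnings.append(
                f"line {lineno}: dropped undetermined anticodon {anticodon!r} ({scaffold} #{index})"
            )
            continue
        isotype1 = _ISOTYPE_3TO1.get(isotype3)
        if isotype1 is None:
            warnings.append(f"line {lineno}: dropped non-standard isotype {isotype3!r}")
            continue
        genes.append(
            TRNAGene(
                scaffold=scaffold,
                index=index,
                isotype=isotype1,
                anticodon=anticodon,
                begin=begin,
                end=end,
                intron_begin=intron_begin,
                intron_end=intron_end,
                score=score,
            )
        )
    if not genes:
        warnings.append("no tRNA genes retained")
    for w in warnings:
        logger.warning("%s", w)
    return TRNAGeneSet(genes=genes, warnings=warnings)


def write_trnascan(geneset: TRNAGeneSet, path: str | Path) -> None:
    """Write a gene set back out in tRNAscan-SE tabular layout."""
    with open(path, "w") as fh:
        fh.write("Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\t\tInf\n")
        fh.write("Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n")
        fh.write("--------\t------\t-----\t----\t----\t-----\t-----\t----\t------\n")
        for g in geneset.genes:
            fh.write(
                f"{g.scaffold}\t{g.index}\t{g.begin}\t{g.end}\t"
                f"{_ISOTYPE_1TO3[g.isotype]}\t{g.anticodon}\t"
                f"{g.intron_begin}\t{g.intron_end}\t{g.score:.1f}\n"
            )


def summarize_trna_set(geneset: TRNAGeneSet) -> pd.DataFrame:
    """Per-amino-acid summary: gene count, anticodon frequencies, scaffolds, introns.

    Anticodon frequencies are rendered superscript-style ("GCC^12, TCC^3") in
    the ``anticodons`` column; the numeric map is in ``anticodon_counts``.
    """
    if not geneset.genes:
        raise ValueError("cannot summarize an empty tRNA gene set")
    rows = []
    by_aa: dict[str, list[TRNAGene]] = {}
    for g in geneset.genes:
        by_aa.setdefault(g.isotype, []).append(g)
    for aa in sorted(by_aa):
        genes = by_aa[aa]
        anti_counts: dict[str, int] = {}
        for g in genes:
            anti_counts[g.anticodon] = anti_counts.get(g.anticodon, 0) + 1
        rows.append(
            {
                "aa": aa,
                "isotype": _ISOTYPE_1TO3[aa],
                "n_genes": len(genes),
                "anticodons": ", ".join(f"{a}^{n}" for a, n in sorted(anti_counts.items())),
                "anticodon_counts": anti_counts,
                "n_scaffolds": len({g.scaffold for g in genes}),
                "n_with_introns": sum(g.has_intron for g in genes),
            }
        )
    return pd.DataFrame(rows)
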