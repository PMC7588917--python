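"""Genetic-code algebra: codon translation, synonymous families, anticodon decoding.

Only the standard nuclear code (NCBI translation table 1) ships tested; other
table ids are accepted but the downstream index definitions (degeneracy classes
for Nc, wobble rules) assume the standard code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

STOP = "*"

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidCodonError(ValueError):
    """Raised for strings that are not uppercase DNA 3-mers over ACGT."""


def _check_triplet(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3 or any(b not in _BASES for b in codon):
        raise InvalidCodonError(f"not an uppercase DNA 3-mer over ACGT: {codon!r}")
    return codon


def reverse_complement(seq: str) -> str:
    for b in seq:
        if b not in _BASES:
            raise InvalidCodonError(f"invalid base {b!r} in {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with its synonymous-family structure.

    Amino acids are one-letter IUPAC codes; stops translate to ``"*"``.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...]
    stop_codons: tuple[str, ...]
    families: dict[str, tuple[str, ...]] = field(repr=False)

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = {c: aa for c, aa in table.forward_table.items()}
        stops = tuple(sorted(table.stop_codons))
        for s in stops:
            codon_to_aa[s] = STOP
        sense = tuple(sorted(c for c in codon_to_aa if codon_to_aa[c] != STOP))
        families: dict[str, list[str]] = {}
        for c in sense:
            families.setdefault(codon_to_aa[c], []).append(c)
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            sense_codons=sense,
            stop_codons=stops,
            families={aa: tuple(cs) for aa, cs in families.items()},
        )

    def __post_init__(self) -> None:
        if self.table_id == 1:
            assert len(self.sense_codons) == 61 and len(self.stop_codons) == 3
            assert all(len(f) in (1, 2, 3, 4, 6) for f in self.families.values())

    def translate(self, codon: str) -> str:
        """Translate a codon; stops return ``"*"``."""
        return self.codon_to_aa[_check_triplet(codon)]

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == STOP

    def family_of(self, codon: str) -> tuple[str, ...]:
        """All sense codons synonymous with ``codon`` (including itself)."""
        aa = self.translate(codon)
        if aa == STOP:
            raise InvalidCodonError(f"stop codon {codon} has no synonymous family")
        return self.families[aa]


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (translation table 1)."""
    return GeneticCode.from_ncbi_id(1)


def translate_codon(codon: str, code: GeneticCode | None = None) -> str:
    """Translate one codon under the standard code; ``"*"`` for stops."""
    return (code or standard_code()).translate(codon)


def anticodon_to_codon(anticodon: str) -> str:
    """Watson–Crick decode: the codon perfectly paired with this anticodon.

    Both are read 5'->3', so the perfectly paired codon is the reverse
    complement (e.g. Gly anticodon GCC reads codon GGC).
    """
    return reverse_complement(_check_triplet(anticodon))


def codon_to_anticodon(codon: str) -> str:
    """Inverse of :func:`anticodon_to_codon`."""
    return reverse_complement(_check_triplet(codon))
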