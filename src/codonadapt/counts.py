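"""Codon and codon-pair counting over a CDS corpus, with RSCU.

Frequencies follow the parts-per-thousand convention: f(A) is per thousand
codons, f(AB) per thousand ordered adjacent pairs, f(X)/f(XY) per thousand
amino acids / amino-acid pairs. Pairs never span gene boundaries and stop
codons never appear (terminal stops are stripped at load time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cds import CodingSequence
from .genetic_code import GeneticCode, standard_code


class EmptyCorpusError(ValueError):
    pass


@dataclass(frozen=True)
class CodonCountTable:
    """Corpus codon counts with per-thousand frequencies f(A)."""

    counts: Mapping[str, int]
    code: GeneticCode = field(default_factory=standard_code, repr=False)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def per_thousand(self, codon: str) -> float:
        """f(codon) in parts per thousand of all counted codons."""
        return 1000.0 * self.count(codon) / self.total

    def aa_count(self, aa: str) -> int:
        return sum(self.count(c) for c in self.code.families[aa])

    def aa_per_thousand(self, aa: str) -> float:
        """f(X): amino-acid frequency per thousand residues."""
        return 1000.0 * self.aa_count(aa) / self.total

    def to_frame(self) -> pd.DataFrame:
        """EMBOSS cusp-compatible table: Codon, AA, Fraction, Frequency, Number."""
        rows = []
        for codon in self.code.sense_codons:
            aa = self.code.translate(codon)
            fam_total = self.aa_count(aa)
            rows.append(
                {
                    "Codon": codon,
                    "AA": aa,
                    "Fraction": self.count(codon) / fam_total if fam_total else np.nan,
                    "Frequency": self.per_thousand(codon),
                    "Number": self.count(codon),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CodonPairStats:
    """Ordered adjacent sense-codon pair counts with f(AB) and f(XY)."""

    pair_counts: Mapping[tuple[str, str], int]
    code: GeneticCode = field(default_factory=standard_code, repr=False)

    @property
    def total_pairs(self) -> int:
        return sum(self.pair_counts.values())

    def count(self, a: str, b: str) -> int:
        return self.pair_counts.get((a, b), 0)

    def per_thousand(self, a: str, b: str) -> float:
        """f(AB) per thousand ordered codon pairs."""
        return 1000.0 * self.count(a, b) / self.total_pairs

    def aa_pair_counts(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for (a, b), n in self.pair_counts.items():
            key = (self.code.translate(a), self.code.translate(b))
            out[key] = out.get(key, 0) + n
        return out

    def aa_pair_per_thousand(self, x: str, y: str) -> float:
        """f(XY) per thousand amino-acid pairs; aggregates all codon pairs coding XY."""
        n = sum(
            cnt
            for (a, b), cnt in self.pair_counts.items()
            if self.code.translate(a) == x and self.code.translate(b) == y
        )
        return 1000.0 * n / self.total_pairs

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"codonA": a, "codonB": b, "count": n, "f_AB": 1000.0 * n / self.total_pairs}
            for (a, b), n in sorted(self.pair_counts.items())
        ]
        return pd.DataFrame(rows)


def count_codons(genes: Sequence[CodingSequence], code: GeneticCode | None = None) -> CodonCountTable:
    """Aggregate codon counts over all genes; f(A) = 1000 * count / total."""
    code = code or standard_code()
    if not genes:
        raise EmptyCorpusError("cannot count codons over an empty gene set")
    counts: dict[str, int] = {}
    for g in genes:
        for c in g.codons:
            counts[c] = counts.get(c, 0) + 1
    return CodonCountTable(counts=counts, code=code)


def count_codon_pairs(genes: Sequence[CodingSequence], code: GeneticCode | None = None) -> CodonPairStats:
    """Count every ordered adjacent codon pair within each gene (l_g - 1 per gene)."""
    code = code or standard_code()
    pair_counts: dict[tuple[str, str], int] = {}
    n_pairs = 0
    for g in genes:
        for a, b in zip(g.codons, g.codons[1:]):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
            n_pairs += 1
    if n_pairs == 0:
        raise EmptyCorpusError("no codon pairs: every gene has fewer than 2 codons")
    return CodonPairStats(pair_counts=pair_counts, code=code)


def compute_rscu(table: CodonCountTable) -> tuple[dict[str, float], set[str]]:
    """Relative synonymous codon usage.

    RSCU_c = count_c / (mean count over c's synonymous family). Families with
    zero total usage are flagged (returned in the second element) and their
    codons carry NaN rather than 0, so "never observed" is distinguishable
    from "observed family, unused codon".
    """
    code = table.code
    rscu: dict[str, float] = {}
    unobserved: set[str] = set()
    for aa, family in code.families.items():
        fam_total = sum(table.count(c) for c in family)
        if fam_total == 0:
            unobserved.add(aa)
            for c in family:
                rscu[c] = float("nan")
            continue
        mean = fam_total / len(family)
        for c in family:
            rscu[c] = table.count(c) / mean
    return rscu, unobserved
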