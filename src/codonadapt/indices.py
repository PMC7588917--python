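"""Per-gene adaptation and bias indices: CAI, Nc, CPS/CPB, tAI, AAtAI, Z-scores.

Conventions
-----------
* CAI weights come from the input corpus itself (genome-wide usage), not a
  curated highly-expressed set; the geometric mean runs over *all* codons of
  a gene including Met/Trp (EMBOSS convention). A Sharp–Li style exclusion of
  single-codon families is available via ``exclude_single_families``.
* Nc is Wright's effective number of codons with the CodonW missing-class
  imputation and a cap at 61; Ile forms its own 3-fold class.
* CPS uses the natural log of the amino-acid-pair-corrected independence
  ratio; CPB is the arithmetic mean of CPS over a gene's l_g - 1 adjacent
  pairs.
* tAI and AAtAI are geometric means of w_i and AAw_i respectively.
* Z-scores standardize each index against the whole gene set using the
  population SD (n denominator).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adaptiveness import AdaptivenessVector
from .cds import CodingSequence
from .counts import CodonCountTable, CodonPairStats
from .genetic_code import GeneticCode, standard_code


class IndexError_(ValueError):
    """Raised when an index is requested on inputs it is undefined for."""


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------

def cai_weights(
    counts: CodonCountTable,
    zero_floor: float = 0.01,
    code: GeneticCode | None = None,
) -> dict[str, float]:
    """Relative-adaptiveness weights for CAI from a reference usage table.

    weight_c = f(c) / max f over c's synonymous family; codons never observed
    get ``zero_floor`` (relative to the family max of 1), the EMBOSS floor.

    Raises
    ------
    IndexError_
        If a synonymous family is entirely absent from the reference corpus.
    """
    code = code or standard_code()
    weights: dict[str, float] = {}
    for aa, family in code.families.items():
        fam_counts = {c: counts.count(c) for c in family}
        fam_max = max(fam_counts.values())
        if fam_max == 0:
            raise IndexError_(f"family {aa} entirely absent from the reference corpus")
        for c, n in fam_counts.items():
            weights[c] = n / fam_max if n > 0 else zero_floor
    return weights


def compute_cai(
    gene: CodingSequence,
    weights: Mapping[str, float],
    exclude_single_families: bool = False,
    code: GeneticCode | None = None,
) -> float:
    """Geometric mean of CAI weights over the gene's codons."""
    code = code or standard_code()
    if gene.length == 0:
        raise IndexError_(f"gene {gene.id}: zero-length gene")
    if exclude_single_families:
        codons = [c for c in gene.codons if len(code.family_of(c)) > 1]
        if not codons:
            raise IndexError_(f"gene {gene.id}: no multi-codon-family codons")
    else:
        codons = list(gene.codons)
    return float(math.exp(sum(math.log(weights[c]) for c in codons) / len(codons)))


# ---------------------------------------------------------------------------
# Nc (Wright's effective number of codons)
# ---------------------------------------------------------------------------

def _family_homozygosity(fam_counts: Sequence[int]) -> float | None:
    """Wright's F-hat for one family; None when usage count n < 2 or F == 0."""
    n = sum(fam_counts)
    if n < 2:
        return None
    p_sq = sum((c / n) ** 2 for c in fam_counts)
    f_hat = (n * p_sq - 1.0) / (n - 1.0)
    return f_hat if f_hat > 0 else None


def compute_nc(gene: CodingSequence, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons for one gene; NaN when undefined.

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with Fk the mean homozygosity of the
    degeneracy-k families usable in the gene (usage >= 2, F > 0). A missing
    3-fold class (Ile) is imputed as the mean of F2 and F4 (CodonW
    convention); a missing 2-, 4- or 6-fold class makes Nc undefined. The
    result is capped at 61.
    """
    code = code or standard_code()
    usage = Counter(gene.codons)
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for family in code.families.values():
        k = len(family)
        if k == 1:
            continue
        f_hat = _family_homozygosity([usage.get(c, 0) for c in family])
        if f_hat is not None:
            class_f[k].append(f_hat)

    n_families = {2: 9, 3: 1, 4: 5, 6: 3}
    mean_f: dict[int, float] = {}
    for k in (2, 4, 6):
        if not class_f[k]:
            return float("nan")
        mean_f[k] = float(np.mean(class_f[k]))
    mean_f[3] = (
        float(np.mean(class_f[3])) if class_f[3] else (mean_f[2] + mean_f[4]) / 2.0
    )

    nc = 2.0 + sum(n_families[k] / mean_f[k] for k in (2, 3, 4, 6))
    return min(nc, 61.0)


# ---------------------------------------------------------------------------
# CPS / CPB
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CPSTable:
    """Codon-pair scores over a reference corpus.

    ``scores`` holds CPS for every pair observed in the corpus (plus, in
    pseudocount mode, unobserved pairs whose amino-acid pair is scorable);
    ``unobserved`` flags pairs that needed the pseudocount.
    """

    scores: Mapping[tuple[str, str], float]
    unobserved: frozenset[tuple[str, str]] = frozenset()
    pseudocount: float = 0.0
    code: GeneticCode = field(default_factory=standard_code, repr=False)

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise IndexError_(f"codon pair ({a},{b}) absent from the CPS table") from None

    def to_frame(self, pairs: CodonPairStats | None = None) -> pd.DataFrame:
        rows = []
        for (a, b), cps in sorted(self.scores.items()):
            row = {"codonA": a, "codonB": b, "CPS": cps, "unobserved": (a, b) in self.unobserved}
            if pairs is not None:
                row["count"] = pairs.count(a, b)
                row["f_AB"] = pairs.per_thousand(a, b)
            rows.append(row)
        return pd.DataFrame(rows)


def build_cps_table(
    pairs: CodonPairStats,
    counts: CodonCountTable,
    pseudocount: float = 0.0,
    code: GeneticCode | None = None,
) -> CPSTable:
    """CPS(AB) = ln[ f(AB)/(f(A) f(B)) * (f(X) f(Y))/f(XY) ], per-thousand units.

    With ``pseudocount = 0`` (strict, the default) only pairs observed in the
    corpus are scored; unobserved pairs are simply absent (flagged downstream,
    never -inf). A positive pseudocount (0.5 in lenient mode) is added to the
    pair count of every unobserved sense-codon pair whose amino-acid pair has
    nonzero frequency.
    """
    code = code or standard_code()
    total_pairs = pairs.total_pairs

    # per-thousand building blocks
    f_codon = {c: counts.per_thousand(c) for c in code.sense_codons}
    f_aa = {aa: counts.aa_per_thousand(aa) for aa in code.families}
    aa_pair_counts = pairs.aa_pair_counts()
    f_aa_pair = {k: 1000.0 * n / total_pairs for k, n in aa_pair_counts.items()}

    scores: dict[tuple[str, str], float] = {}
    unobserved: set[tuple[str, str]] = set()

    def cps_from(f_ab: float, a: str, b: str) -> float:
        x, y = code.translate(a), code.translate(b)
        f_xy = f_aa_pair.get((x, y), 0.0)
        if f_xy == 0.0:
            raise IndexError_(
                f"internal inconsistency: pair ({a},{b}) observed but amino-acid "
                f"pair ({x},{y}) has zero frequency"
            )
        return math.log((f_ab / (f_codon[a] * f_codon[b])) * (f_aa[x] * f_aa[y] / f_xy))

    for (a, b), n in pairs.pair_counts.items():
        scores[(a, b)] = cps_from(1000.0 * n / total_pairs, a, b)

    if pseudocount > 0:
        for a in code.sense_codons:
            for b in code.sense_codons:
                if (a, b) in scores:
                    continue
                x, y = code.translate(a), code.translate(b)
                if (x, y) not in aa_pair_counts:
                    continue  # amino-acid pair itself unseen: still unscorable
                if f_codon[a] == 0.0 or f_codon[b] == 0.0:
                    continue
                scores[(a, b)] = cps_from(1000.0 * pseudocount / total_pairs, a, b)
                unobserved.add((a, b))

    return CPSTable(
        scores=scores,
        unobserved=frozenset(unobserved),
        pseudocount=pseudocount,
        code=code,
    )


def compute_cpb(gene: CodingSequence, cps: CPSTable) -> float:
    """Mean CPS over the gene's l_g - 1 adjacent codon pairs; NaN if l_g < 2.

    In strict mode (no pseudocount) a gene pair missing from the table raises,
    naming the pair.
    """
    if gene.length < 2:
        return float("nan")
    total = 0.0
    for a, b in zip(gene.codons, gene.codons[1:]):
        total += cps.score(a, b)
    return total / (gene.length - 1)


# ---------------------------------------------------------------------------
# tAI / AAtAI
# ---------------------------------------------------------------------------

def _geomean_over_gene(gene: CodingSequence, weights: Mapping[str, float]) -> float:
    if gene.length == 0:
        raise IndexError_(f"gene {gene.id}: zero-length gene")
    return float(math.exp(sum(math.log(weights[c]) for c in gene.codons) / gene.length))


def compute_tai(gene: CodingSequence, adapt: AdaptivenessVector) -> float:
    """tAI: geometric mean of w_i = W_i/W_max over the gene's codons."""
    return _geomean_over_gene(gene, adapt.w)


def compute_aatai(gene: CodingSequence, adapt: AdaptivenessVector) -> float:
    """AAtAI: geometric mean of AAw_i = W_i/W_AAmax over the gene's codons."""
    return _geomean_over_gene(gene, adapt.aa_w)


# ---------------------------------------------------------------------------
# Z-normalization and the per-gene table
# ---------------------------------------------------------------------------

INDEX_COLUMNS = ["CAI", "Nc", "tAI", "AAtAI", "CPB"]


def zscore_indices(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Add Z_<index> columns: (x - mean)/SD per index over the whole gene set.

    Population SD (n denominator); genes with an undefined value are excluded
    from that index's moments and keep NaN for its Z. A zero-SD index raises.
    """
    columns = list(columns) if columns is not None else [c for c in INDEX_COLUMNS if c in table]
    out = table.copy()
    for col in columns:
        values = out[col].to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size < 2:
            raise IndexError_(f"index {col}: need >=2 finite values for Z-scores")
        sd = float(np.std(finite))  # population convention
        if sd == 0:
            raise IndexError_(f"index {col}: zero standard deviation")
        out[f"Z_{col}"] = (values - finite.mean()) / sd
    return out


def gene_index_table(
    genes: Sequence[CodingSequence],
    counts: CodonCountTable,
    adapt: AdaptivenessVector | None = None,
    cps: CPSTable | None = None,
    zscores: bool = True,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Per-gene index table (id, l_g, CAI, Nc, tAI, AAtAI, CPB + Z columns).

    ``adapt`` and ``cps`` are optional: without a tRNA pool the tAI/AAtAI
    columns are omitted; without a CPS table the CPB column is omitted.
    """
    code = code or standard_code()
    weights = cai_weights(counts, code=code)
    rows = []
    for g in genes:
        row: dict[str, object] = {
            "id": g.id,
            "l_g": g.length,
            "CAI": compute_cai(g, weights, code=code),
            "Nc": compute_nc(g, code=code),
        }
        if adapt is not None:
            row["tAI"] = compute_tai(g, adapt)
            row["AAtAI"] = compute_aatai(g, adapt)
        if cps is not None:
            row["CPB"] = compute_cpb(g, cps)
        rows.append(row)
    table = pd.DataFrame(rows)
    if zscores:
        table = zscore_indices(table)
    return table
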