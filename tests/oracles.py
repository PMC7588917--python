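"""Independent brute-force transcriptions of every index formula.

These deliberately share no code with the package: plain loops, explicit
formula transcription, no numpy vectorization. They serve as oracles in the
equivalence tests — if an implementation and its oracle agree to 1e-10 on
arbitrary corpora, an algebra error would have to be present in both.
"""

from __future__ import annotations

import math
from collections import Counter

# --- genetic code written out by hand (standard nuclear code) --------------

_BASES = "TCAG"
_AA_TABLE = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)


def oracle_translate(codon: str) -> str:
    i = _BASES.index(codon[0]) * 16 + _BASES.index(codon[1]) * 4 + _BASES.index(codon[2])
    return _AA_TABLE[i]


SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if oracle_translate(a + b + c) != "*"
]

FAMILIES: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    FAMILIES.setdefault(oracle_translate(_c), []).append(_c)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    return "".join(comp[b] for b in reversed(seq))


# --- CAI --------------------------------------------------------------------

def oracle_cai_weights(codon_counts: dict[str, int], floor: float = 0.01) -> dict[str, float]:
    weights = {}
    for fam in FAMILIES.values():
        fam_max = max(codon_counts.get(c, 0) for c in fam)
        for c in fam:
            n = codon_counts.get(c, 0)
            weights[c] = (n / fam_max) if n > 0 else floor
    return weights


def oracle_cai(codons: list[str], weights: dict[str, float]) -> float:
    # geometric mean via logs (a direct product underflows on long genes)
    log_sum = 0.0
    for c in codons:
        log_sum += math.log(weights[c])
    return math.exp(log_sum / len(codons))


# --- Nc (Wright) ------------------------------------------------------------

def oracle_nc(codons: list[str]) -> float:
    usage = Counter(codons)
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for fam in FAMILIES.values():
        k = len(fam)
        if k == 1:
            continue
        n = sum(usage.get(c, 0) for c in fam)
        if n < 2:
            continue
        s = sum((usage.get(c, 0) / n) ** 2 for c in fam)
        f_hat = (n * s - 1.0) / (n - 1.0)
        if f_hat > 0:
            f_by_class[k].append(f_hat)

    means: dict[int, float] = {}
    for k in (2, 4, 6):
        if not f_by_class[k]:
            return float("nan")
        means[k] = sum(f_by_class[k]) / len(f_by_class[k])
    if f_by_class[3]:
        means[3] = sum(f_by_class[3]) / len(f_by_class[3])
    else:
        means[3] = (means[2] + means[4]) / 2.0
    nc = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(nc, 61.0)


# --- W_i / tAI / AAtAI ------------------------------------------------------

# wobble expansion re-transcribed from the rule definitions: third codon base
# -> (anticodon wobble base, constraint)
_WOBBLE = {"T": ("G", 0.41), "C": ("A", 0.28), "A": ("A", 0.9999), "G": ("T", 0.68)}


def oracle_recognizers(codon: str) -> list[tuple[str, float]]:
    pairs = [(_revcomp(codon), 0.0)]
    if codon not in ("ATG", "TGG"):
        wb, s = _WOBBLE[codon[2]]
        pairs.append((wb + _revcomp(codon)[1:], s))
    if codon == "ATA":
        pairs.append(("CAT", 0.89))
    return pairs


def oracle_w_vectors(tgcn: dict[str, int]) -> tuple[dict[str, float], dict[str, float]]:
    """(w, AAw) per sense codon, with the zero-W geometric-mean substitution."""
    W = {}
    for codon in SENSE_CODONS:
        W[codon] = sum((1.0 - s) * tgcn.get(anti, 0) for anti, s in oracle_recognizers(codon))
    w_max = max(W.values())
    w = {c: W[c] / w_max for c in SENSE_CODONS}
    aa_w = {}
    for fam in FAMILIES.values():
        fam_max = max(W[c] for c in fam)
        for c in fam:
            aa_w[c] = W[c] / fam_max if fam_max > 0 else 0.0

    nonzero_w = [v for v in w.values() if v > 0]
    nonzero_aa = [v for v in aa_w.values() if v > 0]
    w_fill = math.exp(sum(math.log(v) for v in nonzero_w) / len(nonzero_w))
    aa_fill = math.exp(sum(math.log(v) for v in nonzero_aa) / len(nonzero_aa))
    for c in SENSE_CODONS:
        if w[c] == 0:
            w[c] = w_fill
        if aa_w[c] == 0:
            aa_w[c] = aa_fill
    return w, aa_w


def oracle_geomean_index(codons: list[str], weights: dict[str, float]) -> float:
    log_sum = 0.0
    for c in codons:
        log_sum += math.log(weights[c])
    return math.exp(log_sum / len(codons))


# --- CPS / CPB --------------------------------------------------------------

def oracle_cps_table(gene_codon_lists: list[list[str]]) -> dict[tuple[str, str], float]:
    codon_counts: Counter = Counter()
    pair_counts: Counter = Counter()
    for codons in gene_codon_lists:
        for c in codons:
            codon_counts[c] += 1
        for a, b in zip(codons, codons[1:]):
            pair_counts[(a, b)] += 1
    total_codons = sum(codon_counts.values())
    total_pairs = sum(pair_counts.values())

    aa_counts: Counter = Counter()
    for c, n in codon_counts.items():
        aa_counts[oracle_translate(c)] += n
    aa_pair_counts: Counter = Counter()
    for (a, b), n in pair_counts.items():
        aa_pair_counts[(oracle_translate(a), oracle_translate(b))] += n

    table = {}
    for (a, b), n_ab in pair_counts.items():
        f_ab = 1000.0 * n_ab / total_pairs
        f_a = 1000.0 * codon_counts[a] / total_codons
        f_b = 1000.0 * codon_counts[b] / total_codons
        x, y = oracle_translate(a), oracle_translate(b)
        f_x = 1000.0 * aa_counts[x] / total_codons
        f_y = 1000.0 * aa_counts[y] / total_codons
        f_xy = 1000.0 * aa_pair_counts[(x, y)] / total_pairs
        table[(a, b)] = math.log((f_ab / (f_a * f_b)) * ((f_x * f_y) / f_xy))
    return table


def oracle_cpb(codons: list[str], cps: dict[tuple[str, str], float]) -> float:
    scores = [cps[(a, b)] for a, b in zip(codons, codons[1:])]
    return sum(scores) / (len(codons) - 1)


# --- RSCU -------------------------------------------------------------------

def oracle_rscu(codon_counts: dict[str, int]) -> dict[str, float]:
    rscu = {}
    for fam in FAMILIES.values():
        total = sum(codon_counts.get(c, 0) for c in fam)
        for c in fam:
            rscu[c] = codon_counts.get(c, 0) * len(fam) / total if total else float("nan")
    return rscu
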