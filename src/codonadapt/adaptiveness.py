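"""Per-codon adaptiveness to the tRNA pool under wobble rules.

The absolute adaptiveness of codon i is

    W_i = sum_j (1 - S_ij) * tGCN_ij

over the n_i isoacceptor anticodons that recognize it: the Watson–Crick
anticodon (S = 0) plus wobble partners whose selective constraints S_ij come
from a configurable rule set. Derived quantities:

    w_i      = W_i / W_max                (relative adaptiveness, tAI weight)
    AAw_i    = W_i / W_AAmax              (relative to the best codon of the
                                           same synonymous family, AAtAI weight)
    Wfam_i   = W_i / sum_family W_j       (family-normalized share; optionally
                                           scaled by family size)

Codons left with W_i = 0 by the pool receive the geometric mean of the
non-zero w (resp. AAw) values, the reference tAI convention — a hard zero
would annihilate the geometric mean of any gene containing that codon. The
substitution is flagged in the vector's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml

from .genetic_code import (
    GeneticCode,
    InvalidCodonError,
    codon_to_anticodon,
    standard_code,
)
from .trna import TRNAGeneSet


@dataclass(frozen=True)
class WobbleRule:
    anticodon: str
    s: float
    label: str


@dataclass(frozen=True)
class WobbleRuleSet:
    """Recognition rules: codon -> recognizing anticodons with constraints S_ij."""

    generic: Mapping[str, dict]
    special: Mapping[str, dict]

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "WobbleRuleSet":
        if path is None:
            text = resources.files("codonadapt.data").joinpath("wobble_rules.yaml").read_text()
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls(generic=raw["generic"], special=raw.get("special", {}))

    def recognizers(self, codon: str, code: GeneticCode | None = None) -> list[WobbleRule]:
        """All anticodons recognizing ``codon`` with their S_ij (WC first)."""
        code = code or standard_code()
        if code.is_stop(codon):
            raise InvalidCodonError(f"stop codon {codon} is never decoded")
        rules = [WobbleRule(anticodon=codon_to_anticodon(codon), s=0.0, label="WC")]
        special = self.special.get(codon, {})
        if not special.get("drop_wobble", False):
            g = self.generic[codon[2]]
            wobble_anticodon = g["wobble_base"] + codon_to_anticodon(codon)[1:]
            rules.append(WobbleRule(anticodon=wobble_anticodon, s=float(g["s"]), label=g["label"]))
        for extra in special.get("extra", []):
            rules.append(
                WobbleRule(anticodon=extra["anticodon"], s=float(extra["s"]), label=extra["label"])
            )
        return rules


def default_wobble_rules() -> WobbleRuleSet:
    return WobbleRuleSet.from_yaml(None)


def codon_recognizers(
    codon: str,
    rules: WobbleRuleSet,
    genes: TRNAGeneSet,
    code: GeneticCode | None = None,
) -> list[tuple[str, float, int]]:
    """(anticodon, S_ij, tGCN) for every isoacceptor recognizing ``codon``.

    Isoacceptors absent from the pool are retained with tGCN = 0 so the rule
    structure stays visible; they contribute zero weight.
    """
    tgcn = genes.tgcn
    return [(r.anticodon, r.s, tgcn.get(r.anticodon, 0)) for r in rules.recognizers(codon, code)]


@dataclass(frozen=True)
class AdaptivenessVector:
    """Per-sense-codon adaptiveness: W, w = W/Wmax, AAw = W/W_AAmax, family share."""

    W: Mapping[str, float]
    w: Mapping[str, float]
    aa_w: Mapping[str, float]
    w_family: Mapping[str, float]
    substituted: frozenset[str] = frozenset()  # codons whose w/AAw were gap-filled
    provenance: dict = field(default_factory=dict, repr=False)
    code: GeneticCode = field(default_factory=standard_code, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "aa": self.code.translate(c),
                "W": self.W[c],
                "w": self.w[c],
                "AAw": self.aa_w[c],
                "Wfam": self.w_family[c],
                "substituted": c in self.substituted,
            }
            for c in self.code.sense_codons
        ]
        return pd.DataFrame(rows)


def _geometric_mean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def compute_wi(
    genes: TRNAGeneSet,
    rules: WobbleRuleSet | None = None,
    family_norm_scale: Literal["none", "family_size"] = "none",
    code: GeneticCode | None = None,
) -> AdaptivenessVector:
    """Compute the adaptiveness vector for a tRNA pool.

    ``family_norm_scale`` controls the family-normalized column: ``"none"``
    gives W_i / sum_family(W), ``"family_size"`` multiplies that share by the
    family size (so uniform families sit at 1 rather than 1/k).
    """
    code = code or standard_code()
    rules = rules or default_wobble_rules()

    W: dict[str, float] = {}
    for codon in code.sense_codons:
        W[codon] = sum(
            (1.0 - s) * n for _, s, n in codon_recognizers(codon, rules, genes, code)
        )
    w_max = max(W.values())
    if w_max == 0:
        raise ValueError("all W_i are zero: the tRNA pool recognizes no codon")

    w = {c: W[c] / w_max for c in code.sense_codons}
    aa_w: dict[str, float] = {}
    w_family: dict[str, float] = {}
    for aa, family in code.families.items():
        fam_max = max(W[c] for c in family)
        fam_sum = sum(W[c] for c in family)
        scale = len(family) if family_norm_scale == "family_size" else 1
        for c in family:
            aa_w[c] = W[c] / fam_max if fam_max > 0 else 0.0
            w_family[c] = scale * W[c] / fam_sum if fam_sum > 0 else float("nan")

    # reference-tAI gap fill: zero-W codons take the geometric mean of the rest
    zero = frozenset(c for c in code.sense_codons if W[c] == 0)
    if zero:
        w_fill = _geometric_mean(np.array([v for c, v in w.items() if c not in zero]))
        aa_fill = _geometric_mean(np.array([v for c, v in aa_w.items() if v > 0]))
        for c in zero:
            w[c] = w_fill
            if aa_w[c] == 0:
                aa_w[c] = aa_fill

    return AdaptivenessVector(
        W=W,
        w=w,
        aa_w=aa_w,
        w_family=w_family,
        substituted=zero,
        provenance={
            "n_trna_genes": len(genes),
            "family_norm_scale": family_norm_scale,
            "zero_W_substituted": sorted(zero),
        },
        code=code,
    )
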