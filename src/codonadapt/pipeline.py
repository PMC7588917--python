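"""End-to-end orchestration used by the CLI, the analysis scripts and tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .adaptiveness import AdaptivenessVector, WobbleRuleSet, compute_wi, default_wobble_rules
from .cds import CodingSequence, ValidationReport, load_cds
from .counts import CodonCountTable, CodonPairStats, count_codon_pairs, count_codons
from .expression import (
    classify_groups,
    compare_index_by_group,
    correlate_index_expression,
    load_expression,
)
from .indices import CPSTable, build_cps_table, gene_index_table
from .trna import TRNAGeneSet, parse_trnascan

logger = logging.getLogger(__name__)


@dataclass
class IndicesResult:
    indices: pd.DataFrame
    adapt: AdaptivenessVector | None
    cps: CPSTable
    counts: CodonCountTable
    pairs: CodonPairStats
    report: ValidationReport


def run_indices(
    cds_path: str | Path,
    trna_path: str | Path | None = None,
    s_constraints: str | Path | None = None,
    pseudocount: float = 0.0,
    family_norm_scale: str = "none",
) -> IndicesResult:
    """CDS (+ optional tRNA table) -> per-gene index table with Z-scores.

    Without a tRNA file the tAI/AAtAI columns are omitted (CAI, Nc and CPB
    still computed) — graceful degradation rather than failure.
    """
    genes, report = load_cds(cds_path)
    if not genes:
        raise ValueError("no valid coding sequences after validation")
    logger.info("CDS validation: %s", report.summary())

    counts = count_codons(genes)
    pairs = count_codon_pairs(genes)
    cps = build_cps_table(pairs, counts, pseudocount=pseudocount)

    adapt: AdaptivenessVector | None = None
    if trna_path is not None:
        trna = parse_trnascan(trna_path)
        if len(trna) == 0:
            logger.warning("empty tRNA gene set: tAI/AAtAI omitted")
        else:
            rules = WobbleRuleSet.from_yaml(s_constraints) if s_constraints else default_wobble_rules()
            adapt = compute_wi(trna, rules, family_norm_scale=family_norm_scale)  # type: ignore[arg-type]
    else:
        logger.warning("no tRNA gene table given: tAI/AAtAI omitted")

    indices = gene_index_table(genes, counts, adapt=adapt, cps=cps)
    return IndicesResult(
        indices=indices, adapt=adapt, cps=cps, counts=counts, pairs=pairs, report=report
    )


@dataclass
class IntegrationResult:
    groups: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame


def run_integration(
    indices: pd.DataFrame,
    expression_path: str | Path | pd.DataFrame,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
) -> IntegrationResult:
    """Join indices to expression, classify groups A–D, test and correlate."""
    if isinstance(expression_path, pd.DataFrame):
        expression = expression_path.copy()
        if "ratio" not in expression.columns:
            expression["ratio"] = 2.0 ** (expression["log2_bma"] - expression["log2_glucose"])
    else:
        expression = load_expression(expression_path)
    merged = indices.merge(expression, on="id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping gene ids between indices and expression")
    merged = classify_groups(merged, fold_threshold=fold_threshold, alpha=alpha)

    index_names = [c for c in ("CAI", "Nc", "tAI", "AAtAI", "CPB") if c in merged.columns]
    comparisons = compare_index_by_group(merged, index_names)
    correlations = correlate_index_expression(merged, index_names)
    return IntegrationResult(groups=merged, comparisons=comparisons, correlations=correlations)
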