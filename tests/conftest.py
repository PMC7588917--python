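from __future__ import annotations

import pytest

from codonadapt.adaptiveness import compute_wi, default_wobble_rules
from codonadapt.counts import count_codon_pairs, count_codons
from codonadapt.indices import build_cps_table
from codonadapt.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def fixture_dataset():
    """100 synthetic genes with their tRNA pool: the shared oracle corpus."""
    config = SimulationConfig(seed=1, n_genes=100)
    return simulate_all(config)


@pytest.fixture(scope="session")
def fixture_corpus(fixture_dataset):
    """(genes, counts, pairs, cps, adapt) derived from the 100-gene corpus."""
    genes = fixture_dataset.genes
    counts = count_codons(genes)
    pairs = count_codon_pairs(genes)
    cps = build_cps_table(pairs, counts)
    return genes, counts, pairs, cps, fixture_dataset.adapt


@pytest.fixture(scope="session")
def uniform_pool_adapt():
    """Adaptiveness vector from a pool holding every WC anticodon once."""
    from codonadapt.genetic_code import codon_to_anticodon, standard_code
    from codonadapt.trna import TRNAGene, TRNAGeneSet

    code = standard_code()
    genes = [
        TRNAGene(scaffold="s1", index=i + 1, isotype=code.translate(c),
                 anticodon=codon_to_anticodon(c))
        for i, c in enumerate(code.sense_codons)
    ]
    return compute_wi(TRNAGeneSet(genes=genes), default_wobble_rules())
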