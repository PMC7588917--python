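import math

import numpy as np
import pandas as pd
import pytest

from codonadapt.cds import CodingSequence
from codonadapt.counts import count_codon_pairs, count_codons
from codonadapt.genetic_code import standard_code
from codonadapt.indices import (
    IndexError_,
    build_cps_table,
    cai_weights,
    compute_aatai,
    compute_cai,
    compute_cpb,
    compute_nc,
    compute_tai,
    zscore_indices,
)

from .oracles import FAMILIES, SENSE_CODONS


def _gene(gid, codons):
    return CodingSequence(id=gid, codons=tuple(codons))


# --- CAI -------------------------------------------------------------------

def test_cai_weights_modal_codon_is_one(fixture_corpus):
    _, counts, _, _, _ = fixture_corpus
    weights = cai_weights(counts)
    for fam in FAMILIES.values():
        assert math.isclose(max(weights[c] for c in fam), 1.0)


def test_cai_weights_direct_ratio():
    # Phe usage 10 vs 30 -> weights 1/3 and 1
    genes = [_gene("g", ["TTT"] * 10 + ["TTC"] * 30 + SENSE_CODONS)]
    weights = cai_weights(count_codons(genes))
    assert math.isclose(weights["TTT"], 11 / 31)
    assert math.isclose(weights["TTC"], 1.0)


def test_cai_weights_zero_floor_and_absent_family():
    with pytest.raises(IndexError_):
        cai_weights(count_codons([_gene("g", ["TTC"] * 4)]))  # most families absent
    # observed family with one unused codon: that codon gets the floor
    counts = count_codons([_gene("g", [c for c in SENSE_CODONS if c != "TTT"] + ["TTC"] * 3)])
    assert cai_weights(counts)["TTT"] == 0.01


def test_cai_geometric_mean_and_bounds():
    weights = {"GCC": 1.0, "GCT": 1 / 3}
    gene = _gene("g", ["GCT", "GCC"])
    assert math.isclose(compute_cai(gene, weights), math.sqrt(1 / 3))
    assert math.isclose(compute_cai(_gene("m", ["GCC", "GCC"]), weights), 1.0)
    # order invariance
    assert compute_cai(_gene("r", ["GCC", "GCT"]), weights) == compute_cai(gene, weights)


# --- Nc --------------------------------------------------------------------

def test_nc_lower_bound_one_codon_per_family():
    # one codon per amino-acid family, each used many times
    codons = []
    for fam in FAMILIES.values():
        codons.extend([fam[0]] * 10)
    assert compute_nc(_gene("g", codons)) == pytest.approx(20.0)


def test_nc_uniform_usage_approaches_61():
    # exactly balanced families: F = 1/k per class, Nc hits the 61 cap
    codons = []
    for fam in FAMILIES.values():
        codons.extend(list(fam) * 50)
    assert compute_nc(_gene("g", codons)) == pytest.approx(61.0)


def test_nc_undefined_for_tiny_gene():
    assert math.isnan(compute_nc(_gene("g", ["ATG", "TGG"])))


def test_nc_matches_wright_oracle(fixture_corpus):
    from .oracles import oracle_nc

    genes, _, _, _, _ = fixture_corpus
    for g in genes[:30]:
        expected = oracle_nc(list(g.codons))
        got = compute_nc(g)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert math.isclose(got, expected, abs_tol=1e-10)


# --- CPS / CPB -------------------------------------------------------------

def _all_pairs_corpus():
    """Every ordered sense pair exactly once, as 3721 two-codon genes.

    Pair frequency then equals its independence expectation, so CPS = 0
    everywhere.
    """
    return [
        _gene(f"p{i}", [a, b])
        for i, (a, b) in enumerate((a, b) for a in SENSE_CODONS for b in SENSE_CODONS)
    ]


def test_cps_zero_on_engineered_independent_corpus():
    genes = _all_pairs_corpus()
    cps = build_cps_table(count_codon_pairs(genes), count_codons(genes))
    values = np.array(list(cps.scores.values()))
    assert np.all(np.abs(values) < 1e-12)


def test_cps_doubled_pair_is_ln2():
    # shuffle counts inside the Ala->Glu block so (GCT,GAA) doubles while every
    # codon and amino-acid marginal stays at its balanced value:
    #   (GCT,GAA) x2, (GCT,GAG) x0, (GCC,GAA) x0, (GCC,GAG) x2
    drop = {("GCT", "GAG"), ("GCC", "GAA")}
    genes = [
        _gene(f"p{i}", [a, b])
        for i, (a, b) in enumerate(
            (a, b) for a in SENSE_CODONS for b in SENSE_CODONS if (a, b) not in drop
        )
    ]
    genes.append(_gene("x1", ["GCT", "GAA"]))
    genes.append(_gene("x2", ["GCC", "GAG"]))
    cps = build_cps_table(count_codon_pairs(genes), count_codons(genes))
    assert math.isclose(cps.score("GCT", "GAA"), math.log(2.0), rel_tol=1e-12)
    # untouched blocks keep CPS = 0
    assert abs(cps.score("TTT", "GGC")) < 1e-12

    # independent brute-force check on the same corpus
    from .oracles import oracle_cps_table

    oracle = oracle_cps_table([list(g.codons) for g in genes])
    for pair, value in oracle.items():
        assert math.isclose(cps.score(*pair), value, abs_tol=1e-12)


def test_unobserved_pair_flagged_not_minus_inf():
    genes = [_gene("g", ["ATG", "GCC", "GAA"])]
    cps = build_cps_table(count_codon_pairs(genes), count_codons(genes))
    assert ("GAA", "ATG") not in cps.scores
    with pytest.raises(IndexError_, match="GAA"):
        cps.score("GAA", "ATG")


def test_pseudocount_mode_scores_unobserved_pairs():
    genes = [_gene("a", ["ATG", "GCC", "GAA"]), _gene("b", ["ATG", "GCT", "GAG"])]
    cps = build_cps_table(count_codon_pairs(genes), count_codons(genes), pseudocount=0.5)
    # (GCC,GAG) never occurs but Ala-Glu does: scored via pseudocount, flagged
    assert ("GCC", "GAG") in cps.unobserved
    assert ("GCT", "GAA") in cps.unobserved
    assert all(math.isfinite(v) for v in cps.scores.values())
    strict = build_cps_table(count_codon_pairs(genes), count_codons(genes))
    assert ("GCC", "GAG") not in strict.scores


def test_cpb_mean_of_pair_scores():
    class _Fixed:
        def score(self, a, b):
            return 0.2 if (a, b) == ("ATG", "GCC") else 0.4

    gene = _gene("g", ["ATG", "GCC", "GAA"])
    assert math.isclose(compute_cpb(gene, _Fixed()), 0.3)
    assert math.isnan(compute_cpb(_gene("short", ["ATG"]), _Fixed()))


def test_corpus_weighted_mean_cps_zero_on_engineered_corpus():
    genes = _all_pairs_corpus()
    pairs = count_codon_pairs(genes)
    cps = build_cps_table(pairs, count_codons(genes))
    weighted = sum(cps.scores[p] * n for p, n in pairs.pair_counts.items()) / pairs.total_pairs
    assert abs(weighted) < 1e-6


def test_cpb_self_concatenation_adds_one_junction(fixture_corpus):
    genes, _, _, cps, _ = fixture_corpus
    g = genes[0]
    doubled = _gene("d", list(g.codons) * 2)
    junction = cps.score(g.codons[-1], g.codons[0])
    l = g.length
    expected = (2 * (l - 1) * compute_cpb(g, cps) + junction) / (2 * l - 1)
    assert math.isclose(compute_cpb(doubled, cps), expected, rel_tol=1e-12)


# --- tAI / AAtAI ------------------------------------------------------------

def test_tai_and_aatai_phe_toy():
    from codonadapt.adaptiveness import compute_wi, default_wobble_rules
    from codonadapt.trna import TRNAGene, TRNAGeneSet

    pool = TRNAGeneSet(
        genes=[TRNAGene(scaffold="s", index=i, isotype="F", anticodon="GAA") for i in range(5)]
    )
    adapt = compute_wi(pool, default_wobble_rules())
    gene = _gene("g", ["TTT", "TTC"])
    assert math.isclose(compute_tai(gene, adapt), math.sqrt(0.59))
    assert math.isclose(compute_aatai(gene, adapt), math.sqrt(0.59))


def test_tai_upper_bound_and_order_invariance(fixture_dataset):
    adapt = fixture_dataset.adapt
    best = max(SENSE_CODONS, key=lambda c: adapt.w[c])
    assert math.isclose(compute_tai(_gene("g", [best] * 10), adapt), 1.0)
    g1 = _gene("a", ["GGC", "GAA", "TTT"])
    g2 = _gene("b", ["TTT", "GGC", "GAA"])
    assert compute_tai(g1, adapt) == compute_tai(g2, adapt)


def test_aatai_dominates_tai(fixture_corpus):
    genes, _, _, _, adapt = fixture_corpus
    for g in genes:
        assert compute_aatai(g, adapt) >= compute_tai(g, adapt) - 1e-12


def test_aatai_one_on_family_optimal_gene(fixture_dataset):
    adapt = fixture_dataset.adapt
    best_per_family = [max(fam, key=lambda c: adapt.aa_w[c]) for fam in FAMILIES.values()]
    assert math.isclose(compute_aatai(_gene("g", best_per_family), adapt), 1.0)


# --- Z-scores ---------------------------------------------------------------

def test_zscores_population_convention():
    table = pd.DataFrame({"id": list("abc"), "CAI": [1.0, 2.0, 3.0]})
    out = zscore_indices(table, columns=["CAI"])
    assert np.allclose(out["Z_CAI"], [-np.sqrt(1.5), 0.0, np.sqrt(1.5)])


def test_zscore_affine_invariance_and_mean_gene():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    t1 = zscore_indices(pd.DataFrame({"CAI": x}), columns=["CAI"])
    t2 = zscore_indices(pd.DataFrame({"CAI": 3.0 * x + 7.0}), columns=["CAI"])
    assert np.allclose(t1["Z_CAI"], t2["Z_CAI"])
    t3 = zscore_indices(pd.DataFrame({"CAI": np.append(x, x.mean())}), columns=["CAI"])
    assert abs(t3["Z_CAI"].iloc[-1]) < 1e-12


def test_zscore_constant_index_errors():
    with pytest.raises(IndexError_):
        zscore_indices(pd.DataFrame({"CAI": [1.0, 1.0, 1.0]}), columns=["CAI"])
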