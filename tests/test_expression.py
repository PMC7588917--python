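import math
from io import StringIO

import numpy as np
import pandas as pd
import pytest

from codonadapt.expression import (
    ExpressionFormatError,
    classify_groups,
    compare_index_by_group,
    correlate_index_expression,
    load_expression,
)


def _table(rows):
    header = "id\tlog2_glucose\tlog2_bma\tp_value\n"
    return StringIO(header + "".join("\t".join(map(str, r)) + "\n" for r in rows))


def test_ratio_recomputed_from_log2_signals():
    # published worked examples: ratios reproduce to table rounding
    table = load_expression(
        _table([("50297", 13.13, 11.88, 0.19), ("67561", 10.30, 13.71, 0.00002),
                ("eq", 9.0, 9.0, 0.5)])
    )
    assert table.loc[0, "ratio"] == pytest.approx(0.421, rel=0.01)
    assert table.loc[1, "ratio"] == pytest.approx(10.642, rel=0.01)
    assert table.loc[2, "ratio"] == 1.0


def test_load_rejects_duplicates_and_bad_p():
    with pytest.raises(ExpressionFormatError, match="duplicate"):
        load_expression(_table([("a", 1, 2, 0.5), ("a", 1, 2, 0.5)]))
    with pytest.raises(ExpressionFormatError, match="p-values"):
        load_expression(_table([("a", 1, 2, 1.5)]))


def test_malformed_rows_dropped_with_warning():
    table = load_expression(_table([("a", 1, 2, 0.5), ("b", "oops", 2, 0.5)]))
    assert list(table["id"]) == ["a"]


@pytest.mark.parametrize(
    "ratio,p,expected",
    [
        (6.508, 0.00895, "B"),   # induced >= 2-fold, significant
        (0.707, 0.00595, "D"),   # significant but < 2-fold
        (0.421, 0.19, "C"),      # not significant
        (0.4, 0.01, "A"),        # repressed >= 2-fold, significant
        (2.0, 0.01, "B"),        # boundary: fold threshold inclusive
        (0.5, 0.01, "A"),
        (1.2, 0.05, "C"),        # boundary: p == alpha goes to C
    ],
)
def test_group_classification_rule(ratio, p, expected):
    table = pd.DataFrame(
        {"id": ["g"], "ratio": [ratio], "p_value": [p], "log2_glucose": [10.0],
         "log2_bma": [10.0 + math.log2(ratio)]}
    )
    assert classify_groups(table)["group"].iloc[0] == expected


def test_group_partition_exhaustive_and_disjoint(fixture_dataset):
    expr = fixture_dataset.expression.copy()
    expr["ratio"] = 2.0 ** (expr["log2_bma"] - expr["log2_glucose"])
    out = classify_groups(expr)
    assert set(out["group"]) <= {"A", "B", "C", "D"}
    assert out["group"].notna().all()
    assert len(out) == len(expr)


def test_mannwhitney_exact_small_sample():
    merged = pd.DataFrame(
        {"group": ["B"] * 3 + ["C"] * 3, "CAI": [4, 5, 6, 1, 2, 3]}
    )
    result = compare_index_by_group(merged, ["CAI"])
    row = result[result["comparison"] == "B-vs-C"].iloc[0]
    assert row["p_value"] == pytest.approx(0.1)  # 2/20 arrangements as extreme
    assert row["n_B"] == 3 and row["n_other"] == 3


def test_mannwhitney_identical_groups_p_one_and_symmetry():
    merged = pd.DataFrame({"group": ["B"] * 4 + ["C"] * 4, "CAI": [1, 2, 3, 4] * 2})
    row = compare_index_by_group(merged, ["CAI"]).iloc[0]
    assert row["p_value"] == pytest.approx(1.0)
    swapped = pd.DataFrame(
        {"group": ["C"] * 3 + ["B"] * 3, "CAI": [4, 5, 6, 1, 2, 3]}
    )
    orig = pd.DataFrame({"group": ["B"] * 3 + ["C"] * 3, "CAI": [4, 5, 6, 1, 2, 3]})
    p1 = compare_index_by_group(orig, ["CAI"]).iloc[0]["p_value"]
    p2 = compare_index_by_group(swapped, ["CAI"]).iloc[0]["p_value"]
    assert p1 == pytest.approx(p2)


def test_empty_group_skipped_with_warning():
    merged = pd.DataFrame({"group": ["B"] * 3 + ["C"] * 3, "CAI": [4, 5, 6, 1, 2, 3]})
    result = compare_index_by_group(merged, ["CAI"])
    assert set(result["comparison"]) == {"B-vs-C"}  # A and D absent -> skipped


def _corr_frame(x, y, p=None):
    n = len(x)
    return pd.DataFrame(
        {
            "CAI": x,
            "ratio": y,
            "log2_glucose": np.zeros(n) + np.arange(n),  # non-constant filler
            "log2_bma": np.zeros(n) + np.arange(n),
            "p_value": p if p is not None else np.full(n, 0.5),
        }
    )


@pytest.mark.parametrize(
    "x,y,rho",
    [
        ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
        ([1, 2, 3, 4], [40, 30, 20, 10], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ],
)
def test_spearman_known_values(x, y, rho):
    out = correlate_index_expression(_corr_frame(x, y), ["CAI"])
    row = out[(out["expression_var"] == "ratio") & (out["stratum"] == "all")].iloc[0]
    assert row["rho"] == pytest.approx(rho)


def test_constant_vector_flagged_undefined():
    out = correlate_index_expression(_corr_frame([1, 1, 1, 1], [1, 2, 3, 4]), ["CAI"])
    row = out[(out["expression_var"] == "ratio") & (out["stratum"] == "all")].iloc[0]
    assert row["flag"] == "undefined"
    assert math.isnan(row["rho"])


def test_strata_disjoint_and_exhaustive():
    p = [0.0005, 0.01, 0.2, 0.0009, 0.04, 0.9]
    out = correlate_index_expression(
        _corr_frame([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5], p=p), ["CAI"]
    )
    sub = out[(out["expression_var"] == "ratio") & (out["stratum"] != "all")]
    assert sub["n"].sum() == 6  # every gene in exactly one stratum
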