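import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab.ct_io import (
    CtTable,
    CtTableError,
    anova_oneway,
    average_technical_replicates,
    read_ct_table,
    summarize_all,
    summarize_ct,
    tukey_hsd,
)

from conftest import make_table


# ---------------------------------------------------------------- reading


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_long_layout(tmp_path):
    p = _write(
        tmp_path,
        "ct.csv",
        "sample,group,gene,replicate,ct\n"
        "s1,a,G1,1,20\ns1,a,G2,1,25\ns2,b,G1,1,21\ns2,b,G2,1,26\n",
    )
    t = read_ct_table(p, layout="long")
    assert len(t) == 4
    assert t.genes == ["G1", "G2"]
    assert dict(t.groups) == {"s1": "a", "s2": "b"}


def test_read_wide_layout(tmp_path):
    header = "sample,group," + ",".join(f"G{i}" for i in range(1, 6))
    rows = [f"s{j},grp,{','.join(str(20 + i + j / 10) for i in range(5))}" for j in range(1, 13)]
    p = _write(tmp_path, "ct.csv", header + "\n" + "\n".join(rows) + "\n")
    t = read_ct_table(p, layout="wide")
    assert len(t) == 60
    assert t.genes == [f"G{i}" for i in range(1, 6)]  # file column order kept


def test_read_missing_ct_column_errors(tmp_path):
    p = _write(tmp_path, "ct.csv", "sample,group,gene,replicate\ns1,a,G1,1\n")
    with pytest.raises(CtTableError, match="ct"):
        read_ct_table(p, layout="long")


def test_read_non_numeric_ct_errors(tmp_path):
    p = _write(
        tmp_path, "ct.csv",
        "sample,group,gene,replicate,ct\ns1,a,G1,1,Undetermined\ns2,a,G1,1,20\n",
    )
    with pytest.raises(CtTableError, match="non-numeric"):
        read_ct_table(p, layout="long")


def test_duplicate_key_rejected():
    df = pd.DataFrame(
        {"sample": ["s1", "s1"], "group": ["a", "a"], "gene": ["G1", "G1"],
         "replicate": [1, 1], "ct": [20.0, 21.0]}
    )
    with pytest.raises(CtTableError, match="duplicate"):
        CtTable(df)


def test_ct_out_of_range_rejected():
    df = pd.DataFrame(
        {"sample": ["s1"], "group": ["a"], "gene": ["G1"], "replicate": [1], "ct": [50.0]}
    )
    with pytest.raises(CtTableError, match="ct values"):
        CtTable(df)


def test_sample_in_two_groups_rejected():
    df = pd.DataFrame(
        {"sample": ["s1", "s1"], "group": ["a", "b"], "gene": ["G1", "G2"],
         "replicate": [1, 1], "ct": [20.0, 21.0]}
    )
    with pytest.raises(CtTableError, match="more than one group"):
        CtTable(df)


# ------------------------------------------------- technical replicates


@pytest.mark.parametrize(
    "cts, expected",
    [([20.0, 21.0, 22.0], 21.0), ([24.5], 24.5)],
)
def test_replicate_averaging(cts, expected):
    rows = [("s1", "a", "G1", i + 1, c) for i, c in enumerate(cts)]
    rows += [("s1", "a", "G2", i + 1, 30.0) for i in range(len(cts))]
    t = CtTable(pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"]))
    avg = average_technical_replicates(t)
    got = avg.data.set_index("gene").loc["G1", "ct"]
    assert got == pytest.approx(expected)
    assert (avg.data["replicate"] == 1).all()


def test_replicate_averaging_drops_missing():
    rows = [("s1", "a", "G1", 1, 20.0), ("s1", "a", "G1", 2, np.nan), ("s1", "a", "G1", 3, 22.0)]
    t = CtTable(
        pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"]),
        allow_missing=True,
    )
    avg = average_technical_replicates(t, missing="drop")
    assert avg.data["ct"].iloc[0] == pytest.approx(21.0)
    with pytest.raises(CtTableError):
        average_technical_replicates(t, missing="error")


# -------------------------------------------------------------- summary


def test_summary_published_ranges():
    # 12-sample profiles spanning the published per-gene extremes
    low = np.linspace(10.22, 14.18, 12)
    t = make_table({"18S rRNA": low, "UBC": np.linspace(24.46, 26.60, 12)})
    assert summarize_ct(t, "18S rRNA").range == pytest.approx(3.96)
    assert summarize_ct(t, "UBC").range == pytest.approx(2.14)


def test_summary_constant_gene():
    t = make_table({"G1": [25, 25, 25], "G2": [20, 21, 22]})
    s = summarize_ct(t, "G1")
    assert (s.range, s.mean, s.q1, s.median, s.q3) == (0, 25, 25, 25, 25)


def test_summary_order_invariants():
    t = make_table({"G1": [20.5, 23.1, 19.7, 22.0, 21.3]})
    s = summarize_ct(t, "G1")
    assert s.min <= s.q1 <= s.median <= s.q3 <= s.max
    assert s.range == s.max - s.min


def test_summary_unknown_gene():
    t = make_table({"G1": [20, 21]})
    with pytest.raises(KeyError):
        summarize_ct(t, "nope")


def test_summarize_all_column_order():
    t = make_table({"G1": [20, 21, 22], "G2": [25, 26, 27]})
    df = summarize_all(t)
    assert list(df.columns) == ["gene", "n", "min", "q1", "median", "q3", "max", "range", "mean"]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=5.0, max_value=40.0), min_size=2, max_size=30))
def test_summary_range_exact_for_any_input(values):
    t = make_table({"G1": values})
    s = summarize_ct(t, "G1")
    assert s.range == max(values) - min(values)  # exact, no rounding


# ---------------------------------------------------------------- anova


def test_anova_two_group_hand_value():
    t = make_table(
        {"G1": [1, 2, 3, 4, 5, 6]},
        groups={f"s{i}": ("a" if i <= 3 else "b") for i in range(1, 7)},
    )
    res = anova_oneway(t, "G1")
    # SSB = 13.5 (df 1), SSW = 4 (df 4) -> F = 13.5
    assert res.f_statistic == pytest.approx(13.5)
    assert res.group_means == {"a": 2.0, "b": 5.0}


def test_anova_identical_means_f_zero():
    t = make_table(
        {"G1": [1, 2, 3, 3, 2, 1]},
        groups={f"s{i}": ("a" if i <= 3 else "b") for i in range(1, 7)},
    )
    res = anova_oneway(t, "G1")
    assert res.f_statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_anova_degenerate_all_identical_warns():
    t = make_table(
        {"G1": [25.0] * 6},
        groups={f"s{i}": ("a" if i <= 3 else "b") for i in range(1, 7)},
    )
    with pytest.warns(UserWarning, match="zero total variance"):
        res = anova_oneway(t, "G1")
    assert (res.f_statistic, res.p_value) == (0.0, 1.0)


def test_anova_global_shift_invariant():
    groups = {f"s{i}": ("a" if i <= 3 else "b") for i in range(1, 7)}
    vals = [1.4, 2.2, 3.1, 4.0, 5.5, 6.1]
    r1 = anova_oneway(make_table({"G1": vals}, groups=groups), "G1")
    r2 = anova_oneway(make_table({"G1": [v + 7.3 for v in vals]}, groups=groups), "G1")
    assert r1.f_statistic == pytest.approx(r2.f_statistic, abs=1e-9)
    assert r1.p_value == pytest.approx(r2.p_value, abs=1e-9)


def test_anova_requires_two_filled_groups():
    t = make_table({"G1": [1, 2, 3]}, groups={"s1": "a", "s2": "a", "s3": "b"})
    with pytest.raises(ValueError, match="fewer than two"):
        anova_oneway(t, "G1")
    t2 = make_table({"G1": [1, 2, 3]})
    with pytest.raises(ValueError, match="two groups"):
        anova_oneway(t2, "G1")


# ---------------------------------------------------------------- tukey


def test_tukey_identical_groups_not_significant():
    t = make_table(
        {"G1": [1, 2, 3, 1, 2, 3]},
        groups={f"s{i}": ("a" if i <= 3 else "b") for i in range(1, 7)},
    )
    (comp,) = tukey_hsd(t, "G1")
    assert comp.difference == 0.0
    assert not comp.significant


def test_tukey_separated_groups_significant():
    t = make_table(
        {"G1": [1, 2, 3, 10, 11, 12]},
        groups={f"s{i}": ("a" if i <= 3 else "b") for i in range(1, 7)},
    )
    (comp,) = tukey_hsd(t, "G1", alpha=0.05)
    assert comp.significant
    assert comp.difference == pytest.approx(-9.0)


def test_tukey_one_shifted_group_gives_two_significant_pairs():
    groups = {f"s{i}": ["a", "a", "a", "b", "b", "b", "c", "c", "c"][i - 1] for i in range(1, 10)}
    t = make_table({"G1": [1, 2, 3, 1.5, 2.5, 3.5, 20, 21, 22]}, groups=groups)
    comps = tukey_hsd(t, "G1")
    flagged = {frozenset(c.pair) for c in comps if c.significant}
    assert flagged == {frozenset({"a", "c"}), frozenset({"b", "c"})}


def test_tukey_symmetric_in_pair_order():
    groups = {f"s{i}": ("a" if i <= 3 else "b") for i in range(1, 7)}
    t1 = make_table({"G1": [1, 2, 3, 10, 11, 12]}, groups=groups)
    flipped = {f"s{i}": ("b" if i <= 3 else "a") for i in range(1, 7)}
    t2 = make_table({"G1": [1, 2, 3, 10, 11, 12]}, groups=flipped)
    (c1,) = tukey_hsd(t1, "G1")
    (c2,) = tukey_hsd(t2, "G1")
    assert c1.significant == c2.significant
    assert c1.p_value == pytest.approx(c2.p_value, abs=1e-9)


# ------------------------------------------------------------- plumbing


def test_drop_incomplete_samples():
    rows = [
        ("s1", "a", "G1", 1, 20.0), ("s1", "a", "G2", 1, 25.0),
        ("s2", "a", "G1", 1, 21.0),  # s2 lacks G2
    ]
    t = CtTable(
        pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"]),
        require_complete=False,
    )
    kept = t.drop_incomplete_samples()
    assert kept.samples == ["s1"]
    mat = kept.to_matrix()
    assert mat.shape == (2, 1)
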