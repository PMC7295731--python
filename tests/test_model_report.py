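import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from refstab.cli import main as cli_main
from refstab.model import MultiConditionStability, ReferenceGeneStability
from refstab.report import AnalysisConfig, read_config_file, run_analysis, run_multi_condition
from refstab.synthetic import default_spec, generate_ct_table


@pytest.fixture(scope="module")
def synthetic_csv(tmp_path_factory):
    table, _ = generate_ct_table(default_spec(), seed=11)
    p = tmp_path_factory.mktemp("data") / "ct.csv"
    table.data.to_csv(p, index=False)
    return p


def test_model_fit_consistency(synthetic_csv):
    model = ReferenceGeneStability.from_csv(synthetic_csv)
    res = model.fit()
    sf = res.stability_frame()
    # deltaCt == first-iteration geNorm M at E = 2
    assert np.allclose(sf["delta_ct"], sf["genorm_m"], atol=1e-10)
    # geomean bounded by the four method ranks
    rt = res.rank_table
    assert ((res.reffinder.geomean >= rt.min(axis=1)) & (res.reffinder.geomean <= rt.max(axis=1))).all()
    assert "Reference-gene stability" in res.summary()


def test_model_method_subsets(synthetic_csv):
    model = ReferenceGeneStability.from_csv(synthetic_csv, methods=("genorm",))
    res = model.fit()
    assert res.genorm is not None
    assert res.delta_ct is None and res.reffinder is None
    with pytest.raises(ValueError, match="reffinder requires"):
        ReferenceGeneStability.from_csv(synthetic_csv, methods=("genorm", "reffinder"))
    with pytest.raises(ValueError, match="unknown method"):
        ReferenceGeneStability.from_csv(synthetic_csv, methods=("genarm",))


def test_run_analysis_bundle(tmp_path, synthetic_csv):
    cfg = AnalysisConfig(input=str(synthetic_csv), out=str(tmp_path / "out"))
    run_analysis(cfg)
    names = {p.name for p in (tmp_path / "out").iterdir()}
    assert {
        "summary.tsv", "delta_ct.tsv", "bestkeeper.tsv", "genorm.tsv",
        "v_series.tsv", "normfinder.tsv", "aggregate.tsv",
    } <= names
    agg = pd.read_csv(tmp_path / "out" / "aggregate.tsv", sep="\t")
    assert list(agg.columns) == [
        "gene", "delta_ct_rank", "bestkeeper_rank", "genorm_rank",
        "normfinder_rank", "geomean", "final_rank",
    ]
    machine = json.loads((tmp_path / "out" / "summary.json").read_text())
    assert machine["genorm_optimal_n"] >= 2


def test_run_analysis_deterministic(tmp_path, synthetic_csv):
    cfg1 = AnalysisConfig(input=str(synthetic_csv), out=str(tmp_path / "a"))
    cfg2 = AnalysisConfig(input=str(synthetic_csv), out=str(tmp_path / "b"))
    run_analysis(cfg1)
    run_analysis(cfg2)
    for name in ("aggregate.tsv", "v_series.tsv", "summary.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_multi_condition_identical_specs(tmp_path):
    paths = {}
    for cond in ("c1", "c2", "c3"):
        table, _ = generate_ct_table(default_spec(), seed=21)  # same seed: identical data
        p = tmp_path / f"{cond}.csv"
        table.data.to_csv(p, index=False)
        paths[cond] = p
    models = {c: ReferenceGeneStability.from_csv(p) for c, p in paths.items()}
    multi = MultiConditionStability(models).fit()
    per_cond = multi.per_method_ranks["delta_ct"]
    for cond_ranks in per_cond.values():
        assert multi.average_ranks["delta_ct"].equals(cond_ranks.astype(float))


def test_multi_condition_exclusion_identity(tmp_path):
    t1, _ = generate_ct_table(default_spec(), seed=31)
    t2, _ = generate_ct_table(default_spec(), seed=32)
    models = {
        "keep": ReferenceGeneStability(t1),
        "drop": ReferenceGeneStability(t2),
    }
    multi = MultiConditionStability(models).fit(exclude=("drop",))
    kept = multi.sensitivity["delta_ct"].retained_average
    assert kept.equals(multi.per_method_ranks["delta_ct"]["keep"].astype(float))


def test_multi_condition_gene_mismatch(tmp_path):
    t1, _ = generate_ct_table(default_spec(), seed=1)
    df = t1.data.copy()
    df.loc[df["gene"] == "UBC", "gene"] = "other"
    from refstab.ct_io import CtTable

    with pytest.raises(ValueError, match="gene set mismatch"):
        MultiConditionStability(
            {"a": ReferenceGeneStability(t1), "b": ReferenceGeneStability(CtTable(df))}
        )


def test_config_file_parsing(tmp_path):
    p = tmp_path / "run.cfg"
    p.write_text("# comment\nefficiency = 1.9\nlayout = long\n")
    assert read_config_file(p) == {"efficiency": "1.9", "layout": "long"}
    bad = tmp_path / "bad.cfg"
    bad.write_text("efficiency 1.9\n")
    with pytest.raises(ValueError, match="key = value"):
        read_config_file(bad)


# ------------------------------------------------------------------- CLI


def test_cli_simulate_analyze_roundtrip(tmp_path):
    runner = CliRunner()
    ct = tmp_path / "ct.csv"
    r = runner.invoke(cli_main, ["--quiet", "simulate", "--seed", "7", "--out", str(ct)])
    assert r.exit_code == 0, r.output
    truth = json.loads((tmp_path / "ct.truth.json").read_text())
    assert set(truth["order"]) == {"UBC", "actin", "GAPDH", "a-tubulin", "18S rRNA"}

    out = tmp_path / "res"
    r = runner.invoke(
        cli_main,
        ["--quiet", "analyze", "--input", str(ct), "--out", str(out), "--v-cutoff", "0.2"],
    )
    assert r.exit_code == 0, r.output
    assert (out / "aggregate.tsv").exists()
    assert "RefFinder comprehensive order" in r.output


def test_cli_efficiency(tmp_path):
    p = tmp_path / "series.csv"
    # fivefold series with slope -3.6 per log10: Ct rises 3.6*log10(5) per step
    cts = [20.0 + 3.6 * np.log10(5) * i for i in range(4)]
    p.write_text("step,ct\n" + "\n".join(f"{i},{c}" for i, c in enumerate(cts)) + "\n")
    runner = CliRunner()
    r = runner.invoke(cli_main, ["--quiet", "efficiency", "--input", str(p),
                                 "--dilution-factor", "5"])
    assert r.exit_code == 0, r.output
    assert "89.57%" in r.output


def test_cli_multi_with_exclusion(tmp_path):
    runner = CliRunner()
    paths = []
    for i, cond in enumerate(("n10", "s24", "mixed")):
        ct = tmp_path / f"{cond}.csv"
        r = runner.invoke(cli_main, ["--quiet", "simulate", "--seed", str(50 + i),
                                     "--out", str(ct)])
        assert r.exit_code == 0, r.output
        paths.append(f"{cond}={ct}")
    out = tmp_path / "multi"
    r = runner.invoke(
        cli_main,
        ["--quiet", "multi", "--conditions", ",".join(paths), "--exclude", "mixed",
         "--out", str(out)],
    )
    assert r.exit_code == 0, r.output
    assert (out / "average_ranking.tsv").exists()
    assert (out / "sensitivity.tsv").exists()
    sens = pd.read_csv(out / "sensitivity.tsv", sep="\t")
    assert {"method", "gene", "average_all", "average_retained", "shift"} <= set(sens.columns)
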