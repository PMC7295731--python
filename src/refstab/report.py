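"""End-to-end analysis runs and TSV/JSON report bundles.

``run_analysis`` executes the configured stability methods on one Ct
table and writes the report bundle: Ct summaries, per-method stability
tables, the geNorm M trajectory and V series, and the aggregated rank
table. ``run_multi_condition`` repeats that per condition and adds
cross-condition average rankings plus the optional condition-exclusion
sensitivity tables. Every number in the report files comes straight
from an operation result; the report layer only formats.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .aggregate import round_half_up
from .genorm import DEFAULT_AVAILABILITY_CUTOFF, DEFAULT_V_CUTOFF
from .model import ALL_METHODS, MultiConditionStability, ReferenceGeneStability

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run (mirrors the CLI flags)."""

    input: str
    layout: str = "long"
    methods: Sequence[str] = ALL_METHODS
    efficiency: float | Mapping[str, float] = 2.0
    v_cutoff: float = DEFAULT_V_CUTOFF
    availability_cutoff: float = DEFAULT_AVAILABILITY_CUTOFF
    bestkeeper_dispersion: str = "mad"
    drop_incomplete: bool = False
    out: str = "results"
    value_decimals: int = 3
    rank_decimals: int = 2

    def build_model(self) -> ReferenceGeneStability:
        return ReferenceGeneStability.from_csv(
            self.input,
            layout=self.layout,
            drop_incomplete=self.drop_incomplete,
            efficiency=self.efficiency,
            methods=tuple(self.methods),
            v_cutoff=self.v_cutoff,
            availability_cutoff=self.availability_cutoff,
            bestkeeper_dispersion=self.bestkeeper_dispersion,
        )


def read_config_file(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line (expected key = value): {raw!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def _fmt(df: pd.DataFrame, decimals: int) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(lambda v: f"{v:.{decimals}f}")
    return out


def _write(df: pd.DataFrame, path: Path, index_label: str | None = "gene") -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def run_analysis(config: AnalysisConfig):
    """Run one condition's analysis and write the report bundle.

    Returns the fitted :class:`~refstab.model.StabilityResults`; writes
    summary.tsv, delta_ct.tsv, bestkeeper.tsv, genorm.tsv, v_series.tsv,
    normfinder.tsv and aggregate.tsv (those applicable to the chosen
    methods) plus summary.json under ``config.out``.
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    model = config.build_model()
    res = model.fit()
    nd = config.value_decimals

    _write(_fmt(res.ct_summary().set_index("gene"), nd), outdir / "summary.tsv")
    if res.delta_ct is not None:
        df = pd.DataFrame({"stability": res.delta_ct.stability, "rank": res.delta_ct.ranks})
        _write(_fmt(df, nd), outdir / "delta_ct.tsv")
    if res.bestkeeper is not None:
        bk = res.bestkeeper
        df = pd.DataFrame(
            {
                "mean_ct": bk.mean_ct,
                "dispersion": bk.dispersion,
                "cv_percent": bk.cv_percent,
                "r": bk.correlation,
                "rank": bk.ranks,
            }
        )
        _write(_fmt(df, nd), outdir / "bestkeeper.tsv")
    if res.genorm is not None:
        g = res.genorm
        rows = []
        for it, m in enumerate(g.m_trajectory, start=1):
            for gene, val in m.items():
                rows.append({"iteration": it, "gene": gene, "M": val})
        _write(_fmt(pd.DataFrame(rows), nd), outdir / "genorm.tsv", index_label=None)
        if g.v_series is not None:
            vdf = g.v_series.rename("V").to_frame()
            _write(_fmt(vdf, nd), outdir / "v_series.tsv", index_label="n")
    if res.normfinder is not None:
        nfres = res.normfinder
        df = pd.DataFrame({"stability": nfres.stability, "rank": nfres.ranks})
        _write(_fmt(df, nd), outdir / "normfinder.tsv")
        diag = []
        for grp in nfres.sigma2.columns:
            for gene in nfres.sigma2.index:
                diag.append(
                    {
                        "gene": gene,
                        "group": grp,
                        "sigma2": nfres.sigma2.loc[gene, grp],
                        "d": nfres.d.loc[gene, grp],
                        "d_shrunk": nfres.d_shrunk.loc[gene, grp],
                    }
                )
        _write(_fmt(pd.DataFrame(diag), 4), outdir / "normfinder_diagnostics.tsv", index_label=None)
    if res.reffinder is not None:
        df = res.rank_table.copy()
        df.columns = [f"{c}_rank" for c in df.columns]
        df["geomean"] = res.reffinder.geomean
        df["final_rank"] = res.reffinder.final_ranks
        _write(_fmt(df, nd), outdir / "aggregate.tsv")

    machine = {
        "version": __version__,
        "genes": model.table.genes,
        "samples": model.table.samples,
        "methods": list(config.methods),
        "stability": {
            c: {g: float(v) for g, v in col.items()}
            for c, col in res.stability_frame().items()
        },
    }
    if res.genorm is not None and res.genorm.v_series is not None:
        machine["genorm_optimal_n"] = res.genorm.optimal_n
        machine["genorm_v_series"] = {int(n): float(v) for n, v in res.genorm.v_series.items()}
    (outdir / "summary.json").write_text(json.dumps(machine, indent=2, sort_keys=True))
    logger.info("wrote report bundle to %s", outdir)
    return res


def run_multi_condition(
    configs: Mapping[str, AnalysisConfig],
    exclude: Sequence[str] = (),
    out: str | Path = "results",
):
    """Per-condition analyses plus cross-condition average rankings.

    Writes each condition's bundle into a subdirectory, then
    ``average_ranking.tsv`` (mean rank per gene per method, 2 decimals,
    round half up) and, when ``exclude`` is non-empty,
    ``sensitivity.tsv`` with the recomputed averages and rank shifts.
    """
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    models = {}
    for cond, cfg in configs.items():
        cfg.out = str(outdir / cond)
        run_analysis(cfg)
        models[cond] = cfg.build_model()
    multi = MultiConditionStability(models).fit(exclude=exclude)

    avg = pd.DataFrame(multi.average_ranks).map(round_half_up)
    _write(_fmt(avg, 2), outdir / "average_ranking.tsv")
    if multi.sensitivity is not None:
        rows = []
        for method, sens in multi.sensitivity.items():
            for gene in sens.full_average.index:
                rows.append(
                    {
                        "method": method,
                        "gene": gene,
                        "average_all": round_half_up(sens.full_average[gene]),
                        "average_retained": round_half_up(sens.retained_average[gene]),
                        "shift": round_half_up(sens.shift[gene]),
                    }
                )
        _write(_fmt(pd.DataFrame(rows), 2), outdir / "sensitivity.tsv", index_label=None)
    return multi
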