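"""Model/results interface for reference-gene stability analysis.

``ReferenceGeneStability`` is built from a Ct table (or a long-format
DataFrame / CSV); ``fit()`` runs the requested stability methods and
returns a ``StabilityResults`` object carrying per-method estimates,
the genes x methods rank table, the RefFinder aggregation, diagnostics
and a ``summary()`` report. Multi-condition studies are handled by
``MultiConditionStability``, which averages per-condition ranks and
supports the condition-exclusion sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import genorm as gn
from . import normfinder as nf
from . import pairwise as pw
from .ct_io import CtTable, read_ct_table, summarize_all
from .quantify import RelQuantMatrix, relative_quantities

ALL_METHODS = ("delta_ct", "bestkeeper", "genorm", "normfinder", "reffinder")


class ReferenceGeneStability:
    """Stability of candidate reference genes in an RT-qPCR Ct table.

    Parameters
    ----------
    table
        Validated :class:`~refstab.ct_io.CtTable`.
    efficiency
        Per-cycle amplification fold change, global or per gene
        (2.0 = perfectly doubling assay).
    methods
        Subset of ``delta_ct, bestkeeper, genorm, normfinder, reffinder``;
        ``reffinder`` requires the other four.
    v_cutoff, availability_cutoff
        geNorm pairwise-variation and M-value cutoffs.
    bestkeeper_dispersion
        ``'mad'`` (mean absolute deviation, default) or ``'sd'``.

    Examples
    --------
    >>> from refstab import ReferenceGeneStability
    >>> from refstab.synthetic import default_spec, generate_ct_table
    >>> table, truth = generate_ct_table(default_spec(), seed=17)
    >>> res = ReferenceGeneStability(table).fit()
    >>> res.reffinder.order[-1] == truth.order[-1]
    True
    """

    def __init__(
        self,
        table: CtTable,
        *,
        efficiency: float | Mapping[str, float] = 2.0,
        methods: Sequence[str] = ALL_METHODS,
        v_cutoff: float = gn.DEFAULT_V_CUTOFF,
        availability_cutoff: float = gn.DEFAULT_AVAILABILITY_CUTOFF,
        bestkeeper_dispersion: str = "mad",
        group_by: Mapping[str, str] | pd.Series | None = None,
    ) -> None:
        unknown = set(methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {', '.join(sorted(unknown))}")
        if "reffinder" in methods and not set(agg.METHODS) <= set(methods):
            raise ValueError("reffinder requires delta_ct, bestkeeper, genorm and normfinder")
        self.table = table
        self.efficiency = efficiency
        self.methods = tuple(methods)
        self.v_cutoff = v_cutoff
        self.availability_cutoff = availability_cutoff
        self.bestkeeper_dispersion = bestkeeper_dispersion
        self.group_by = group_by

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "ReferenceGeneStability":
        """Build from a long-format frame (sample, group, gene, replicate, ct)."""
        return cls(CtTable(data), **kwargs)

    @classmethod
    def from_csv(
        cls, path: str | Path, layout: str = "long", *, drop_incomplete: bool = False, **kwargs
    ) -> "ReferenceGeneStability":
        table = read_ct_table(path, layout=layout, allow_missing=drop_incomplete)
        if drop_incomplete:
            table = table.drop_incomplete_samples()
        return cls(table, **kwargs)

    def fit(self) -> "StabilityResults":
        matrix = self.table.to_matrix()
        quantities = relative_quantities(matrix, self.efficiency)
        out: dict[str, object] = {}
        if "delta_ct" in self.methods:
            out["delta_ct"] = pw.delta_ct_stability(matrix)
        if "bestkeeper" in self.methods:
            out["bestkeeper"] = pw.bestkeeper(matrix, dispersion=self.bestkeeper_dispersion)
        if "genorm" in self.methods:
            out["genorm"] = gn.genorm_full(
                quantities,
                v_cutoff=self.v_cutoff,
                availability_cutoff=self.availability_cutoff,
            )
        if "normfinder" in self.methods:
            out["normfinder"] = nf.normfinder_stability(self.table, group_by=self.group_by)
        reff = None
        rank_table = None
        if "reffinder" in self.methods:
            rank_table = agg.rank_table_from_results(
                out["delta_ct"].ranks,  # type: ignore[union-attr]
                out["bestkeeper"].ranks,  # type: ignore[union-attr]
                out["genorm"].ranking,  # type: ignore[union-attr]
                out["normfinder"].ranks,  # type: ignore[union-attr]
            )
            reff = agg.reffinder(rank_table)
        return StabilityResults(
            model=self,
            quantities=quantities,
            delta_ct=out.get("delta_ct"),
            bestkeeper=out.get("bestkeeper"),
            genorm=out.get("genorm"),
            normfinder=out.get("normfinder"),
            rank_table=rank_table,
            reffinder=reff,
        )


@dataclass
class StabilityResults:
    """Fitted stability estimates, ranks, aggregation and diagnostics."""

    model: ReferenceGeneStability
    quantities: RelQuantMatrix
    delta_ct: pw.PairwiseStability | None
    bestkeeper: pw.BestKeeperResult | None
    genorm: gn.GeNormResult | None
    normfinder: nf.NormFinderResult | None
    rank_table: pd.DataFrame | None
    reffinder: agg.RefFinderResult | None

    @property
    def genes(self) -> list[str]:
        return self.model.table.genes

    def stability_frame(self) -> pd.DataFrame:
        """Per-gene stability value and rank for every fitted method."""
        cols = {}
        if self.delta_ct is not None:
            cols["delta_ct"] = self.delta_ct.stability
            cols["delta_ct_rank"] = self.delta_ct.ranks
        if self.bestkeeper is not None:
            cols["bestkeeper"] = self.bestkeeper.dispersion
            cols["bestkeeper_rank"] = self.bestkeeper.ranks
        if self.genorm is not None:
            cols["genorm_m"] = self.genorm.m_values
            cols["genorm_rank"] = self.genorm.ranking
        if self.normfinder is not None:
            cols["normfinder"] = self.normfinder.stability
            cols["normfinder_rank"] = self.normfinder.ranks
        if self.reffinder is not None:
            cols["geomean"] = self.reffinder.geomean
            cols["final_rank"] = self.reffinder.final_ranks
        return pd.DataFrame(cols).loc[self.genes]

    def ct_summary(self) -> pd.DataFrame:
        return summarize_all(self.model.table)

    def summary(self) -> str:
        """Plain-text report: stability values, ranks, geNorm decisions."""
        lines = []
        lines.append("Reference-gene stability analysis")
        lines.append("=" * 64)
        t = self.model.table
        lines.append(
            f"{len(t.genes)} genes, {len(t.samples)} samples, "
            f"{t.groups.nunique()} groups"
        )
        sf = self.stability_frame()
        value_cols = [c for c in sf.columns if not c.endswith("_rank") and c != "final_rank"]
        fmt = sf.copy()
        for c in value_cols:
            fmt[c] = fmt[c].map(lambda v: f"{v:.3f}")
        lines.append("")
        lines.append(fmt.to_string())
        if self.genorm is not None:
            g = self.genorm
            lines.append("")
            lines.append(
                f"geNorm: most stable pair {g.final_pair[0]} / {g.final_pair[1]}; "
                f"all M < {g.availability_cutoff}: {bool(g.available.all())}"
            )
            if g.v_series is not None:
                vtxt = ", ".join(f"V{n}/{n+1}={v:.3f}" for n, v in g.v_series.items())
                lines.append(f"geNorm V series: {vtxt}")
                tag = "" if g.optimal_met_cutoff else " (no V below cutoff)"
                lines.append(
                    f"Optimal number of reference genes at cutoff "
                    f"{g.v_cutoff}: {g.optimal_n}{tag}"
                )
        if self.normfinder is not None:
            lines.append(
                f"NormFinder: inter-group dispersion gamma2 = {self.normfinder.gamma2:.4f}; "
                f"{100 * self.normfinder.clamped_fraction:.0f}% variance estimates clamped"
            )
        if self.reffinder is not None:
            lines.append(
                "RefFinder comprehensive order (most stable first): "
                + " > ".join(self.reffinder.order)
            )
        return "\n".join(lines)

    # -- plotting ------------------------------------------------------

    def plot_m_trajectory(self, ax=None):
        """Stepwise-exclusion M profile, least stable genes dropped left to right."""
        if self.genorm is None:
            raise ValueError("geNorm was not fitted")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        traj = self.genorm.m_trajectory
        xs = list(range(len(traj)))
        mean_m = [float(m.mean()) for m in traj]
        labels = self.genorm.exclusion_order + ["/".join(self.genorm.final_pair)]
        ax.plot(xs, mean_m, marker="o")
        ax.set_xticks(xs, labels, rotation=45, ha="right")
        ax.set_xlabel("least stable gene excluded")
        ax.set_ylabel("average expression stability M")
        return ax

    def plot_v_series(self, ax=None):
        """Pairwise variation V(n, n+1) with the decision cutoff."""
        if self.genorm is None or self.genorm.v_series is None:
            raise ValueError("geNorm V series was not fitted")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.genorm.v_series
        ax.bar([f"V{n}/{n+1}" for n in v.index], v.to_numpy())
        ax.axhline(self.genorm.v_cutoff, ls="--", color="k", lw=1)
        ax.set_ylabel("pairwise variation V")
        return ax


class MultiConditionStability:
    """Cross-condition aggregation of per-condition stability analyses."""

    def __init__(self, models: Mapping[str, ReferenceGeneStability]) -> None:
        if not models:
            raise ValueError("at least one condition required")
        gene_sets = {c: tuple(m.table.genes) for c, m in models.items()}
        first = next(iter(gene_sets.values()))
        for c, gs in gene_sets.items():
            if set(gs) != set(first):
                raise ValueError(f"gene set mismatch in condition {c!r}")
        self.models = dict(models)

    def fit(self, exclude: Iterable[str] = ()) -> "MultiConditionResults":
        results = {c: m.fit() for c, m in self.models.items()}
        per_method: dict[str, dict[str, pd.Series]] = {}
        for c, r in results.items():
            sf = r.stability_frame()
            for m in ("delta_ct", "bestkeeper", "genorm", "normfinder"):
                col = "genorm_rank" if m == "genorm" else f"{m}_rank"
                if col in sf.columns:
                    per_method.setdefault(m, {})[c] = sf[col]
            if r.reffinder is not None:
                per_method.setdefault("reffinder", {})[c] = r.reffinder.final_ranks
        averages = {m: agg.average_ranking(cond) for m, cond in per_method.items()}
        sensitivity = None
        exclude = tuple(exclude)
        if exclude:
            sensitivity = {
                m: agg.exclusion_sensitivity(cond, exclude) for m, cond in per_method.items()
            }
        return MultiConditionResults(
            condition_results=results,
            per_method_ranks=per_method,
            average_ranks=averages,
            sensitivity=sensitivity,
            excluded=exclude,
        )


@dataclass
class MultiConditionResults:
    condition_results: dict[str, StabilityResults]
    per_method_ranks: dict[str, dict[str, pd.Series]]
    average_ranks: dict[str, pd.Series]
    sensitivity: dict[str, agg.SensitivityResult] | None
    excluded: tuple[str, ...]

    def summary(self) -> str:
        lines = ["Cross-condition average rankings", "=" * 48]
        frame = pd.DataFrame(self.average_ranks)
        lines.append(frame.map(lambda v: f"{agg.round_half_up(v):.2f}").to_string())
        if self.sensitivity:
            lines.append("")
            lines.append(f"Excluding condition(s): {', '.join(self.excluded)}")
            kept = pd.DataFrame({m: s.retained_average for m, s in self.sensitivity.items()})
            lines.append(kept.map(lambda v: f"{agg.round_half_up(v):.2f}").to_string())
        return "\n".join(lines)
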