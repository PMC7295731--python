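"""Ct tables: reading, validation, summaries and group comparisons.

A Ct (threshold-cycle) table is the universal input to every stability
method in this package: one Ct value per gene x sample x technical
replicate, with each sample annotated by the experimental group it
belongs to (a life stage, a population, a treatment level, ...).

The canonical on-disk representation is a long CSV/TSV with columns
``sample,group,gene,replicate,ct``; a wide layout (one row per sample,
one column per gene) is also accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LONG_COLUMNS = ("sample", "group", "gene", "replicate", "ct")

CT_MAX = 45.0  # instruments stop at 40-45 cycles; anything above is not a detection


class CtTableError(ValueError):
    """Raised for structurally invalid Ct tables."""


@dataclass(frozen=True)
class SampleAnnotation:
    """A sample's identity and its experimental group membership."""

    sample: str
    group: str
    tags: Mapping[str, str] = field(default_factory=dict)


class CtTable:
    """Ct values indexed by gene x sample x replicate with group labels.

    Parameters
    ----------
    data
        Long-format frame with columns ``sample, group, gene, replicate, ct``.
        Extra columns are kept as per-row annotations.
    validate
        Check invariants on construction (finite Ct in (0, 45], unique
        (gene, sample, replicate) keys, one group per sample).
    require_complete
        Additionally require every (gene, sample) pair to be present.
    allow_missing
        Permit NaN Ct entries (flagged missing reactions).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        validate: bool = True,
        require_complete: bool = True,
        allow_missing: bool = False,
    ) -> None:
        missing_cols = [c for c in LONG_COLUMNS if c not in data.columns]
        if missing_cols:
            raise CtTableError(f"missing required column(s): {', '.join(missing_cols)}")
        df = data.copy()
        df["sample"] = df["sample"].astype(str)
        df["group"] = df["group"].astype(str)
        df["gene"] = df["gene"].astype(str)
        df["ct"] = pd.to_numeric(df["ct"], errors="coerce") if allow_missing else df["ct"]
        self.data = df.reset_index(drop=True)
        if validate:
            self.validate(require_complete=require_complete, allow_missing=allow_missing)

    # -- invariants ------------------------------------------------------

    def validate(self, *, require_complete: bool = True, allow_missing: bool = False) -> None:
        df = self.data
        ct = pd.to_numeric(df["ct"], errors="coerce")
        bad = ct.isna() if not allow_missing else pd.Series(False, index=df.index)
        if bad.any():
            raise CtTableError(
                f"non-numeric or missing ct values in rows {list(df.index[bad][:5])}"
            )
        present = ct.dropna()
        if ((present <= 0) | (present > CT_MAX)).any():
            raise CtTableError(f"ct values must lie in (0, {CT_MAX}]")
        dup = df.duplicated(subset=["gene", "sample", "replicate"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["gene", "sample", "replicate"]].tolist()
            raise CtTableError(f"duplicate (gene, sample, replicate) key: {key}")
        ngroups = df.groupby("sample")["group"].nunique()
        if (ngroups > 1).any():
            raise CtTableError(
                f"sample(s) assigned to more than one group: "
                f"{list(ngroups.index[ngroups > 1])}"
            )
        if (df["group"].str.len() == 0).any():
            raise CtTableError("empty group label")
        if require_complete:
            counts = df.pivot_table(
                index="gene", columns="sample", values="ct", aggfunc="size", fill_value=0
            )
            if (counts == 0).any().any():
                missing = [
                    (g, s)
                    for g in counts.index
                    for s in counts.columns
                    if counts.loc[g, s] == 0
                ]
                raise CtTableError(f"missing (gene, sample) pairs: {missing[:5]}")

    # -- accessors -------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        """Gene ids in order of first appearance."""
        return list(dict.fromkeys(self.data["gene"]))

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    @property
    def groups(self) -> pd.Series:
        """Series mapping sample id -> group label (first-appearance order)."""
        return self.data.drop_duplicates("sample").set_index("sample")["group"]

    @property
    def annotations(self) -> list[SampleAnnotation]:
        out = []
        for s, g in self.groups.items():
            out.append(SampleAnnotation(sample=s, group=g))
        return out

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CtTable({len(self.genes)} genes x {len(self.samples)} samples, "
            f"{len(self.data)} entries)"
        )

    def subset_samples(self, samples: Iterable[str]) -> "CtTable":
        keep = set(samples)
        return CtTable(self.data[self.data["sample"].isin(keep)], validate=False)

    def drop_incomplete_samples(self) -> "CtTable":
        """Remove samples lacking a Ct for any gene (complete-matrix methods)."""
        counts = self.data.pivot_table(
            index="gene", columns="sample", values="ct", aggfunc="size", fill_value=0
        )
        full = counts.columns[(counts > 0).all(axis=0)]
        return self.subset_samples(full)

    def to_matrix(self) -> pd.DataFrame:
        """Gene x sample Ct matrix after technical-replicate averaging.

        Raises ``CtTableError`` if any cell is missing; run
        ``drop_incomplete_samples`` first for incomplete data.
        """
        avg = average_technical_replicates(self)
        mat = avg.data.pivot_table(index="gene", columns="sample", values="ct")
        mat = mat.reindex(index=self.genes, columns=self.samples)
        if mat.isna().any().any():
            raise CtTableError("incomplete Ct matrix; use drop_incomplete_samples()")
        return mat


@dataclass(frozen=True)
class SummaryStats:
    """Per-gene descriptive statistics of sample-level Ct values (cycles)."""

    gene: str
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    range: float
    mean: float


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    difference: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    gene: str
    f_statistic: float
    p_value: float
    group_means: Mapping[str, float]
    tukey: Sequence[PairwiseComparison] = ()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_ct_table(path: str | Path, layout: str = "long", *, allow_missing: bool = False) -> CtTable:
    """Read a Ct table from a CSV/TSV file.

    ``layout='long'`` expects columns ``sample,group,gene,replicate,ct``.
    ``layout='wide'`` expects ``sample,group,<gene1>,<gene2>,...`` with
    technical replicates as repeated sample rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [str(c).strip() for c in df.columns]
    if layout == "long":
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise CtTableError(f"missing required column(s): {', '.join(missing)}")
        long = df
    elif layout == "wide":
        for c in ("sample", "group"):
            if c not in df.columns:
                raise CtTableError(f"missing required column(s): {c}")
        gene_cols = [c for c in df.columns if c not in ("sample", "group")]
        if not gene_cols:
            raise CtTableError("wide layout needs at least one gene column")
        # repeated sample rows are technical replicates, numbered in file order
        df = df.copy()
        df["replicate"] = df.groupby("sample").cumcount() + 1
        long = df.melt(
            id_vars=["sample", "group", "replicate"],
            value_vars=gene_cols,
            var_name="gene",
            value_name="ct",
        )
        # preserve the gene column order from the file
        long["gene"] = pd.Categorical(long["gene"], categories=gene_cols, ordered=True)
        long = long.sort_values(["gene", "sample", "replicate"], kind="stable")
        long["gene"] = long["gene"].astype(str)
    else:
        raise ValueError(f"unknown layout {layout!r}; expected 'long' or 'wide'")
    ct = pd.to_numeric(long["ct"], errors="coerce")
    if ct.isna().any() and not allow_missing:
        bad = long.loc[ct.isna(), "ct"].iloc[0]
        raise CtTableError(f"non-numeric ct value: {bad!r}")
    long = long.assign(ct=ct)
    return CtTable(long, allow_missing=allow_missing, require_complete=not allow_missing)


def average_technical_replicates(table: CtTable, *, missing: str = "error") -> CtTable:
    """Collapse technical replicates to one arithmetic-mean Ct per (gene, sample).

    ``missing='drop'`` averages the present replicate values only;
    ``missing='error'`` rejects NaN entries.
    """
    df = table.data
    if df["ct"].isna().any():
        if missing == "error":
            raise CtTableError("missing ct values; pass missing='drop' to ignore them")
        df = df.dropna(subset=["ct"])
    out = (
        df.groupby(["gene", "sample", "group"], sort=False, as_index=False)["ct"].mean()
    )
    out["replicate"] = 1
    return CtTable(out[list(LONG_COLUMNS)], validate=False)


def _tukey_hinges(values: np.ndarray) -> tuple[float, float, float]:
    """Quartiles by the inclusive convention: the median belongs to both halves."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    med = float(np.median(v))
    half = (n + 1) // 2
    return float(np.median(v[:half])), med, float(np.median(v[n - half :]))


def summarize_ct(table: CtTable, gene: str) -> SummaryStats:
    """Descriptive statistics of a gene's sample-level Ct values."""
    if gene not in table.genes:
        raise KeyError(f"unknown gene {gene!r}")
    avg = average_technical_replicates(table)
    values = avg.data.loc[avg.data["gene"] == gene, "ct"].to_numpy(dtype=float)
    q1, med, q3 = _tukey_hinges(values)
    vmin, vmax = float(values.min()), float(values.max())
    return SummaryStats(
        gene=gene,
        n=values.size,
        min=vmin,
        q1=q1,
        median=med,
        q3=q3,
        max=vmax,
        range=vmax - vmin,
        mean=float(values.mean()),
    )


def summarize_all(table: CtTable) -> pd.DataFrame:
    """Summary table for every gene, fixed column order."""
    rows = [summarize_ct(table, g).__dict__ for g in table.genes]
    return pd.DataFrame(rows)[["gene", "n", "min", "q1", "median", "q3", "max", "range", "mean"]]


def _group_values(table: CtTable, gene: str, group_by: Mapping[str, str] | None) -> dict[str, np.ndarray]:
    avg = average_technical_replicates(table)
    sub = avg.data[avg.data["gene"] == gene]
    if group_by is None:
        labels = sub["group"]
    else:
        labels = sub["sample"].map(dict(group_by))
        if labels.isna().any():
            raise KeyError("grouping does not cover all samples")
    return {g: v["ct"].to_numpy(dtype=float) for g, v in sub.groupby(labels, sort=False)}


def anova_oneway(
    table: CtTable, gene: str, group_by: Mapping[str, str] | None = None
) -> AnovaResult:
    """Classical one-way ANOVA on a gene's Ct values across groups.

    A table with zero total variance is degenerate (0/0); it returns
    F = 0, p = 1 with a warning instead of erroring.
    """
    if gene not in table.genes:
        raise KeyError(f"unknown gene {gene!r}")
    groups = _group_values(table, gene, group_by)
    if len(groups) < 2:
        raise ValueError("one-way ANOVA requires at least two groups")
    for label, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {label!r} has fewer than two values")
    arrays = list(groups.values())
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = allv.size - len(arrays)
    if ssb + ssw <= 1e-300:
        warnings.warn(f"zero total variance for gene {gene!r}; returning F=0, p=1")
        f, p = 0.0, 1.0
    elif ssw <= 1e-300:
        f, p = np.inf, 0.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    means = {g: float(v.mean()) for g, v in groups.items()}
    return AnovaResult(gene=gene, f_statistic=float(f), p_value=float(p), group_means=means)


def tukey_hsd(
    table: CtTable,
    gene: str,
    group_by: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> list[PairwiseComparison]:
    """All-pairs Tukey HSD comparisons of group mean Ct at level ``alpha``."""
    groups = _group_values(table, gene, group_by)
    if len(groups) < 2:
        raise ValueError("Tukey HSD requires at least two groups")
    for label, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {label!r} has fewer than two values")
    labels = list(groups)
    arrays = [groups[g] for g in labels]
    if max(a.var() for a in arrays) <= 1e-300 and len({a.mean() for a in arrays}) == 1:
        # identical groups: every difference 0, nothing significant
        return [
            PairwiseComparison((labels[i], labels[j]), 0.0, 1.0, False)
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    res = stats.tukey_hsd(*arrays)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            diff = float(arrays[i].mean() - arrays[j].mean())
            p = float(res.pvalue[i, j])
            out.append(
                PairwiseComparison((labels[i], labels[j]), diff, p, bool(p < alpha))
            )
    return out


def anova_with_tukey(
    table: CtTable, gene: str, group_by: Mapping[str, str] | None = None, alpha: float = 0.05
) -> AnovaResult:
    base = anova_oneway(table, gene, group_by)
    comps = tukey_hsd(table, gene, group_by, alpha)
    return AnovaResult(
        gene=base.gene,
        f_statistic=base.f_statistic,
        p_value=base.p_value,
        group_means=base.group_means,
        tukey=tuple(comps),
    )
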