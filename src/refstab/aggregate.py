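"""Rank construction and aggregation across stability methods and conditions.

RefFinder-style comprehensive ranking: each method (comparative deltaCt,
BestKeeper, geNorm, NormFinder) contributes a per-gene rank; a gene's
comprehensive stability is the geometric mean of its four ranks, and the
final order is ascending in that value. Cross-condition summaries are
arithmetic means of per-condition ranks, with an exclusion-sensitivity
variant that recomputes the averages after dropping chosen conditions.

Ranks follow the competition convention throughout: tied genes share the
smallest applicable rank and the next distinct rank skips the tied count
(1, 1, 3, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

METHODS = ("delta_ct", "bestkeeper", "genorm", "normfinder")


def competition_rank(values, ascending: bool = True) -> pd.Series:
    """Competition (min) ranks: ties share the smallest rank, next skips."""
    s = pd.Series(values, dtype=float)
    if s.empty:
        raise ValueError("cannot rank an empty score vector")
    ranks = s.rank(method="min", ascending=ascending)
    ranks.name = "rank"
    return ranks.astype(int)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (2.345 -> 2.35), as used in report tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RefFinderResult:
    rank_table: pd.DataFrame  # genes x methods
    geomean: pd.Series  # comprehensive stability per gene
    final_ranks: pd.Series  # competition ranks of the geometric means
    order: list[str]  # genes, most stable first


def reffinder(rank_table: pd.DataFrame | Mapping[str, Mapping[str, float]]) -> RefFinderResult:
    """Comprehensive stability = geometric mean of the four method ranks.

    ``rank_table`` is genes x methods (columns must cover all of
    delta_ct, bestkeeper, genorm, normfinder).
    """
    rt = pd.DataFrame(rank_table)
    missing = [m for m in METHODS if m not in rt.columns]
    if missing:
        raise ValueError(f"missing method rank(s): {', '.join(missing)}")
    rt = rt[list(METHODS)].astype(float)
    if rt.isna().any().any():
        raise ValueError("rank table contains missing entries")
    gm = pd.Series(
        np.exp(np.log(rt.to_numpy()).mean(axis=1)), index=rt.index, name="geomean"
    )
    # all-equal ranks must give that rank exactly (min <= geomean <= max)
    equal = rt.min(axis=1) == rt.max(axis=1)
    gm[equal] = rt.min(axis=1)[equal]
    ranks = competition_rank(gm, ascending=True)
    order = list(gm.sort_values(kind="stable").index)
    return RefFinderResult(rank_table=rt, geomean=gm, final_ranks=ranks, order=order)


def average_ranking(per_condition: Mapping[str, Mapping[str, float] | pd.Series]) -> pd.Series:
    """Arithmetic mean rank per gene over conditions.

    Every gene must be ranked in every condition.
    """
    if not per_condition:
        raise ValueError("no conditions given")
    frame = pd.DataFrame({c: pd.Series(r, dtype=float) for c, r in per_condition.items()})
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)]
        raise ValueError(f"gene(s) missing from a condition: {list(bad)}")
    avg = frame.mean(axis=1)
    avg.name = "average_rank"
    return avg


@dataclass(frozen=True)
class SensitivityResult:
    full_average: pd.Series
    retained_average: pd.Series
    excluded: tuple[str, ...]
    shift: pd.Series  # full - retained; positive = gene's average rank improved


def exclusion_sensitivity(
    per_condition: Mapping[str, Mapping[str, float] | pd.Series],
    exclude: Iterable[str],
) -> SensitivityResult:
    """Recompute average rankings with conditions excluded; report shifts."""
    exclude = tuple(exclude)
    unknown = [c for c in exclude if c not in per_condition]
    if unknown:
        raise KeyError(f"unknown condition(s): {', '.join(unknown)}")
    retained = {c: r for c, r in per_condition.items() if c not in exclude}
    if not retained:
        raise ValueError("exclusion leaves zero conditions")
    full = average_ranking(per_condition)
    kept = average_ranking(retained)
    shift = full - kept
    shift.name = "rank_shift"
    return SensitivityResult(
        full_average=full, retained_average=kept, excluded=exclude, shift=shift
    )


def rank_table_from_results(
    delta_ct_ranks: pd.Series,
    bestkeeper_ranks: pd.Series,
    genorm_ranks: pd.Series,
    normfinder_ranks: pd.Series,
) -> pd.DataFrame:
    """Assemble the genes x methods rank table RefFinder aggregates."""
    return pd.DataFrame(
        {
            "delta_ct": delta_ct_ranks,
            "bestkeeper": bestkeeper_ranks,
            "genorm": genorm_ranks,
            "normfinder": normfinder_ranks,
        }
    )
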