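"""geNorm: M values, stepwise exclusion, normalization factors and V series.

A gene's expression stability M is the mean, over all other candidates,
of the standard deviation across samples of the log2 expression ratio
between the two genes. Stable pairs co-vary, so their ratio is nearly
constant and their mutual SD small. Stepwise exclusion repeatedly drops
the gene with the highest M until two remain; those two are the tied
most-stable pair (they have, by construction, identical M in the final
round, since each is the other's only partner).

The pairwise-variation series V(n, n+1) compares normalization factors
(per-sample geometric means of relative quantities) built from the n
and n+1 best-ranked genes; once V falls below a cutoff (0.15 by default)
adding the (n+1)-th gene no longer changes normalization meaningfully,
which fixes the optimal number of reference genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import competition_rank
from .quantify import RelQuantMatrix

logger = logging.getLogger(__name__)

DEFAULT_AVAILABILITY_CUTOFF = 1.5  # M below this = usable reference gene
DEFAULT_V_CUTOFF = 0.15


def _as_quantities(q) -> pd.DataFrame:
    if isinstance(q, RelQuantMatrix):
        mat = q.values
    else:
        mat = pd.DataFrame(q)
    if (mat.to_numpy(dtype=float) <= 0).any():
        raise ValueError("relative quantities must be strictly positive")
    return mat.astype(float)


def genorm_m(quantities) -> pd.Series:
    """Average pairwise log2-ratio SD per gene (the geNorm M value)."""
    mat = _as_quantities(quantities)
    k, n = mat.shape
    if k < 2:
        raise ValueError("need at least two genes")
    if n < 2:
        raise ValueError("need at least two samples")
    logq = np.log2(mat.to_numpy())
    diff = logq[:, None, :] - logq[None, :, :]
    sd = diff.std(axis=2, ddof=1)
    m = sd.sum(axis=1) / (k - 1)  # diagonal is zero; for k=2 both M equal S(1,2)
    return pd.Series(m, index=mat.index, name="M")


@dataclass(frozen=True)
class GeNormResult:
    m_values: pd.Series  # first-iteration M per gene
    m_trajectory: list[pd.Series]  # M per remaining gene, per iteration
    exclusion_order: list[str]  # least stable first
    final_pair: tuple[str, str]
    ranking: pd.Series  # competition ranks; final pair shares rank 1
    ranked_genes: list[str]  # best first (final pair in input order)
    available: pd.Series  # M < availability cutoff, per gene
    availability_cutoff: float
    nf: dict[int, pd.Series] = field(default_factory=dict)  # NF_n per sample
    v_series: pd.Series | None = None  # V(n, n+1) indexed by n
    optimal_n: int | None = None
    optimal_met_cutoff: bool | None = None
    v_cutoff: float = DEFAULT_V_CUTOFF


def genorm_stepwise(
    quantities, availability_cutoff: float = DEFAULT_AVAILABILITY_CUTOFF
) -> GeNormResult:
    """Stepwise exclusion of the least stable gene down to the final pair.

    Ties at the maximal M are broken by input gene order (first listed is
    removed) and logged. The final pair shares rank 1 under competition
    ranking; the next gene takes rank 3.
    """
    mat = _as_quantities(quantities)
    genes = list(mat.index)
    if len(genes) < 3:
        raise ValueError("stepwise exclusion needs at least three genes")
    m0 = genorm_m(mat)
    trajectory: list[pd.Series] = []
    remaining = list(genes)
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = genorm_m(mat.loc[remaining])
        trajectory.append(m)
        worst_val = m.max()
        ties = [g for g in remaining if m[g] == worst_val]
        if len(ties) > 1:
            logger.warning(
                "tie at maximal M (%.6g) among %s; removing first-listed %s",
                worst_val, ties, ties[0],
            )
        worst = ties[0]
        exclusion.append(worst)
        remaining = [g for g in remaining if g != worst]
    final_m = genorm_m(mat.loc[remaining])
    trajectory.append(final_m)
    final_pair = tuple(remaining)
    ranked = list(remaining) + list(reversed(exclusion))
    # competition ranks: pair at 1, then 3, 4, ...
    ranks = pd.Series(0, index=genes, dtype=int)
    ranks[list(final_pair)] = 1
    for pos, g in enumerate(reversed(exclusion)):
        ranks[g] = 3 + pos
    available = m0 < availability_cutoff
    available.name = "available"
    return GeNormResult(
        m_values=m0,
        m_trajectory=trajectory,
        exclusion_order=exclusion,
        final_pair=final_pair,  # type: ignore[arg-type]
        ranking=ranks,
        ranked_genes=ranked,
        available=available,
        availability_cutoff=availability_cutoff,
    )


def normalization_factor(quantities, genes: Sequence[str]) -> pd.Series:
    """NF per sample: geometric mean of the subset's relative quantities."""
    mat = _as_quantities(quantities)
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("a normalization factor needs at least two genes")
    sub = mat.loc[genes]
    nf = pd.Series(
        np.exp(np.log(sub.to_numpy()).mean(axis=0)), index=mat.columns, name="NF"
    )
    return nf


def pairwise_variation_series(quantities, ranked_genes: Sequence[str]) -> pd.Series:
    """V(n, n+1) = SD over samples of log2(NF_n / NF_{n+1}), n = 2..k-1."""
    mat = _as_quantities(quantities)
    ranked = list(ranked_genes)
    k = len(ranked)
    if k < 3:
        raise ValueError("pairwise variation needs at least three genes")
    out = {}
    for n in range(2, k):
        nf_n = normalization_factor(mat, ranked[:n])
        nf_n1 = normalization_factor(mat, ranked[: n + 1])
        ratio = np.log2(nf_n.to_numpy() / nf_n1.to_numpy())
        out[n] = float(np.std(ratio, ddof=1))
    v = pd.Series(out, name="V")
    v.index.name = "n"
    return v


@dataclass(frozen=True)
class OptimalGeneDecision:
    n: int
    met_cutoff: bool  # False when no V fell below the cutoff
    cutoff: float
    trace: tuple[tuple[int, float, bool], ...]  # (n, V, V < cutoff)


def optimal_gene_number(
    v_series: pd.Series | Mapping[int, float], cutoff: float = DEFAULT_V_CUTOFF
) -> OptimalGeneDecision:
    """Smallest n with V(n, n+1) < cutoff; k (all genes) with a warning if none."""
    v = pd.Series(dict(v_series), dtype=float).sort_index()
    if v.empty:
        raise ValueError("empty V series")
    trace = tuple((int(n), float(val), bool(val < cutoff)) for n, val in v.items())
    for n, val in v.items():
        if val < cutoff:
            return OptimalGeneDecision(n=int(n), met_cutoff=True, cutoff=cutoff, trace=trace)
    k = int(v.index.max()) + 1
    warnings.warn(
        f"no V(n, n+1) below cutoff {cutoff}; recommending all {k} genes"
    )
    return OptimalGeneDecision(n=k, met_cutoff=False, cutoff=cutoff, trace=trace)


def genorm_full(
    quantities,
    v_cutoff: float = DEFAULT_V_CUTOFF,
    availability_cutoff: float = DEFAULT_AVAILABILITY_CUTOFF,
) -> GeNormResult:
    """Stepwise ranking plus NF, V series and the optimal-gene-number rule."""
    mat = _as_quantities(quantities)
    res = genorm_stepwise(mat, availability_cutoff=availability_cutoff)
    nf = {
        n: normalization_factor(mat, res.ranked_genes[:n])
        for n in range(2, len(res.ranked_genes) + 1)
    }
    v = pairwise_variation_series(mat, res.ranked_genes)
    decision = optimal_gene_number(v, cutoff=v_cutoff)
    return GeNormResult(
        m_values=res.m_values,
        m_trajectory=res.m_trajectory,
        exclusion_order=res.exclusion_order,
        final_pair=res.final_pair,
        ranking=res.ranking,
        ranked_genes=res.ranked_genes,
        available=res.available,
        availability_cutoff=availability_cutoff,
        nf=nf,
        v_series=v,
        optimal_n=decision.n,
        optimal_met_cutoff=decision.met_cutoff,
        v_cutoff=v_cutoff,
    )
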