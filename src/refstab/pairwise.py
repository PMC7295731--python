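"""Comparative deltaCt stability and BestKeeper descriptive statistics.

The comparative deltaCt method scores a candidate reference gene by how
variable its Ct difference to every other candidate is: for genes i, k
it takes the sample standard deviation of Ct_i - Ct_k over samples, and
averages over partners k. Because a per-sample loading shift adds the
same constant to every gene in that sample, it cancels in the
differences — the method is loading-invariant by construction.

BestKeeper instead works on raw Ct: per-gene dispersion about the mean
Ct, the coefficient of variation, and the Pearson correlation of each
gene with the "BestKeeper index" (the per-sample geometric mean of Ct
across all candidates). Dispersion of raw Ct is *not* loading-invariant,
a documented limitation of the approach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import competition_rank
from .ct_io import CtTable
from .quantify import _as_ct_matrix


@dataclass(frozen=True)
class PairwiseStability:
    sd_matrix: pd.DataFrame  # genes x genes, SD of pairwise Ct differences
    stability: pd.Series  # mean of off-diagonal row entries, per gene
    ranks: pd.Series  # competition ranks, ascending (smaller = more stable)


@dataclass(frozen=True)
class BestKeeperResult:
    mean_ct: pd.Series
    dispersion: pd.Series  # mean absolute deviation about the mean (or SD), cycles
    cv_percent: pd.Series  # 100 * dispersion / mean
    index: pd.Series  # per-sample geometric mean of Ct over genes
    correlation: pd.Series  # Pearson r of each gene's Ct with the index
    ranks: pd.Series  # by dispersion, ascending
    dispersion_kind: str  # 'mad' or 'sd'


def pairwise_sd_matrix(table: CtTable | pd.DataFrame) -> pd.DataFrame:
    """S(i, k) = sample SD (n-1) over samples of Ct_i - Ct_k."""
    mat = _as_ct_matrix(table)
    if mat.shape[0] < 2:
        raise ValueError("need at least two genes")
    if mat.shape[1] < 2:
        raise ValueError("need at least two samples")
    vals = mat.to_numpy(dtype=float)
    diff = vals[:, None, :] - vals[None, :, :]  # genes x genes x samples
    s = diff.std(axis=2, ddof=1)
    np.fill_diagonal(s, 0.0)
    return pd.DataFrame(s, index=mat.index, columns=mat.index)


def delta_ct_stability(table: CtTable | pd.DataFrame) -> PairwiseStability:
    """Mean pairwise-SD stability per gene; lower is more stable."""
    s = pairwise_sd_matrix(table)
    k = s.shape[0]
    off = (s.sum(axis=1)) / (k - 1)  # diagonal is zero
    off.name = "stability"
    return PairwiseStability(
        sd_matrix=s, stability=off, ranks=competition_rank(off, ascending=True)
    )


def bestkeeper(table: CtTable | pd.DataFrame, dispersion: str = "mad") -> BestKeeperResult:
    """BestKeeper descriptives on raw Ct.

    ``dispersion='mad'`` (default) is the mean absolute deviation about
    the mean Ct; ``'sd'`` switches to the sample standard deviation.
    """
    mat = _as_ct_matrix(table)
    if mat.shape[1] < 2:
        raise ValueError("need at least two samples")
    mean_ct = mat.mean(axis=1)
    centered = mat.sub(mean_ct, axis=0)
    if dispersion == "mad":
        disp = centered.abs().mean(axis=1)
    elif dispersion == "sd":
        disp = mat.std(axis=1, ddof=1)
    else:
        raise ValueError("dispersion must be 'mad' or 'sd'")
    index = pd.Series(
        np.exp(np.log(mat.to_numpy(dtype=float)).mean(axis=0)),
        index=mat.columns,
        name="bestkeeper_index",
    )
    corr = {}
    idx = index.to_numpy()
    for g in mat.index:
        x = mat.loc[g].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(idx) == 0:
            corr[g] = 1.0 if np.std(x) == np.std(idx) else np.nan
        else:
            corr[g] = float(np.corrcoef(x, idx)[0, 1])
    disp.name = "dispersion"
    return BestKeeperResult(
        mean_ct=mean_ct,
        dispersion=disp,
        cv_percent=100.0 * disp / mean_ct,
        index=index,
        correlation=pd.Series(corr, name="r"),
        ranks=competition_rank(disp, ascending=True),
        dispersion_kind=dispersion,
    )
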