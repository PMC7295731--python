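"""NormFinder-style model-based stability estimation.

The model decomposes a gene's log2 expression, after removing the
per-sample mean across genes (which absorbs loading differences), into
a gene-specific intra-group variance and a systematic inter-group
deviation. Per gene i and group g:

* sigma2(i, g) — intra-group variance of the centered signal, estimated
  without bias by sigma2 = max(0, k/(k-2) * (s2(i,g) - s2bar(g)/(k-1))),
  where s2 is the within-group sample variance of the centered values
  and s2bar the mean of s2 over genes. Centering k genes deflates each
  variance and couples them; the correction undoes both effects.
* d(i, g) — the gene's group-mean deviation from its overall mean,
  shrunk towards zero by an empirical-Bayes factor
  gamma2 / (gamma2 + sigma2/n_g), where gamma2 is the excess dispersion
  of the observed d values beyond what sampling noise alone explains.

The stability value rho(i) averages |shrunken deviation| plus the
standard error of the intra-group signal over groups; smaller is more
stable. With a single group the deviations vanish by definition and
rho reduces to the gene's intra-group standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import competition_rank
from .ct_io import CtTable
from .quantify import RelQuantMatrix

logger = logging.getLogger(__name__)


def sample_center(y: pd.DataFrame) -> pd.DataFrame:
    """Remove the per-sample mean over genes; columns of the result sum to 0."""
    return y.sub(y.mean(axis=0), axis=1)


def intragroup_variance(
    z: pd.DataFrame, groups: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Unbiased intra-group variance per (gene, group) from centered data.

    Returns the genes x groups estimate matrix and the fraction of
    entries clamped at zero (the raw estimator can go negative).
    """
    k = z.shape[0]
    if k < 3:
        raise ValueError("intra-group variance estimation needs at least 3 genes")
    groups = pd.Series(groups)
    labels = list(dict.fromkeys(groups))
    est = {}
    clamped = 0
    for g in labels:
        cols = groups.index[groups == g]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")
        s2 = z[cols].var(axis=1, ddof=1)
        s2bar = s2.mean()
        raw = (k / (k - 2)) * (s2 - s2bar / (k - 1))
        clamped += int((raw < 0).sum())
        est[g] = raw.clip(lower=0.0)
    sigma2 = pd.DataFrame(est)
    frac = clamped / sigma2.size
    if frac:
        logger.info("clamped %.1f%% of intra-group variance estimates at zero", 100 * frac)
    return sigma2, frac


def intergroup_shrinkage(
    d: pd.DataFrame, sigma2: pd.DataFrame, n_g: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Empirical-Bayes shrinkage of group deviations.

    gamma2 = max(0, Var(d) - mean(sigma2/n_g)) over all (gene, group)
    cells (sample variance, ddof=1); each deviation is multiplied by
    gamma2 / (gamma2 + sigma2(i,g)/n_g). gamma2 = 0 shrinks everything
    to zero: the observed deviations are explained by sampling noise.
    """
    if d.shape[1] < 2:
        return d * 0.0, 0.0
    noise = sigma2.div(n_g, axis=1)
    gamma2 = max(0.0, float(np.var(d.to_numpy(), ddof=1)) - float(noise.to_numpy().mean()))
    if gamma2 == 0.0:
        return d * 0.0, 0.0
    factor = gamma2 / (gamma2 + noise)
    return d * factor, gamma2


@dataclass(frozen=True)
class NormFinderResult:
    stability: pd.Series  # rho per gene; smaller = more stable
    ranks: pd.Series
    sigma2: pd.DataFrame  # genes x groups intra-group variances (log2 units^2)
    d: pd.DataFrame  # raw group deviations
    d_shrunk: pd.DataFrame
    gamma2: float  # shared inter-group dispersion
    n_per_group: pd.Series
    clamped_fraction: float


def _log_quantities(table, use: str) -> tuple[pd.DataFrame, pd.Series]:
    """Genes x samples log2 signal plus the sample -> group mapping."""
    if isinstance(table, RelQuantMatrix):
        if use != "quantity":
            raise ValueError("a RelQuantMatrix carries quantities; pass use='quantity'")
        return np.log2(table.values), None  # type: ignore[return-value]
    if isinstance(table, CtTable):
        mat = table.to_matrix()
        groups = table.groups.reindex(mat.columns)
        if use == "ct":
            # -Ct is log2 abundance up to per-gene constants (E = 2); the
            # constants drop out of centering and group deviations alike
            return -mat, groups
        return np.log2(mat), groups
    raise TypeError("expected a CtTable or RelQuantMatrix")


def normfinder_stability(
    table: CtTable,
    group_by: pd.Series | dict | None = None,
    *,
    use: str = "ct",
) -> NormFinderResult:
    """Model-based stability of each candidate gene; lower rho = more stable.

    ``group_by`` maps sample id -> group label; defaults to the table's
    own group annotations. ``use='ct'`` treats -Ct as the log2 signal
    (the Q = 2^dCt convention); ``use='quantity'`` takes log2 of
    pre-computed relative quantities.
    """
    y, default_groups = _log_quantities(table, use)
    groups = pd.Series(group_by) if group_by is not None else default_groups
    if groups is None:
        raise ValueError("grouping required (pass group_by)")
    groups = groups.reindex(y.columns)
    if groups.isna().any():
        raise ValueError("grouping does not cover all samples")
    k = y.shape[0]
    if k < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    z = sample_center(y)
    labels = list(dict.fromkeys(groups))
    n_g = pd.Series({g: int((groups == g).sum()) for g in labels})

    if len(labels) == 1:
        cols = list(y.columns)
        s2 = z[cols].var(axis=1, ddof=1)
        s2bar = s2.mean()
        sigma2_single = ((k / (k - 2)) * (s2 - s2bar / (k - 1))).clip(lower=0.0)
        rho = np.sqrt(sigma2_single)
        rho.name = "stability"
        sigma2 = sigma2_single.to_frame(labels[0])
        zero = sigma2 * 0.0
        return NormFinderResult(
            stability=rho,
            ranks=competition_rank(rho, ascending=True),
            sigma2=sigma2,
            d=zero,
            d_shrunk=zero,
            gamma2=0.0,
            n_per_group=n_g,
            clamped_fraction=float((s2 - s2bar / (k - 1) < 0).mean()),
        )

    sigma2, clamped = intragroup_variance(z, groups)
    group_means = pd.DataFrame(
        {g: z[groups.index[groups == g]].mean(axis=1) for g in labels}
    )
    d = group_means.sub(group_means.mean(axis=1), axis=0)  # unweighted across groups
    d_shrunk, gamma2 = intergroup_shrinkage(d, sigma2, n_g)
    se = np.sqrt(sigma2.div(n_g, axis=1))
    rho = (d_shrunk.abs() + se).mean(axis=1)
    rho.name = "stability"
    return NormFinderResult(
        stability=rho,
        ranks=competition_rank(rho, ascending=True),
        sigma2=sigma2,
        d=d,
        d_shrunk=d_shrunk,
        gamma2=gamma2,
        n_per_group=n_g,
        clamped_fraction=clamped,
    )
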