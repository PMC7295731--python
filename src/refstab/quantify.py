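"""Amplification efficiency from dilution series, and relative quantities.

A standard curve regresses mean Ct on log10 of relative template
concentration across a dilution series; the per-cycle amplification
efficiency follows from its slope as

    E% = (10^(-1/slope) - 1) x 100

so a perfectly doubling assay (E = 100%) has slope -1/log10(2) = -3.3219.

Relative quantities convert Ct values to the dimensionless abundances
the geNorm family of statistics operates on: x(g, s) = E_g^(minCt_g - Ct(g, s)),
anchored so each gene's most abundant sample has x = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ct_io import CtTable

#: slope of a 100%-efficient assay, cycles per log10 dilution
PERFECT_SLOPE = -1.0 / np.log10(2.0)


@dataclass(frozen=True)
class DilutionSeries:
    """Mean Ct at each point of a serial dilution.

    ``concentrations`` are relative template amounts, strictly positive
    and strictly decreasing (most concentrated point first).
    """

    concentrations: tuple[float, ...]
    cts: tuple[float, ...]
    dilution_factor: float | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        cts = np.asarray(self.cts, dtype=float)
        if conc.size != cts.size:
            raise ValueError("concentrations and cts must have equal length")
        if conc.size < 3:
            raise ValueError("a dilution series needs at least 3 points")
        if (conc <= 0).any():
            raise ValueError("relative concentrations must be strictly positive")
        if not (np.diff(conc) < 0).all():
            raise ValueError("relative concentrations must be strictly decreasing")

    @classmethod
    def from_steps(
        cls, cts, dilution_factor: float, *, start: float = 1.0
    ) -> "DilutionSeries":
        """Build a series from equally spaced dilution steps.

        Step i (0-based) has relative concentration start / factor**i,
        e.g. a fivefold series gives 1, 1/5, 1/25, ...
        """
        cts = tuple(float(c) for c in cts)
        conc = tuple(start / dilution_factor**i for i in range(len(cts)))
        return cls(concentrations=conc, cts=cts, dilution_factor=dilution_factor)


@dataclass(frozen=True)
class StandardCurveFit:
    slope: float  # cycles per log10 concentration
    intercept: float  # cycles
    r_squared: float
    efficiency_percent: float
    valid: bool  # False when slope >= 0 (nonsense assay)


def efficiency_from_slope(slope: float) -> float:
    """E% = (10^(-1/slope) - 1) x 100."""
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(series: DilutionSeries) -> StandardCurveFit:
    """Ordinary least squares of Ct on log10(relative concentration)."""
    x = np.log10(np.asarray(series.concentrations, dtype=float))
    y = np.asarray(series.cts, dtype=float)
    if np.ptp(x) <= 0:
        raise ValueError("degenerate dilution series: no concentration spread")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    valid = slope < 0
    if not valid:
        warnings.warn(f"non-negative standard-curve slope {slope:.4g}; assay flagged invalid")
    eff = efficiency_from_slope(slope) if slope != 0 else float("nan")
    return StandardCurveFit(
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency_percent=eff,
        valid=valid,
    )


def read_dilution_series(
    path: str | Path, dilution_factor: float | None = None
) -> DilutionSeries:
    """Read a dilution-series CSV with columns ``concentration,ct`` or ``step,ct``."""
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "ct" not in df.columns:
        raise ValueError("dilution series file needs a 'ct' column")
    if "concentration" in df.columns:
        order = df.sort_values("concentration", ascending=False)
        return DilutionSeries(
            concentrations=tuple(order["concentration"].astype(float)),
            cts=tuple(order["ct"].astype(float)),
            dilution_factor=dilution_factor,
        )
    if "step" in df.columns:
        if dilution_factor is None:
            raise ValueError("step layout requires a dilution factor")
        order = df.sort_values("step")
        return DilutionSeries.from_steps(order["ct"].astype(float), dilution_factor)
    raise ValueError("dilution series file needs a 'concentration' or 'step' column")


@dataclass(frozen=True)
class RelQuantMatrix:
    """Relative quantities x(gene, sample) in (0, 1], max 1 per gene."""

    values: pd.DataFrame  # genes x samples
    efficiencies: pd.Series  # fold change per cycle, per gene

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def _as_ct_matrix(table) -> pd.DataFrame:
    if isinstance(table, CtTable):
        return table.to_matrix()
    return pd.DataFrame(table)


def relative_quantities(
    table: CtTable | pd.DataFrame,
    efficiency: float | Mapping[str, float] = 2.0,
) -> RelQuantMatrix:
    """Efficiency-corrected relative quantities from a complete Ct matrix.

    x(g, s) = E_g^(minCt_g - Ct(g, s)); the sample attaining the gene's
    minimum Ct gets x = 1. ``efficiency`` is the per-cycle fold change
    (2.0 = 100% efficiency), global or per gene.
    """
    mat = _as_ct_matrix(table)
    if mat.isna().any().any():
        raise ValueError("incomplete Ct matrix")
    if isinstance(efficiency, Mapping):
        eff = pd.Series({g: float(efficiency[g]) for g in mat.index})
    else:
        eff = pd.Series(float(efficiency), index=mat.index)
    if (eff <= 1.0).any():
        raise ValueError("efficiency (fold change per cycle) must exceed 1")
    min_ct = mat.min(axis=1)
    x = pd.DataFrame(
        np.power(eff.to_numpy()[:, None], (min_ct.to_numpy()[:, None] - mat.to_numpy())),
        index=mat.index,
        columns=mat.columns,
    )
    return RelQuantMatrix(values=x, efficiencies=eff)
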