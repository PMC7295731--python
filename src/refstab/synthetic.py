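"""Synthetic Ct tables with known variance structure.

The generator draws Ct values on the cycle (log2) scale — the scale all
implemented statistics operate on — from an additive Gaussian model:

    Ct(i, s, rep) = mu_i + delta(i, group(s)) + L(s) + eps(i, s) + tau(i, s, rep)

with mu_i the gene's base Ct level, delta a fixed per-group effect,
L ~ N(0, sigma_L^2) a sample-loading shift shared by all genes in the
sample, eps ~ N(0, sigma_i^2) the gene's biological instability, and
tau ~ N(0, sigma_tau^2) independent technical-replicate noise.

A gene's true instability is sigma_i^2 plus the variance of its group
effects, which fixes a ground-truth stability ordering that recovery
tests can score against.

Draw order (fixed for reproducibility across versions): all loading
shifts sample-by-sample, then the instability noise gene-major
(gene x sample), then technical noise gene x sample x replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ct_io import CtTable


@dataclass(frozen=True)
class GeneSpec:
    """One gene's generative parameters (all in cycles)."""

    name: str
    base_ct: float
    noise_sd: float = 0.0
    group_effects: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for a synthetic Ct study."""

    genes: tuple[GeneSpec, ...]
    groups: tuple[tuple[str, int], ...]  # (label, number of samples)
    loading_sd: float = 0.3
    technical_sd: float = 0.1
    replicates: int = 3

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names")
        for g in self.genes:
            if not (5.0 < g.base_ct < 40.0):
                raise ValueError(f"base Ct of {g.name} outside (5, 40)")
            if g.noise_sd < 0:
                raise ValueError("negative noise SD")
        if self.loading_sd < 0 or self.technical_sd < 0:
            raise ValueError("negative SD")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not self.groups or any(n < 1 for _, n in self.groups):
            raise ValueError("each group needs at least one sample")

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)


@dataclass(frozen=True)
class GroundTruth:
    """Known stability ordering implied by the generative parameters."""

    order: tuple[str, ...]  # most stable first
    total_instability: pd.Series  # sigma_i^2 + Var_g delta(i, .) per gene
    tied: bool


def default_spec() -> SyntheticSpec:
    """The packaged study-like default: 5 genes x 12 samples x 3 replicates.

    Base Ct levels match the observed per-gene averages of a five-gene
    nematode reference panel (18S rRNA highly abundant at ~12.9 cycles,
    the rest moderate at 21-26); instability SDs span 0.1-0.6 cycles so
    the ground-truth ordering is UBC < actin < GAPDH < a-tubulin < 18S.
    Twelve samples in four life-stage groups of three, three technical
    replicates each.
    """
    genes = (
        GeneSpec("UBC", base_ct=25.53, noise_sd=0.10),
        GeneSpec("actin", base_ct=21.12, noise_sd=0.15),
        GeneSpec("GAPDH", base_ct=24.85, noise_sd=0.20),
        GeneSpec("a-tubulin", base_ct=25.68, noise_sd=0.30),
        GeneSpec("18S rRNA", base_ct=12.89, noise_sd=0.60),
    )
    groups = (("egg", 3), ("juvenile", 3), ("female", 3), ("male", 3))
    return SyntheticSpec(genes=genes, groups=groups)


def ground_truth_order(spec: SyntheticSpec) -> GroundTruth:
    """Ascending total instability; ties broken by input order and flagged."""
    labels = [lbl for lbl, _ in spec.groups]
    totals = {}
    for g in spec.genes:
        deltas = np.array([g.group_effects.get(lbl, 0.0) for lbl in labels])
        totals[g.name] = g.noise_sd**2 + float(np.var(deltas))
    s = pd.Series(totals, name="total_instability")
    order = tuple(s.sort_values(kind="stable").index)  # stable = input-order ties
    tied = bool(s.duplicated().any())
    return GroundTruth(order=order, total_instability=s, tied=tied)


def generate_ct_table(spec: SyntheticSpec, seed: int) -> tuple[CtTable, GroundTruth]:
    """Draw one synthetic Ct table; deterministic given (spec, seed)."""
    rng = np.random.default_rng(seed)
    k = len(spec.genes)
    n = spec.n_samples
    r = spec.replicates

    sample_ids, sample_groups = [], []
    for label, count in spec.groups:
        for j in range(1, count + 1):
            sample_ids.append(f"{label}_{j}")
            sample_groups.append(label)

    loading = rng.normal(0.0, spec.loading_sd, size=n)
    sds = np.array([g.noise_sd for g in spec.genes])
    eps = rng.normal(0.0, 1.0, size=(k, n)) * sds[:, None]
    tau = rng.normal(0.0, spec.technical_sd, size=(k, n, r))

    rows = []
    for i, gene in enumerate(spec.genes):
        for s in range(n):
            base = (
                gene.base_ct
                + gene.group_effects.get(sample_groups[s], 0.0)
                + loading[s]
                + eps[i, s]
            )
            for rep in range(r):
                rows.append(
                    (sample_ids[s], sample_groups[s], gene.name, rep + 1, base + tau[i, s, rep])
                )
    df = pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
    return CtTable(df), ground_truth_order(spec)


# ---------------------------------------------------------------------------
# YAML round-trip for CLI use
# ---------------------------------------------------------------------------


def spec_from_yaml(path: str | Path) -> SyntheticSpec:
    """Load a SyntheticSpec from YAML (see ``spec_to_yaml`` for the shape)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    genes = tuple(
        GeneSpec(
            name=str(g["name"]),
            base_ct=float(g["base_ct"]),
            noise_sd=float(g.get("noise_sd", 0.0)),
            group_effects={str(k): float(v) for k, v in (g.get("group_effects") or {}).items()},
        )
        for g in doc["genes"]
    )
    groups = tuple((str(g["label"]), int(g["n"])) for g in doc["groups"])
    return SyntheticSpec(
        genes=genes,
        groups=groups,
        loading_sd=float(doc.get("loading_sd", 0.3)),
        technical_sd=float(doc.get("technical_sd", 0.1)),
        replicates=int(doc.get("replicates", 3)),
    )


def spec_to_yaml(spec: SyntheticSpec, path: str | Path) -> None:
    doc = {
        "genes": [
            {
                "name": g.name,
                "base_ct": g.base_ct,
                "noise_sd": g.noise_sd,
                "group_effects": dict(g.group_effects),
            }
            for g in spec.genes
        ],
        "groups": [{"label": lbl, "n": n} for lbl, n in spec.groups],
        "loading_sd": spec.loading_sd,
        "technical_sd": spec.technical_sd,
        "replicates": spec.replicates,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
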