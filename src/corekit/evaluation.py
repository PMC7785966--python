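"""Quality evaluation of a candidate core collection.

Compares the core against the original panel (and the removed complement) on
the seven diversity statistics, tests the three headline parameters (Ne, H,
I) with a t-test *paired across loci* — core and original share the same
loci, so the per-locus values are coupled — reports per-compound and total
metabolite means for each set, and flags core membership on the full-panel
PCoA projection (the core is overlaid on the original ordination rather than
re-ordinated alone, so the two sets share axes).

A uniform random-subset baseline provides context for the allele retention
rate achieved by LDSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .diversity import (
    STAT_NAMES,
    DiversitySummary,
    diversity_summary,
    retention_rate,
)
from .io import GenotypeMatrix, MetaboliteTable
from .structure import DistanceMatrix, genetic_distance, pcoa

T_TEST_PARAMS = ("ne", "h", "i")


def paired_t(
    core_values: Sequence[float], original_values: Sequence[float]
) -> tuple[float, float]:
    """Two-sided paired t-test on per-locus differences.

    t = mean(d) / (sd(d)/sqrt(L)) with L-1 degrees of freedom.  Degenerate
    inputs: zero variance of the differences gives p = 1 when the mean is also
    zero, else p = 0 (with a warning).
    """
    x = np.asarray(core_values, dtype=float)
    y = np.asarray(original_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length vectors of length >= 2")
    d = x - y
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        warnings.warn("zero variance of differences with nonzero mean; p -> 0")
        return float(np.sign(mean)) * np.inf, 0.0
    t = mean / (sd / np.sqrt(len(d)))
    p = 2.0 * float(_stats.t.sf(abs(t), len(d) - 1))
    return float(t), p


@dataclass(frozen=True)
class EvaluationReport:
    core_ids: tuple[str, ...]
    removed_ids: tuple[str, ...]
    params: dict[str, dict[str, float]]          # set name -> stat -> mean
    retention_percent: dict[str, float]          # stat -> 100 * core/original
    ra: float                                    # allele retention rate (%)
    t_tests: dict[str, dict[str, float]]         # stat -> {"t": ..., "p": ...}
    coumarin_means: dict[str, dict[str, float]]  # set name -> compound -> mean
    pcoa_overlay: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "core_ids": list(self.core_ids),
            "removed_ids": list(self.removed_ids),
            "params": self.params,
            "retention_percent": self.retention_percent,
            "ra": self.ra,
            "t_tests": self.t_tests,
            "coumarin_means": self.coumarin_means,
        }
        if self.pcoa_overlay is not None:
            out["pcoa_overlay"] = self.pcoa_overlay.to_dict(orient="list")
        return out


def evaluate(
    genotypes: GenotypeMatrix,
    metabolites: MetaboliteTable,
    core_ids: Iterable[str],
    distance: DistanceMatrix | None = None,
    include_pcoa: bool = True,
    n_axes: int = 2,
) -> EvaluationReport:
    """Full quality report for a candidate core collection."""
    core = tuple(core_ids)
    all_ids = set(genotypes.accession_ids)
    unknown = [a for a in core if a not in all_ids]
    if unknown:
        raise ValueError(f"core contains unknown accession {unknown[0]!r}")
    if len(core) == 0:
        raise ValueError("core collection is empty")
    if len(set(core)) == len(all_ids):
        raise ValueError("core collection equals the original panel")
    removed = tuple(a for a in genotypes.accession_ids if a not in set(core))

    summaries = {
        "original": diversity_summary(genotypes),
        "core": diversity_summary(genotypes, core),
        "removed": diversity_summary(genotypes, removed),
    }
    params = {name: dict(s.means) for name, s in summaries.items()}
    retention = {
        stat: 100.0 * params["core"][stat] / params["original"][stat]
        for stat in STAT_NAMES
    }
    ra = retention_rate(summaries["core"], summaries["original"])
    t_tests = {}
    for stat in T_TEST_PARAMS:
        core_vec = [getattr(ld, stat) for ld in summaries["core"].per_locus]
        orig_vec = [getattr(ld, stat) for ld in summaries["original"].per_locus]
        t, p = paired_t(core_vec, orig_vec)
        t_tests[stat] = {"t": t, "p": p}

    met = metabolites.to_frame()
    sets = {"original": list(genotypes.accession_ids), "core": list(core), "removed": list(removed)}
    coumarin_means = {}
    for name, ids in sets.items():
        sub = met.loc[ids]
        means = {c: float(sub[c].mean()) for c in metabolites.compound_ids}
        means["total"] = float(sub.sum(axis=1).mean())
        coumarin_means[name] = means

    overlay = None
    if include_pcoa:
        if distance is None:
            distance = genetic_distance(genotypes)
        res = pcoa(distance, n_axes=n_axes)
        overlay = res.to_frame()
        overlay["in_core"] = [a in set(core) for a in res.accession_ids]
    return EvaluationReport(
        core, removed, params, retention, ra, t_tests, coumarin_means, overlay
    )


@dataclass(frozen=True)
class BaselineResult:
    """Distribution of Ra and total metabolite mean over random subsets."""

    size: int
    reps: int
    ra: np.ndarray
    total_coumarin_mean: np.ndarray
    summary: dict[str, dict[str, float]] = field(default_factory=dict)


def random_baseline(
    genotypes: GenotypeMatrix,
    metabolites: MetaboliteTable,
    size: int,
    reps: int,
    seed: int | None = None,
) -> BaselineResult:
    """Uniform random subsets of a given size: Ra and metabolite-mean context."""
    n = genotypes.n_accessions
    if not 1 <= size < n:
        raise ValueError(f"size must be in [1, {n - 1}]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    full = diversity_summary(genotypes)
    met = metabolites.to_frame()
    ids = np.array(genotypes.accession_ids)
    ras = np.empty(reps)
    totals = np.empty(reps)
    for r in range(reps):
        pick = rng.choice(n, size=size, replace=False)
        subset = ids[np.sort(pick)]
        summ = diversity_summary(genotypes, subset)
        ras[r] = retention_rate(summ, full)
        totals[r] = float(met.loc[list(subset)].sum(axis=1).mean())

    def describe(v: np.ndarray) -> dict[str, float]:
        return {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if reps > 1 else 0.0,
            "q05": float(np.quantile(v, 0.05)),
            "median": float(np.median(v)),
            "q95": float(np.quantile(v, 0.95)),
        }

    return BaselineResult(
        size, reps, ras, totals, {"ra": describe(ras), "total_coumarin_mean": describe(totals)}
    )
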