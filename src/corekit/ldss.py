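"""Least-distance stepwise sampling (LDSS) of nested core collections.

LDSS deletes genetic duplication one accession at a time: at each step the
closest pair of retained accessions is located (this is exactly the first
merge UPGMA would perform, so the procedure is equivalent to the "repeated
clustering" formulation without rebuilding a dendrogram per step) and the
pair member with the lower total metabolite content is removed.  Distances
between the remaining accessions are unaffected by a removal, so the matrix
is simply masked.

Checkpoints are recorded whenever the retained count reaches one of the
requested target sizes, which makes the resulting collections nested by
construction: the 10% core is a subset of the 15% core, and so on.

Tie rules (both documented and deterministic): ties in the minimum distance
resolve to the lowest (row, column) index pair; ties in metabolite score
remove the lexicographically larger accession id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import DiversitySummary, diversity_summary, retention_rate
from .io import GenotypeMatrix, MetaboliteTable
from .structure import DistanceMatrix, genetic_distance

#: The sampling-ratio ladder used throughout: 40% down to 10%.
DEFAULT_RATIOS: tuple[float, ...] = (0.40, 0.35, 0.30, 0.25, 0.20, 0.15, 0.10)


def target_size(n: int, ratio: float, rounding: str = "half_up") -> int:
    """Number of accessions at a sampling ratio (minimum 1)."""
    if not 0 < ratio <= 1:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    if n < 1:
        raise ValueError("n must be >= 1")
    x = n * ratio
    if rounding == "half_up":
        size = math.floor(x + 0.5)
    elif rounding == "floor":
        size = math.floor(x)
    elif rounding == "ceil":
        size = math.ceil(x)
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    return max(size, 1)


@dataclass(frozen=True)
class LdssStep:
    step: int
    removed: str
    partner: str
    pair_distance: float
    removed_total: float


@dataclass(frozen=True)
class CoreCollection:
    """Ordered removal log with checkpointed nested subsets."""

    accession_ids: tuple[str, ...]  # original panel order
    removal_log: tuple[LdssStep, ...]
    checkpoints: dict[float, tuple[str, ...]]  # sampling ratio -> subset
    target_sizes: dict[float, int]

    def core_at(self, ratio: float) -> tuple[str, ...]:
        if ratio not in self.checkpoints:
            raise KeyError(f"no checkpoint at ratio {ratio}")
        return self.checkpoints[ratio]

    def removed_ids(self) -> tuple[str, ...]:
        return tuple(s.removed for s in self.removal_log)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s).copy() for s in self.removal_log])


def ldss_sample(
    distance: DistanceMatrix,
    metabolites: MetaboliteTable,
    ratios: Sequence[float] | None = None,
    sizes: Sequence[int] | None = None,
    rounding: str = "half_up",
) -> CoreCollection:
    """Run LDSS down to the smallest target size, checkpointing on the way.

    ``ratios`` (default the 40%..10% ladder) are converted to sizes with
    :func:`target_size`; pass explicit ``sizes`` to override (e.g. a published
    ladder whose rounding is irregular).
    """
    ids = distance.accession_ids
    n = len(ids)
    scores = metabolites.total_scores()
    missing = [a for a in ids if a not in scores]
    if missing:
        raise ValueError(f"metabolite score missing for accession {missing[0]!r}")
    for a in ids:
        if not np.isfinite(scores[a]):
            raise ValueError(f"metabolite score for {a!r} is not finite")
    if ratios is None and sizes is None:
        ratios = DEFAULT_RATIOS
    if sizes is None:
        sizes = [target_size(n, r, rounding) for r in ratios]  # type: ignore[union-attr]
    elif ratios is None:
        ratios = [s / n for s in sizes]
    if len(ratios) != len(sizes):
        raise ValueError("ratios and sizes must have the same length")
    if len(set(sizes)) != len(sizes):
        raise ValueError(f"duplicate target sizes: {sorted(sizes)}")
    if any(s < 1 or s > n for s in sizes):
        raise ValueError("target sizes must lie in [1, n]")
    by_size = sorted(zip(sizes, ratios), reverse=True)

    d = distance.values.copy().astype(float)
    np.fill_diagonal(d, np.inf)
    alive = np.ones(n, dtype=bool)
    log: list[LdssStep] = []
    checkpoints: dict[float, tuple[str, ...]] = {}
    targets = list(by_size)
    current = n

    def record_hits() -> None:
        nonlocal targets
        while targets and targets[0][0] == current:
            size, ratio = targets.pop(0)
            checkpoints[ratio] = tuple(ids[i] for i in range(n) if alive[i])

    record_hits()
    smallest = by_size[-1][0]
    step = 0
    while current > smallest:
        masked = np.where(np.outer(alive, alive), d, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if i > j:  # argmin returns the lowest (row, col) in row-major order
            i, j = j, i
        a, b = ids[i], ids[j]
        if scores[a] < scores[b]:
            drop, keep = a, b
        elif scores[b] < scores[a]:
            drop, keep = b, a
        else:  # equal totals: remove the lexicographically larger id
            drop, keep = (a, b) if a > b else (b, a)
        step += 1
        log.append(LdssStep(step, drop, keep, float(d[i, j]), float(scores[drop])))
        alive[ids.index(drop)] = False
        current -= 1
        record_hits()
    return CoreCollection(
        ids,
        tuple(log),
        checkpoints,
        {ratio: size for size, ratio in by_size},
    )


@dataclass(frozen=True)
class LadderResult:
    """Per-ratio diversity and metabolite summaries for an LDSS ladder."""

    core: CoreCollection
    table: pd.DataFrame
    summaries: dict[float, DiversitySummary]
    full_summary: DiversitySummary


def ladder(
    genotypes: GenotypeMatrix,
    metabolites: MetaboliteTable,
    ratios: Sequence[float] | None = None,
    sizes: Sequence[int] | None = None,
    distance: DistanceMatrix | None = None,
    distance_kind: str = "band_sq_euclidean",
    rounding: str = "half_up",
) -> LadderResult:
    """Build the nested ladder and summarize each checkpoint.

    The output table mirrors the usual core-collection report: one row for the
    original panel plus one per sampling ratio, with the seven diversity
    means, the allele retention rate Ra and per-compound / total metabolite
    means (mg/g).
    """
    if distance is None:
        distance = genetic_distance(genotypes, distance_kind)
    if tuple(distance.accession_ids) != tuple(genotypes.accession_ids):
        raise ValueError("distance and genotypes must cover the same accessions")
    core = ldss_sample(distance, metabolites, ratios=ratios, sizes=sizes, rounding=rounding)
    full = diversity_summary(genotypes)
    met = metabolites.to_frame().loc[list(genotypes.accession_ids)]

    rows = []
    summaries: dict[float, DiversitySummary] = {}

    def one_row(name: str, ratio: float, subset_ids: Sequence[str]) -> dict:
        summ = diversity_summary(genotypes, subset_ids) if ratio < 1.0 else full
        ra = retention_rate(summ, full)
        if ratio < 1.0:
            summ = replace(summ, ra=ra)
            summaries[ratio] = summ
        sub = met.loc[list(subset_ids)]
        row = {
            "name": name,
            "ratio": ratio,
            "size": len(subset_ids),
            **{stat: summ.means[stat] for stat in summ.means},
            "ra": ra,
        }
        for compound in metabolites.compound_ids:
            row[f"mean_{compound}"] = float(sub[compound].mean())
        row["mean_total"] = float(sub.sum(axis=1).mean())
        return row

    rows.append(one_row("original", 1.0, list(genotypes.accession_ids)))
    for ratio in sorted(core.checkpoints, reverse=True):
        if ratio >= 1.0:
            continue
        name = f"{round(ratio * 100):g}CC"
        rows.append(one_row(name, ratio, core.checkpoints[ratio]))
    return LadderResult(core, pd.DataFrame(rows), summaries, full)
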