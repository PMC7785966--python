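"""Per-locus genetic diversity statistics for codominant SSR data.

With :math:`p_i` the allele frequencies at a locus and :math:`N` the number of
typed accessions there, the statistics are

* ``Na`` — observed allele count,
* ``Ne`` — effective allele number, :math:`1 / \\sum p_i^2`,
* ``Ho`` — observed heterozygosity, the heterozygote fraction among typed,
* ``H``  — Nei's gene diversity, :math:`1 - \\sum p_i^2` (plug-in),
* ``He`` — unbiased expected heterozygosity, :math:`\\frac{2N}{2N-1} H`
  (Levene's small-sample correction — the POPGENE convention, which is why a
  panel can report both 0.72 for He and 0.71 for H on the same data),
* ``I``  — Shannon's information index, :math:`-\\sum p_i \\ln p_i`,
* ``PIC`` — Botstein's polymorphism information content,
  :math:`1 - \\sum p_i^2 - \\sum_{i<j} 2 p_i^2 p_j^2`.

Missing calls are handled by pairwise deletion per locus: frequencies and Ho
use only the accessions typed at that locus.  Means across loci are
unweighted.  The allele retention rate of a subset is
``Ra = 100 x meanNa(subset) / meanNa(full)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import MISSING, GenotypeMatrix

STAT_NAMES = ("na", "ne", "ho", "he", "i", "h", "pic")


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Per-locus allele frequencies with the per-locus typed count."""

    frequencies: dict[str, dict[int, float]]
    n_typed: dict[str, int]

    def __post_init__(self) -> None:
        for locus, freqs in self.frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"frequencies at locus {locus!r} sum to {total}")
            if any(f <= 0 for f in freqs.values()):
                raise ValueError(f"zero/negative frequency at locus {locus!r}")


@dataclass(frozen=True)
class LocusDiversity:
    locus: str
    na: int
    ne: float
    ho: float
    he: float
    i: float
    h: float
    pic: float
    n_typed: int


@dataclass(frozen=True)
class DiversitySummary:
    """Per-locus statistics plus their unweighted means across loci."""

    per_locus: tuple[LocusDiversity, ...]
    means: dict[str, float]
    total_alleles: int
    ra: float | None = None  # set when the summary describes a subset

    @property
    def locus_ids(self) -> tuple[str, ...]:
        return tuple(ld.locus for ld in self.per_locus)

    def to_dict(self) -> dict:
        out = {
            "means": dict(self.means),
            "total_alleles": self.total_alleles,
            "per_locus": [vars(ld).copy() for ld in self.per_locus],
        }
        if self.ra is not None:
            out["ra"] = self.ra
        return out


def _subset_indices(genotypes: GenotypeMatrix, subset: Iterable[str] | None) -> np.ndarray:
    if subset is None:
        return np.arange(genotypes.n_accessions)
    return genotypes.accession_indices(subset)


def allele_frequencies(
    genotypes: GenotypeMatrix, subset: Iterable[str] | None = None
) -> AlleleFrequencyTable:
    """Allele frequencies per locus: copies / (2 x typed accessions).

    Missing calls are excluded (pairwise deletion).  A locus with no typed
    accession in the subset is a hard error naming the locus.
    """
    idx = _subset_indices(genotypes, subset)
    freqs: dict[str, dict[int, float]] = {}
    n_typed: dict[str, int] = {}
    for l, locus in enumerate(genotypes.locus_ids):
        calls = genotypes.calls[idx, l, :]
        typed = calls[calls[:, 0] != MISSING]
        if typed.size == 0:
            raise ValueError(f"locus {locus!r} has no typed accession in the subset")
        alleles, counts = np.unique(typed.ravel(), return_counts=True)
        denom = typed.shape[0] * 2
        freqs[locus] = {int(a): float(c) / denom for a, c in zip(alleles, counts)}
        n_typed[locus] = int(typed.shape[0])
    return AlleleFrequencyTable(freqs, n_typed)


def _diversity_from_freqs(
    locus: str, freqs: dict[int, float], ho: float, n_typed: int
) -> LocusDiversity:
    p = np.array(sorted(freqs.values(), reverse=True), dtype=float)
    sum_p2 = float(np.sum(p**2))
    sum_p4 = float(np.sum(p**4))
    h = 1.0 - sum_p2
    he = (2 * n_typed / (2 * n_typed - 1)) * h if n_typed >= 1 else h
    shannon = float(-np.sum(p * np.log(p)))
    pic = 1.0 - sum_p2 - (sum_p2**2 - sum_p4)  # Σ_{i<j} 2 p_i² p_j² = (Σp²)² − Σp⁴
    return LocusDiversity(
        locus=locus,
        na=len(freqs),
        ne=1.0 / sum_p2,
        ho=ho,
        he=he,
        i=shannon,
        h=h,
        pic=pic,
        n_typed=n_typed,
    )


def locus_diversity(
    genotypes: GenotypeMatrix, locus: str, subset: Iterable[str] | None = None
) -> LocusDiversity:
    """All seven statistics for one locus (pairwise deletion of missing)."""
    idx = _subset_indices(genotypes, subset)
    l = genotypes.locus_index(locus)
    calls = genotypes.calls[idx, l, :]
    typed = calls[calls[:, 0] != MISSING]
    if typed.size == 0:
        raise ValueError(f"locus {locus!r} has no typed accession in the subset")
    alleles, counts = np.unique(typed.ravel(), return_counts=True)
    denom = typed.shape[0] * 2
    freqs = {int(a): float(c) / denom for a, c in zip(alleles, counts)}
    ho = float(np.mean(typed[:, 0] != typed[:, 1]))
    return _diversity_from_freqs(locus, freqs, ho, typed.shape[0])


def diversity_summary(
    genotypes: GenotypeMatrix, subset: Iterable[str] | None = None
) -> DiversitySummary:
    """Per-locus diversity plus unweighted means and the total allele count."""
    if genotypes.n_loci < 1:
        raise ValueError("genotype matrix has no loci")
    idx = _subset_indices(genotypes, subset)
    table = allele_frequencies(genotypes, subset)
    per_locus = []
    for l, locus in enumerate(genotypes.locus_ids):
        calls = genotypes.calls[idx, l, :]
        typed = calls[calls[:, 0] != MISSING]
        ho = float(np.mean(typed[:, 0] != typed[:, 1]))
        per_locus.append(
            _diversity_from_freqs(locus, table.frequencies[locus], ho, typed.shape[0])
        )
    means = {
        stat: float(np.mean([getattr(ld, stat) for ld in per_locus]))
        for stat in STAT_NAMES
    }
    total = int(sum(ld.na for ld in per_locus))
    return DiversitySummary(tuple(per_locus), means, total)


def retention_rate(
    subset_summary: DiversitySummary | float, full_summary: DiversitySummary | float
) -> float:
    """Allele retention rate Ra (%), reported to 2 decimals.

    Accepts two :class:`DiversitySummary` objects over the same loci, or the
    two mean-Na values directly.
    """
    if isinstance(subset_summary, DiversitySummary) and isinstance(
        full_summary, DiversitySummary
    ):
        if subset_summary.locus_ids != full_summary.locus_ids:
            raise ValueError("retention_rate requires identical locus sets")
        sub_mean = subset_summary.means["na"]
        full_mean = full_summary.means["na"]
    else:
        sub_mean = float(subset_summary)  # type: ignore[arg-type]
        full_mean = float(full_summary)  # type: ignore[arg-type]
    if full_mean <= 0:
        raise ValueError("full-panel mean Na must be positive")
    return round(100.0 * sub_mean / full_mean, 2)
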