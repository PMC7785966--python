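"""Synthetic germplasm panels with controlled population structure.

The generator emulates a wild medicinal-plant panel of the kind the pipeline
analyses: a few weakly differentiated populations scored at a modest number
of multi-allelic SSR loci, with skewed, population-structured metabolite
profiles.

Genetics follow the Balding–Nichols model: each locus draws ancestral allele
frequencies ``p`` from a flat symmetric Dirichlet over its allele count, and
each population draws its own frequencies from ``Dirichlet(p (1-F)/F)``,
which has expectation ``p`` and Wright's fixation index ``F`` as the expected
differentiation.  Genotypes are unions of two gametes drawn within the
population (Hardy–Weinberg equilibrium, no linkage).  Missing calls are
masked completely at random.

Metabolite concentrations are log-normal per compound with a multiplicative
per-population shift on the natural scale (i.e. additive on the log scale),
truncated at a configurable maximum rather than redrawn — a small, documented
bias that caps unrealistic tails.

``study_like_config`` reproduces the study geometry this package was built
around: 208 accessions in three populations of 70/69/69, 17 loci with 4–15
alleles each, F targeting the ~6% among-population variance regime, and six
coumarins dominated by columbianadin and osthole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix, MetaboliteTable

#: Band within which the realized among-population AMOVA percentage is
#: expected to fall for the study-shaped default configuration (replicate calibration).
STUDY_LIKE_AMOVA_BAND: tuple[float, float] = (2.0, 12.0)


@dataclass(frozen=True)
class CompoundModel:
    """Log-normal model of one compound: exp(N(log_median, log_sd²)) mg/g."""

    name: str
    log_median: float
    log_sd: float
    pop_shifts: tuple[float, ...] = ()  # multiplicative, one per population


@dataclass(frozen=True)
class SyntheticConfig:
    population_sizes: tuple[int, ...] = (70, 69, 69)
    population_names: tuple[str, ...] = ("pop1", "pop2", "pop3")
    n_loci: int = 17
    allele_range: tuple[int, int] = (4, 15)
    fst: float = 0.035
    missing_rate: float = 0.01
    compounds: tuple[CompoundModel, ...] = ()
    coumarin_max: float = 20.0
    seed: int = 715

    def __post_init__(self) -> None:
        if len(self.population_sizes) != len(self.population_names):
            raise ValueError("population_sizes and population_names length mismatch")
        if any(s < 2 for s in self.population_sizes):
            raise ValueError("population sizes must be >= 2")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        lo, hi = self.allele_range
        if not (2 <= lo <= hi <= 50):
            raise ValueError("allele_range must satisfy 2 <= lo <= hi <= 50")

    @property
    def n_populations(self) -> int:
        return len(self.population_sizes)


def _default_compounds(n_pops: int) -> tuple[CompoundModel, ...]:
    """Six-coumarin model: columbianadin dominant, osthole next, with the
    first populations shifted up in columbianadin and the last shifted up in
    osthole (the qualitative pattern seen in wild panels)."""
    flat = (1.0,) * n_pops

    def shifts(values: tuple[float, ...]) -> tuple[float, ...]:
        return values if len(values) == n_pops else flat

    return (
        CompoundModel("umbelliferone", np.log(0.05), 0.5, flat),
        CompoundModel("8-methoxypsoralen", np.log(0.40), 0.6, flat),
        CompoundModel("bergapten", np.log(0.15), 0.6, flat),
        CompoundModel("columbianetin acetate", np.log(0.45), 0.6, flat),
        CompoundModel("osthole", np.log(0.90), 0.7, shifts((0.8, 0.8, 1.6))),
        CompoundModel("columbianadin", np.log(1.2), 0.9, shifts((1.3, 1.2, 0.6))),
    )


@dataclass(frozen=True)
class SyntheticPanel:
    genotypes: GenotypeMatrix
    metabolites: MetaboliteTable
    populations: dict[str, str]
    ground_truth: dict = field(default_factory=dict)


def study_like_config(seed: int = 715) -> SyntheticConfig:
    """The default study-shaped configuration (3 populations of 70/69/69,
    17 SSR loci with 4–15 alleles, F in the ~6% differentiation regime)."""
    return SyntheticConfig(compounds=_default_compounds(3), seed=seed)


def generate(config: SyntheticConfig, seed: int | None = None) -> SyntheticPanel:
    """Draw one panel; all randomness flows through a single seeded generator."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = config.population_sizes
    pops = config.population_names
    n = int(sum(sizes))
    lo, hi = config.allele_range
    compounds = config.compounds or _default_compounds(config.n_populations)

    accession_ids = []
    pop_of: dict[str, str] = {}
    pop_index = np.empty(n, dtype=int)
    k = 0
    for p, (name, size) in enumerate(zip(pops, sizes)):
        for i in range(size):
            acc = f"{name}-{i + 1:03d}"
            accession_ids.append(acc)
            pop_of[acc] = name
            pop_index[k] = p
            k += 1

    locus_ids = [f"ssr{l + 1:02d}" for l in range(config.n_loci)]
    calls = np.empty((n, config.n_loci, 2), dtype=np.int64)
    ancestral: dict[str, dict[int, float]] = {}
    pop_freqs: dict[str, dict[str, dict[int, float]]] = {name: {} for name in pops}
    for l, locus in enumerate(locus_ids):
        n_alleles = int(rng.integers(lo, hi + 1))
        labels = 100 + 14 * l + 2 * np.arange(n_alleles)  # a dinucleotide ladder
        anc = rng.dirichlet(np.ones(n_alleles))
        ancestral[locus] = dict(zip(labels.tolist(), anc.tolist()))
        for p, name in enumerate(pops):
            if config.fst > 0:
                pf = rng.dirichlet(anc * (1.0 - config.fst) / config.fst)
            else:
                pf = anc
            pop_freqs[name][locus] = dict(zip(labels.tolist(), pf.tolist()))
            rows = np.flatnonzero(pop_index == p)
            gametes = rng.choice(n_alleles, size=(len(rows), 2), p=pf)
            calls[rows, l, :] = labels[gametes]
    if config.missing_rate > 0:
        mask = rng.random((n, config.n_loci)) < config.missing_rate
        # keep every locus typed somewhere
        for l in range(config.n_loci):
            if mask[:, l].all():  # pragma: no cover - vanishingly unlikely
                mask[0, l] = False
        calls[mask] = MISSING

    values = np.empty((n, len(compounds)))
    for c, cm in enumerate(compounds):
        shifts = np.array(
            [cm.pop_shifts[p] if cm.pop_shifts else 1.0 for p in pop_index]
        )
        raw = rng.lognormal(mean=cm.log_median, sigma=cm.log_sd, size=n) * shifts
        values[:, c] = np.minimum(raw, config.coumarin_max)

    genotypes = GenotypeMatrix(tuple(accession_ids), tuple(locus_ids), calls)
    metabolites = MetaboliteTable(
        tuple(accession_ids), tuple(cm.name for cm in compounds), values
    )
    ground_truth = {
        "fst": config.fst,
        "ancestral_frequencies": ancestral,
        "population_frequencies": pop_freqs,
        "compounds": [vars(cm).copy() for cm in compounds],
    }
    return SyntheticPanel(genotypes, metabolites, pop_of, ground_truth)
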