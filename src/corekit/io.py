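"""File formats and the shared data model for germplasm panels.

The package works from three tables: a codominant SSR genotype matrix
(accessions x loci, two allele calls per locus, recorded as fragment sizes in
base pairs), a metabolite concentration table (accessions x compounds, mg/g
dry root weight), and an optional accession -> population map.

Conventions
-----------
* A missing genotype is written as ``0`` on disk (GenAlEx convention) and held
  as a negative sentinel in memory so that 0 can never collide with a real
  fragment size.  An accession may be entirely untyped at a locus; a
  half-missing call (one allele recorded, one missing) is rejected because it
  makes the allele dosage ambiguous.
* Allele labels are compared as plain integers.  No fragment-size binning is
  applied — calls are taken exactly as given.
* Accession order is preserved from the input everywhere; all derived outputs
  are deterministic in that order.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: In-memory sentinel for a missing allele call (0 is the on-disk encoding).
MISSING: int = -1

#: The six coumarins quantified in dried Angelica biserrata root (mg/g).
DEFAULT_COMPOUNDS: tuple[str, ...] = (
    "umbelliferone",
    "8-methoxypsoralen",
    "bergapten",
    "columbianetin acetate",
    "osthole",
    "columbianadin",
)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid codominant genotype calls for a panel of accessions.

    Parameters
    ----------
    accession_ids, locus_ids
        Ordered, unique identifiers.
    calls
        Integer array of shape ``(n_accessions, n_loci, 2)``.  Each entry is a
        positive allele label (fragment size in bp) or :data:`MISSING`; the two
        slots of a call are either both present or both missing.
    """

    accession_ids: tuple[str, ...]
    locus_ids: tuple[str, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "accession_ids", tuple(self.accession_ids))
        object.__setattr__(self, "locus_ids", tuple(self.locus_ids))
        calls = np.asarray(self.calls, dtype=np.int64)
        object.__setattr__(self, "calls", calls)
        _check_unique(self.accession_ids, "accession")
        _check_unique(self.locus_ids, "locus")
        n, L = len(self.accession_ids), len(self.locus_ids)
        if calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({n} accessions, {L} loci, 2)"
            )
        miss = calls == MISSING
        half = miss[:, :, 0] ^ miss[:, :, 1]
        if half.any():
            a, l = np.argwhere(half)[0]
            raise ValueError(
                "half-missing genotype for accession "
                f"{self.accession_ids[a]!r} at locus {self.locus_ids[l]!r}"
            )
        bad = (~miss) & (calls <= 0)
        if bad.any():
            a, l, _ = np.argwhere(bad)[0]
            raise ValueError(
                "allele labels must be positive integers; offending call for "
                f"accession {self.accession_ids[a]!r} at locus {self.locus_ids[l]!r}"
            )

    # -- basic queries ------------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def accession_indices(self, ids: Iterable[str]) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        idx = []
        for a in ids:
            if a not in pos:
                raise KeyError(f"unknown accession id: {a!r}")
            idx.append(pos[a])
        return np.asarray(sorted(set(idx)), dtype=int)

    def subset(self, ids: Iterable[str]) -> "GenotypeMatrix":
        """Restrict to the given accessions, keeping the panel's order."""
        idx = self.accession_indices(ids)
        return GenotypeMatrix(
            tuple(self.accession_ids[i] for i in idx),
            self.locus_ids,
            self.calls[idx],
        )

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_ids.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus id: {locus!r}") from None


@dataclass(frozen=True)
class MetaboliteTable:
    """Per-accession metabolite concentrations (mg/g).

    Values must be non-negative and finite; no missing values are permitted,
    because the core-sampling deletion rule compares total contents directly.
    """

    accession_ids: tuple[str, ...]
    compound_ids: tuple[str, ...]
    values: np.ndarray  # (n_accessions, n_compounds) float

    def __post_init__(self) -> None:
        object.__setattr__(self, "accession_ids", tuple(self.accession_ids))
        object.__setattr__(self, "compound_ids", tuple(self.compound_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        _check_unique(self.accession_ids, "accession")
        n, m = len(self.accession_ids), len(self.compound_ids)
        if vals.shape != (n, m):
            raise ValueError(f"values shape {vals.shape} != ({n}, {m})")
        if not np.isfinite(vals).all():
            raise ValueError("metabolite values must be finite (no missing values)")
        if (vals < 0).any():
            a, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative concentration for accession {self.accession_ids[a]!r}, "
                f"compound {self.compound_ids[c]!r}"
            )

    def total_scores(self) -> dict[str, float]:
        """Total content per accession: the unweighted sum over compounds."""
        sums = self.values.sum(axis=1)
        return dict(zip(self.accession_ids, sums.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.accession_ids), columns=list(self.compound_ids)
        )

    def subset(self, ids: Iterable[str]) -> "MetaboliteTable":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        idx = sorted({pos[a] for a in ids})
        return MetaboliteTable(
            tuple(self.accession_ids[i] for i in idx), self.compound_ids, self.values[idx]
        )


# PopulationMap is a plain mapping accession_id -> population label.
PopulationMap = Mapping[str, str]


def validate_population_map(populations: PopulationMap, genotypes: GenotypeMatrix) -> None:
    """Every labelled accession must exist in the panel; >= 1 population."""
    known = set(genotypes.accession_ids)
    for acc in populations:
        if acc not in known:
            raise ValueError(f"population map labels unknown accession {acc!r}")
    if len(set(populations.values())) < 1:
        raise ValueError("population map must define at least one population")


# ---------------------------------------------------------------------------
# Genotype file I/O
# ---------------------------------------------------------------------------

def _parse_allele(cell: str, accession: str, locus: str) -> int:
    cell = cell.strip()
    try:
        value = int(cell)
    except ValueError:
        raise ValueError(
            f"non-integer allele {cell!r} for accession {accession!r} "
            f"at locus {locus!r}"
        ) from None
    if value < 0:
        raise ValueError(
            f"negative allele {value} for accession {accession!r} at locus {locus!r}"
        )
    return MISSING if value == 0 else value


def _finish_pair(a1: int, a2: int, accession: str, locus: str) -> tuple[int, int]:
    if (a1 == MISSING) != (a2 == MISSING):
        raise ValueError(
            f"half-missing genotype for accession {accession!r} at locus {locus!r}"
        )
    return a1, a2


def read_genotypes(path: str | Path, dialect: str = "simple_tsv") -> GenotypeMatrix:
    """Read a codominant genotype table.

    ``dialect='simple_tsv'``: header ``accession<TAB>locus...``, each cell
    ``a1/a2`` with ``0/0`` for missing.  ``dialect='genalex_csv'``: GenAlEx
    codominant CSV — two leading metadata rows tolerated and skipped when the
    first cell of row 1 is an integer, optional ``Pop`` column, two columns
    per locus with the locus name on the first of each pair, 0 = missing.
    """
    path = Path(path)
    if dialect == "simple_tsv":
        return _read_simple_tsv(path)
    if dialect == "genalex_csv":
        return _read_genalex_csv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_simple_tsv(path: Path) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"empty genotype file: {path}")
    header = [c.strip() for c in rows[0]]
    loci = header[1:]
    accessions: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    for row in rows[1:]:
        acc = row[0].strip()
        accessions.append(acc)
        if len(row) != 1 + len(loci):
            raise ValueError(f"row for accession {acc!r} has {len(row) - 1} loci, expected {len(loci)}")
        pairs = []
        for locus, cell in zip(loci, row[1:]):
            parts = cell.strip().split("/")
            if len(parts) != 2:
                raise ValueError(
                    f"genotype cell {cell!r} for accession {acc!r} at locus "
                    f"{locus!r} is not of the form a1/a2"
                )
            a1 = _parse_allele(parts[0], acc, locus)
            a2 = _parse_allele(parts[1], acc, locus)
            pairs.append(_finish_pair(a1, a2, acc, locus))
        calls.append(pairs)
    _check_unique(accessions, "accession")
    return GenotypeMatrix(tuple(accessions), tuple(loci), np.asarray(calls, dtype=np.int64))


def _read_genalex_csv(path: Path) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"empty genotype file: {path}")
    start = 0
    try:  # two GenAlEx metadata rows: counts row + title row
        int(rows[0][0])
        start = 2
    except (ValueError, IndexError):
        pass
    header = [c.strip() for c in rows[start]]
    has_pop = len(header) > 1 and header[1].lower().startswith("pop")
    first_locus_col = 2 if has_pop else 1
    loci = [header[i] for i in range(first_locus_col, len(header), 2) if header[i]]
    accessions: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    for row in rows[start + 1 :]:
        acc = row[0].strip()
        accessions.append(acc)
        cells = row[first_locus_col : first_locus_col + 2 * len(loci)]
        if len(cells) != 2 * len(loci):
            raise ValueError(
                f"row for accession {acc!r} has {len(cells)} allele columns, "
                f"expected {2 * len(loci)}"
            )
        pairs = []
        for k, locus in enumerate(loci):
            a1 = _parse_allele(cells[2 * k], acc, locus)
            a2 = _parse_allele(cells[2 * k + 1], acc, locus)
            pairs.append(_finish_pair(a1, a2, acc, locus))
        calls.append(pairs)
    _check_unique(accessions, "accession")
    return GenotypeMatrix(tuple(accessions), tuple(loci), np.asarray(calls, dtype=np.int64))


def write_genotypes(
    genotypes: GenotypeMatrix,
    path: str | Path,
    dialect: str = "simple_tsv",
    populations: PopulationMap | None = None,
) -> None:
    """Write a genotype table in the given dialect (0 encodes missing)."""
    path = Path(path)
    disk = np.where(genotypes.calls == MISSING, 0, genotypes.calls)
    if dialect == "simple_tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["accession", *genotypes.locus_ids])
            for i, acc in enumerate(genotypes.accession_ids):
                w.writerow([acc] + [f"{a}/{b}" for a, b in disk[i]])
        return
    if dialect == "genalex_csv":
        pops = populations or {}
        labels = [pops.get(a, "pop1") for a in genotypes.accession_ids]
        pop_names = list(dict.fromkeys(labels))
        sizes = [labels.count(p) for p in pop_names]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([genotypes.n_loci, genotypes.n_accessions, len(pop_names), *sizes])
            w.writerow(["corekit genotype export", "", *pop_names])
            header = ["Sample", "Pop"]
            for locus in genotypes.locus_ids:
                header += [locus, ""]
            w.writerow(header)
            for i, acc in enumerate(genotypes.accession_ids):
                w.writerow([acc, labels[i], *disk[i].ravel().tolist()])
        return
    raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Metabolite and population-map I/O
# ---------------------------------------------------------------------------

def read_metabolites(path: str | Path) -> MetaboliteTable:
    """Read an accessions x compounds CSV of concentrations in mg/g.

    The first column holds accession ids; every remaining column is a compound.
    Empty or non-numeric cells are hard errors — no imputation is performed.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] < 1:
        raise ValueError("metabolite table needs at least one compound column")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"non-numeric or empty concentration for accession {df.index[r]!r}, "
            f"compound {df.columns[c]!r}"
        )
    return MetaboliteTable(
        tuple(str(a) for a in df.index), tuple(str(c) for c in df.columns), values
    )


def write_metabolites(table: MetaboliteTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index_label="accession")


def read_populations(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``accession<TAB>population`` (header optional)."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or not row[0].strip():
                continue
            acc, pop = row[0].strip(), row[1].strip()
            if acc.lower() in {"accession", "sample", "id"}:
                continue
            if acc in out:
                raise ValueError(f"duplicate accession id in population map: {acc!r}")
            out[acc] = pop
    return out


def write_populations(populations: PopulationMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["accession", "population"])
        for acc, pop in populations.items():
            w.writerow([acc, pop])


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(obj, path: str | Path, format: str = "json") -> None:
    """Serialize a result object (dataclass, dict or DataFrame) to JSON or TSV."""
    path = Path(path)
    if format == "json":
        payload = obj.to_dict() if hasattr(obj, "to_dict") and not isinstance(obj, pd.DataFrame) else obj
        with open(path, "w") as fh:
            json.dump(_to_jsonable(payload), fh, indent=2)
            fh.write("\n")
        return
    if format == "tsv":
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", index=False)
            return
        frame = pd.DataFrame(_to_jsonable(obj))
        frame.to_csv(path, sep="\t", index=False)
        return
    raise ValueError(f"unknown report format {format!r}")


def write_tree_newick(dendrogram, path: str | Path) -> None:
    """Write an ultrametric dendrogram (see :mod:`corekit.structure`) as Newick."""
    with open(path, "w") as fh:
        fh.write(dendrogram.to_newick())
        fh.write("\n")
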