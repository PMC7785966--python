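"""Genetic structure: distances, UPGMA, PCoA, AMOVA and pairwise PhiPT.

Codominant calls are first expanded into a binary band matrix (accession x
distinct allele, 1 = carries at least one copy).  Two distances are offered:

* ``simple_matching`` — one minus the simple matching coefficient, counting
  shared presences *and* shared absences over the columns known in both
  accessions (the NTSYS convention used for UPGMA clustering);
* ``band_squared_euclidean`` — the squared Euclidean distance between band
  vectors (the GenAlEx-style individual distance for codominant data), the
  default input for PCoA and AMOVA.

A :class:`DistanceMatrix` whose ``kind`` is ``band_squared_euclidean`` already
holds squared distances; PCoA and AMOVA square any other kind internally.
All tie-breaking is by lowest (row, column) index so that every result is
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

_SQUARED_KINDS = {"band_squared_euclidean"}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    accession_ids: tuple[str, ...]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "accession_ids", tuple(self.accession_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.accession_ids)
        if vals.shape != (n, n):
            raise ValueError(f"distance matrix shape {vals.shape} != ({n}, {n})")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (vals < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def squared_form(self) -> np.ndarray:
        """The matrix of squared distances, whatever the stored kind."""
        if self.kind in _SQUARED_KINDS:
            return self.values
        return self.values**2

    def subset(self, ids: Iterable[str]) -> "DistanceMatrix":
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        idx = sorted({pos[a] for a in ids})
        return DistanceMatrix(
            tuple(self.accession_ids[i] for i in idx),
            self.values[np.ix_(idx, idx)],
            self.kind,
        )


# ---------------------------------------------------------------------------
# Band encoding and distances
# ---------------------------------------------------------------------------

def band_matrix(genotypes: GenotypeMatrix) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Binary incidence matrix accession x distinct allele.

    Entry 1 means the accession carries >= 1 copy of the allele (dosage is
    collapsed).  A missing call flags all of that locus's columns as unknown
    (NaN) for that accession, to be excluded pairwise downstream.
    """
    columns: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    for l, locus in enumerate(genotypes.locus_ids):
        calls = genotypes.calls[:, l, :]
        alleles = sorted({int(a) for a in calls.ravel() if a != MISSING})
        block = np.zeros((genotypes.n_accessions, len(alleles)))
        for j, allele in enumerate(alleles):
            block[:, j] = np.any(calls == allele, axis=1)
        block[calls[:, 0] == MISSING, :] = np.nan
        blocks.append(block)
        columns.extend((locus, a) for a in alleles)
    return np.hstack(blocks), columns


def simple_matching_distance(
    bands: np.ndarray, accession_ids: Iterable[str] | None = None
) -> DistanceMatrix:
    """d = 1 − SM, with SM the fraction of mutually known columns that agree
    (shared presences and shared absences both count as matches)."""
    bands = np.asarray(bands, dtype=float)
    n = bands.shape[0]
    if n < 2:
        raise ValueError("need at least 2 accessions")
    ids = tuple(accession_ids) if accession_ids is not None else tuple(
        f"acc{i}" for i in range(n)
    )
    known = ~np.isnan(bands)
    filled = np.nan_to_num(bands)
    # pairwise counts via matrix products over the known-indicator
    both_known = known.astype(float) @ known.astype(float).T
    ones = filled * known
    zeros = (1.0 - filled) * known
    matches = ones @ ones.T + zeros @ zeros.T
    if (both_known - np.diag(np.diag(both_known)) == 0).any() and n > 1:
        off = both_known + np.diag(np.full(n, np.inf))
        if (off == 0).any():
            i, j = np.argwhere(off == 0)[0]
            raise ValueError(
                f"accessions {ids[i]!r} and {ids[j]!r} share no known band columns"
            )
    d = 1.0 - matches / both_known
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids, np.clip(d, 0.0, None), "simple_matching")


def band_squared_euclidean_distance(
    genotypes: GenotypeMatrix,
) -> DistanceMatrix:
    """Squared Euclidean distance between band vectors.

    With missing loci the sum runs over mutually known columns and is rescaled
    by (total columns / known columns) so that distances stay comparable.
    """
    bands, _ = band_matrix(genotypes)
    n, m = bands.shape
    known = ~np.isnan(bands)
    filled = np.nan_to_num(bands)
    both_known = known.astype(float) @ known.astype(float).T
    if (both_known + np.diag(np.full(n, np.inf)) == 0).any():
        raise ValueError("a pair of accessions shares no known band columns")
    g = filled @ filled.T
    sq = filled**2 @ known.T.astype(float) + known.astype(float) @ (filled**2).T - 2 * g
    d2 = sq * (m / both_known)
    np.fill_diagonal(d2, 0.0)
    d2 = (d2 + d2.T) / 2.0
    return DistanceMatrix(
        genotypes.accession_ids, np.clip(d2, 0.0, None), "band_squared_euclidean"
    )


def genetic_distance(genotypes: GenotypeMatrix, kind: str = "band_sq_euclidean") -> DistanceMatrix:
    """Convenience front end: ``band_sq_euclidean`` (default) or ``simple_matching``."""
    if kind in {"band_sq_euclidean", "band_squared_euclidean"}:
        return band_squared_euclidean_distance(genotypes)
    if kind == "simple_matching":
        bands, _ = band_matrix(genotypes)
        return simple_matching_distance(bands, genotypes.accession_ids)
    raise ValueError(f"unknown distance kind {kind!r}")


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DendroNode:
    height: float
    name: str | None = None
    children: tuple["DendroNode", "DendroNode"] | None = None

    def leaves(self) -> list[str]:
        if self.children is None:
            return [self.name]  # type: ignore[list-item]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass(frozen=True)
class Dendrogram:
    """Ultrametric binary merge tree; heights are half cophenetic distances."""

    root: DendroNode
    accession_ids: tuple[str, ...]
    linkage: np.ndarray  # scipy-style (n-1, 4): id_a, id_b, merge distance, size

    def to_newick(self) -> str:
        def render(node: DendroNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.children is None:
                return f"{node.name}:{length:g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{length:g}"

        if self.root.children is None:
            return f"{self.root.name};"
        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def upgma(distance: DistanceMatrix) -> Dendrogram:
    """Unweighted pair-group (average linkage) clustering.

    Repeatedly merges the minimum-distance pair of clusters at height d/2;
    the distance between clusters is the size-weighted arithmetic mean of the
    member distances.  Ties break on the lowest (row, column) cluster index,
    so the output is deterministic.
    """
    n = distance.n
    if n < 2:
        raise ValueError("UPGMA needs at least 2 accessions")
    d = distance.values.astype(float).copy()
    nodes: dict[int, DendroNode] = {
        i: DendroNode(0.0, distance.accession_ids[i]) for i in range(n)
    }
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    # dist maps frozenset pairs of active cluster ids to distances
    active: list[int] = list(range(n))
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    linkage_rows = []
    next_id = n
    while len(active) > 1:
        best = None
        best_pair = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                v = dist[(i, j) if i < j else (j, i)]
                if best is None or v < best:
                    best = v
                    best_pair = (i, j)
        i, j = best_pair  # type: ignore[misc]
        h = best / 2.0  # type: ignore[operator]
        node = DendroNode(h, None, (nodes[i], nodes[j]))
        size = sizes[i] + sizes[j]
        linkage_rows.append((i, j, best, size))
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(i, k) if i < k else (k, i)]
            djk = dist[(j, k) if j < k else (k, j)]
            dnew = (sizes[i] * dik + sizes[j] * djk) / size
            dist[(k, next_id)] = dnew
        active = [k for k in active if k not in (i, j)] + [next_id]
        nodes[next_id] = node
        sizes[next_id] = size
        next_id += 1
    return Dendrogram(
        nodes[next_id - 1], distance.accession_ids, np.asarray(linkage_rows, dtype=float)
    )


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCoAResult:
    accession_ids: tuple[str, ...]
    eigenvalues: np.ndarray          # all, descending (negatives included)
    coordinates: np.ndarray          # n x n_retained (positive axes only)
    percent_explained: np.ndarray    # per retained axis, over positive sum

    def to_frame(self) -> pd.DataFrame:
        cols = {f"axis{k + 1}": self.coordinates[:, k] for k in range(self.coordinates.shape[1])}
        return pd.DataFrame({"accession": list(self.accession_ids), **cols})


def pcoa(distance: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Principal coordinates analysis (Gower double centering).

    The matrix ``B = -1/2 J D^2 J`` is eigendecomposed; axes are ordered by
    eigenvalue.  Negative eigenvalues (non-Euclidean input) are reported but
    excluded from the percent-variance denominator and carry no coordinates.
    """
    n = distance.n
    if n < 3:
        raise ValueError("PCoA needs at least 3 accessions")
    d2 = distance.squared_form()
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos = eigval > max(1e-10 * max(eigval.max(), 1.0), 0.0)
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    if n_axes > n - 1:
        warnings.warn(f"n_axes={n_axes} clipped to {n - 1}")
        n_axes = n - 1
    n_keep = min(n_axes, n_pos)
    coords = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    pos_sum = eigval[pos].sum() if n_pos else 1.0
    percent = 100.0 * eigval[:n_keep] / pos_sum
    return PCoAResult(distance.accession_ids, eigval, coords, percent)


# ---------------------------------------------------------------------------
# AMOVA / PhiPT
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    var_among: float
    var_within: float
    percent_among: float
    percent_within: float
    phi_pt: float
    p_value: float | None = None
    n_permutations: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _amova_components(
    d2: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float, int, int]:
    """Sums of squares and variance components from squared distances."""
    n = d2.shape[0]
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    k = len(groups)
    iu = np.triu_indices(n, 1)
    ss_total = float(d2[iu].sum()) / n
    ss_within = 0.0
    for idx in groups:
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += float(sub[np.triu_indices(len(idx), 1)].sum()) / len(idx)
    ss_among = ss_total - ss_within
    df_among = k - 1
    df_within = n - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within else 0.0
    sizes = np.array([len(g) for g in groups], dtype=float)
    n0 = (n - float((sizes**2).sum()) / n) / df_among
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    return ss_among, ss_within, var_among, var_within, df_among, df_within


def amova(
    distance: DistanceMatrix,
    populations: Mapping[str, str],
    n_permutations: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """One-level AMOVA on squared distances with PhiPT.

    The total sum of squares ``SS = Σ_{i<j} d²_ij / n`` is partitioned into
    among- and within-population parts; variance components come from the
    expected mean squares with the standard unequal-size coefficient ``n0``.
    Negative components are clamped to zero (with a warning).  The permutation
    p-value shuffles population labels with a fixed seed.
    """
    try:
        labels = np.array([populations[a] for a in distance.accession_ids])
    except KeyError as exc:
        raise ValueError(f"population map misses accession {exc.args[0]!r}") from None
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"population {small!r} has fewer than 2 members")
    d2 = distance.squared_form()
    ss_a, ss_w, var_a, var_w, df_a, df_w = _amova_components(d2, labels)
    denom_raw = var_a + var_w
    phi_raw = var_a / denom_raw if denom_raw != 0 else 0.0
    if var_a < 0:
        warnings.warn("negative among-population variance component clamped to 0")
        var_a = 0.0
    if var_w < 0:  # pragma: no cover - requires pathological input
        warnings.warn("negative within-population variance component clamped to 0")
        var_w = 0.0
    total = var_a + var_w
    if total <= 0:
        warnings.warn("all variance components are zero; PhiPT reported as 0")
        phi = 0.0
        pct_a, pct_w = 0.0, 100.0
    else:
        phi = var_a / total
        pct_a = 100.0 * var_a / total
        pct_w = 100.0 * var_w / total
    p_value = None
    if n_permutations > 0:
        # the permuted statistic stays unclamped so that ties at zero do not
        # pile the null p-value distribution at 1
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            _, _, pa, pw, _, _ = _amova_components(d2, perm)
            phi_perm = pa / (pa + pw) if pa + pw != 0 else 0.0
            if phi_perm >= phi_raw - 1e-12:
                hits += 1
        p_value = (hits + 1) / (n_permutations + 1)
    return AmovaResult(
        df_a, df_w, ss_a, ss_w, var_a, var_w, pct_a, pct_w, phi, p_value, n_permutations
    )


def pairwise_phipt(
    distance: DistanceMatrix, populations: Mapping[str, str]
) -> pd.DataFrame:
    """PhiPT for every population pair (AMOVA restricted to the pair)."""
    labels = {a: populations[a] for a in distance.accession_ids}
    pops = list(dict.fromkeys(labels.values()))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ids = [a for a, p in labels.items() if p in (pops[i], pops[j])]
            res = amova(distance.subset(ids), labels)
            out.iloc[i, j] = out.iloc[j, i] = res.phi_pt
    return out
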