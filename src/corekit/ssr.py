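"""MISA-style microsatellite detection in transcript sequences.

A simple sequence repeat (SSR) is a perfect tandem run of a 1-6 bp motif.  The
detector reports maximal perfect runs whose repeat count meets a per-motif-
length minimum — by default at least 10 repeats for mononucleotides, 6 for
dinucleotides and 5 for tri-/tetra-/penta-/hexanucleotides — and merges runs
separated by at most ``max_interruption`` bases into compound records, the
convention of the MISA tool.  Motifs that are repetitions of a shorter unit
(e.g. ATAT) are folded onto that unit, so a run is never double-reported at
two motif lengths.  A single N terminates any run; characters outside
{A, C, G, T, N} are errors.

Coordinates are 1-based and inclusive on the given strand.  Reverse-strand
scanning is unnecessary because motif canonicalization already folds the two
strands into one class (e.g. CT -> AG/CT).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

#: Minimum repeat counts for motif lengths 1..6.
DEFAULT_MIN_REPEATS: tuple[int, ...] = (10, 6, 5, 5, 5, 5)

#: Maximal distance (bp) between two runs merged into one compound SSR.
DEFAULT_MAX_INTERRUPTION: int = 100

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class SsrRecord:
    """One detected SSR locus (simple run or compound of nearby runs)."""

    sequence_id: str
    motif: str
    repeat_count: int
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    kind: str = "simple"  # "simple" | "compound"
    member_motifs: tuple[tuple[str, int], ...] | None = None


@dataclass(frozen=True)
class SsrSummary:
    n_sequences: int
    n_sequences_with_ssr: int
    n_sequences_multi_ssr: int
    n_loci: int
    n_simple: int
    n_compound: int
    counts_by_motif_length: dict[int, int] = field(default_factory=dict)
    counts_by_repeat_number: dict[int, int] = field(default_factory=dict)
    counts_by_motif_class: dict[str, int] = field(default_factory=dict)
    frequency_percent: float = 0.0


def _primitive_period(motif: str) -> int:
    """Length of the smallest unit whose repetition equals ``motif``."""
    k = len(motif)
    for p in range(1, k + 1):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return p
    return k  # pragma: no cover


def canonical_motif(motif: str) -> str:
    """Canonical repeat class of a motif.

    The canonical form is the lexicographic minimum over all cyclic rotations
    of the motif and of its reverse complement, after first reducing motifs
    that are repetitions of a shorter unit to that unit.  E.g. ``T -> A``,
    ``CT -> AG``, ``ATAT -> AT``.
    """
    motif = motif.upper()
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    unit = motif[: _primitive_period(motif)]
    rc = unit.translate(_COMPLEMENT)[::-1]
    candidates = [unit[i:] + unit[:i] for i in range(len(unit))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def _find_simple_runs(
    sequence: str, min_repeats: Sequence[int]
) -> list[tuple[int, int, str, int]]:
    """Maximal primitive perfect runs as (start0, end0, motif, count)."""
    n = len(sequence)
    out: list[tuple[int, int, str, int]] = []
    for k, threshold in enumerate(min_repeats, start=1):
        j = 0
        while j + k <= n:
            # extend a self-similar stretch: sequence[i] == sequence[i+k]
            if sequence[j] == "N":
                j += 1
                continue
            i = j
            while (
                i + k < n
                and sequence[i + k] == sequence[i]
                and sequence[i + k] != "N"
            ):
                i += 1
            run_len = i - j + k  # length of the self-similar region from j
            count = run_len // k
            if count >= threshold:
                motif = sequence[j : j + k]
                if _primitive_period(motif) == k and "N" not in motif:
                    out.append((j, j + k * count - 1, motif, count))
                j = j + k * count  # jump past complete repeats
            else:
                j += 1
    out.sort(key=lambda r: (r[0], r[1], len(r[2])))
    return out


def find_ssrs(
    sequence: str,
    sequence_id: str = "seq",
    min_repeats: Sequence[int] = DEFAULT_MIN_REPEATS,
    max_interruption: int = DEFAULT_MAX_INTERRUPTION,
) -> list[SsrRecord]:
    """Detect SSR loci in one nucleotide sequence.

    Returns records in ascending start order; after compound merging the
    records are non-overlapping.
    """
    sequence = sequence.upper()
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence {sequence_id!r}: {sorted(bad)}")
    if len(min_repeats) != 6:
        raise ValueError("min_repeats must give thresholds for motif lengths 1..6")
    runs = _find_simple_runs(sequence, min_repeats)
    records: list[SsrRecord] = []
    group: list[tuple[int, int, str, int]] = []

    def flush() -> None:
        if not group:
            return
        if len(group) == 1:
            s, e, motif, count = group[0]
            records.append(
                SsrRecord(sequence_id, motif, count, s + 1, e + 1, "simple")
            )
        else:
            s = group[0][0]
            e = max(g[1] for g in group)
            members = tuple((g[2], g[3]) for g in group)
            records.append(
                SsrRecord(
                    sequence_id,
                    "+".join(g[2] for g in group),
                    sum(g[3] for g in group),
                    s + 1,
                    e + 1,
                    "compound",
                    members,
                )
            )
        group.clear()

    for run in runs:
        if group and run[0] - group[-1][1] - 1 > max_interruption:
            flush()
        group.append(run)
    flush()
    return records


def find_ssrs_fasta(
    path: str | Path,
    min_repeats: Sequence[int] = DEFAULT_MIN_REPEATS,
    max_interruption: int = DEFAULT_MAX_INTERRUPTION,
) -> tuple[list[SsrRecord], int]:
    """Scan every record of a FASTA file; returns (records, n_sequences)."""
    from Bio import SeqIO

    records: list[SsrRecord] = []
    n_sequences = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_sequences += 1
        records.extend(
            find_ssrs(str(rec.seq), rec.id, min_repeats, max_interruption)
        )
    return records, n_sequences


def summarize_ssrs(records: Iterable[SsrRecord], n_sequences: int) -> SsrSummary:
    """Aggregate detected loci into the standard MISA-style summary.

    A compound record counts as one locus.  Motif-length, repeat-number and
    motif-class breakdowns cover simple records only (compound members mix
    motif lengths).  ``frequency_percent`` is 100 x loci / sequences.
    """
    if n_sequences <= 0:
        raise ValueError("n_sequences must be positive")
    records = list(records)
    per_seq = Counter(r.sequence_id for r in records)
    simple = [r for r in records if r.kind == "simple"]
    compound = [r for r in records if r.kind == "compound"]
    by_len = Counter(len(r.motif) for r in simple)
    by_rep = Counter(r.repeat_count for r in simple)
    by_class = Counter(canonical_motif(r.motif) for r in simple)
    n_loci = len(records)
    return SsrSummary(
        n_sequences=n_sequences,
        n_sequences_with_ssr=len(per_seq),
        n_sequences_multi_ssr=sum(1 for v in per_seq.values() if v > 1),
        n_loci=n_loci,
        n_simple=len(simple),
        n_compound=len(compound),
        counts_by_motif_length=dict(sorted(by_len.items())),
        counts_by_repeat_number=dict(sorted(by_rep.items())),
        counts_by_motif_class=dict(sorted(by_class.items())),
        frequency_percent=round(100.0 * n_loci / n_sequences, 2),
    )
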