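"""Putative G-quadruplex (pG4) motif scanning.

A pG4 motif is at least four runs of at least three consecutive guanines, each
pair of neighbouring runs separated by a loop of 1-7 bases. Scanning is
leftmost-greedy over maximal G-runs: a run longer than the minimum is consumed
whole (never split into run + loop + run), a chain of runs is extended as far
as the loop bound allows, and after a match the scan resumes at the first base
past the match. Both strands are scanned; minus-strand hits are reported on
forward-axis coordinates with the matched-strand sequence attached.

``N`` (and, optionally, soft-masked lowercase) bases can take part in neither
runs nor loops, so a motif never spans an assembly gap.
"""
from __future__ import annotations

import re
from collections import defaultdict
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .intervals import merge_intervals, union_size

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_INVALID_RE = re.compile(r"[^ACGTNacgtn]")
_MASK_TO_N = str.maketrans("acgtn", "NNNNN")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case (soft-masking survives the flip)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the pG4 search pattern [G>=min_run N(loop_min-loop_max)]x(min_runs).

    Defaults encode the canonical G3+ N1-7 pattern with at least four runs.
    ``skip_masked`` treats soft-masked (lowercase) bases like N, excluding
    repeat-masked regions from motifs.
    """

    min_run_length: int = 3
    min_runs: int = 4
    loop_min: int = 1
    loop_max: int = 7
    skip_masked: bool = False

    def __post_init__(self) -> None:
        if self.min_run_length < 2:
            raise ValueError("min_run_length must be >= 2")
        if self.min_runs < 2:
            raise ValueError("min_runs must be >= 2")
        if not (1 <= self.loop_min <= self.loop_max):
            raise ValueError("need 1 <= loop_min <= loop_max")

    @property
    def min_span(self) -> int:
        return self.min_runs * self.min_run_length + (self.min_runs - 1) * self.loop_min


@dataclass
class PG4Hit:
    """One pG4 motif occurrence.

    ``start``/``end`` are 0-based half-open on the forward genomic axis;
    ``sequence`` holds the motif bases on the matched strand, and ``runs``
    the (start, end) offsets of the G-runs within ``sequence``. ``q_score``
    is an externally supplied stability score (e.g. Quadron), if any.
    """

    chrom: str
    start: int
    end: int
    strand: str
    n_runs: int
    sequence: str
    runs: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    q_score: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty hit interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.sequence and len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match interval span")

    @property
    def loops(self) -> tuple[str, ...]:
        """Loop sequences between consecutive G-runs (matched strand)."""
        return tuple(
            self.sequence[self.runs[i][1] : self.runs[i + 1][0]]
            for i in range(len(self.runs) - 1)
        )


def _prepare(seq: str, params: ScanParams) -> str:
    m = _INVALID_RE.search(seq)
    if m:
        raise ValueError(
            f"non-nucleotide character {m.group()!r} at offset {m.start()}"
        )
    if params.skip_masked:
        return seq.translate(_MASK_TO_N)
    return seq.upper()


def scan_strand(
    seq: str, params: ScanParams | None = None, chrom: str = "seq"
) -> list[PG4Hit]:
    """Scan one strand for pG4 motifs; coordinates are offsets into ``seq``.

    Returns leftmost-greedy, non-overlapping matches in scan order. Raises
    ``ValueError`` naming the offset of any non-{A,C,G,T,N} character.
    """
    params = params or ScanParams()
    s = _prepare(seq, params)
    run_re = re.compile(f"G{{{params.min_run_length},}}")
    runs = [(m.start(), m.end()) for m in run_re.finditer(s)]
    hits: list[PG4Hit] = []
    i = 0
    while i < len(runs):
        j = i
        while j + 1 < len(runs):
            gap_s, gap_e = runs[j][1], runs[j + 1][0]
            gap = gap_e - gap_s
            if params.loop_min <= gap <= params.loop_max and "N" not in s[gap_s:gap_e]:
                j += 1
            else:
                break
        n = j - i + 1
        if n >= params.min_runs:
            start, end = runs[i][0], runs[j][1]
            hits.append(
                PG4Hit(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+",
                    n_runs=n,
                    sequence=s[start:end],
                    runs=tuple((rs - start, re_ - start) for rs, re_ in runs[i : j + 1]),
                )
            )
        # no chain starting inside runs[i..j] can succeed where this one failed,
        # and after a match scanning resumes past the match end
        i = j + 1
    return hits


def scan_genome(
    genome: Mapping[str, str], params: ScanParams | None = None
) -> list[PG4Hit]:
    """Scan every sequence on both strands; minus-strand hits are mapped back
    to forward-axis coordinates. Deterministic (chrom, start, strand) order."""
    params = params or ScanParams()
    hits: list[PG4Hit] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        length = len(seq)
        hits.extend(scan_strand(seq, params, chrom))
        for h in scan_strand(reverse_complement(seq), params, chrom):
            hits.append(
                PG4Hit(
                    chrom=chrom,
                    start=length - h.end,
                    end=length - h.start,
                    strand="-",
                    n_runs=h.n_runs,
                    sequence=h.sequence,
                    runs=h.runs,
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def merged_hit_intervals(hits: Iterable[PG4Hit]) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome union of hit intervals, strands merged."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for h in hits:
        by_chrom[h.chrom].append((h.start, h.end))
    return {c: merge_intervals(v) for c, v in by_chrom.items()}


def merged_pg4_bp(hits: Iterable[PG4Hit]) -> int:
    """Bases covered by >= 1 pG4 on either strand (union on the forward axis)."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for h in hits:
        by_chrom[h.chrom].append((h.start, h.end))
    return sum(union_size(v) for v in by_chrom.values())


def ungapped_length(genome: Mapping[str, str]) -> int:
    """Genome length excluding N/n bases."""
    total = 0
    for seq in genome.values():
        total += len(seq) - seq.count("N") - seq.count("n")
    return total


def pg4_fraction_from_counts(pg4_bp: int, ungapped_bp: int, precision: int = 2) -> float:
    """Percentage of the (ungapped) genome covered by pG4, from raw counts."""
    if ungapped_bp <= 0:
        raise ValueError("ungapped genome length must be positive")
    return round(100.0 * pg4_bp / ungapped_bp, precision)


def pg4_fraction(
    genome: Mapping[str, str], hits: Iterable[PG4Hit], precision: int = 2
) -> float:
    """Percentage of ungapped genome bases covered by pG4 (strand union)."""
    return pg4_fraction_from_counts(
        merged_pg4_bp(hits), ungapped_length(genome), precision
    )
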