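"""500-bp genome binning, per-bin hairpin free energy, and the dG landscape.

The genome is divided into contiguous fixed-size bins; each gap-free,
full-length bin is scored by a folding adapter with the free energy of its
most stable hairpin/loop configuration. The resulting dG histogram (5 kcal/mol
increments spanning -272.5..7.5) is the landscape against which individual
pG4 hotspots are located: a hotspot's percentile says what fraction of scored
bins fold at least as stably.
"""
from __future__ import annotations

import logging
from bisect import bisect_right
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .folding import FoldingAdapter
from .scan import PG4Hit, reverse_complement

logger = logging.getLogger(__name__)

BIN_SIZE = 500
HIST_LO = -272.5
HIST_HI = 7.5
HIST_STEP = 5.0


@dataclass
class GenomeBin:
    """One fixed-size genome bin; ``dg`` stays ``None`` for gap-containing,
    terminal (short) or unscored bins."""

    chrom: str
    start: int
    end: int
    has_gap: bool
    terminal: bool = False
    dg: float | None = None

    @property
    def scoreable(self) -> bool:
        return not (self.has_gap or self.terminal)


def bin_genome(genome: Mapping[str, str], bin_size: int = BIN_SIZE) -> list[GenomeBin]:
    """Contiguous non-overlapping bins per chromosome; a trailing bin shorter
    than ``bin_size`` is kept but flagged terminal. ``has_gap`` marks any N."""
    bins: list[GenomeBin] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for start in range(0, len(seq), bin_size):
            end = min(start + bin_size, len(seq))
            bins.append(
                GenomeBin(
                    chrom=chrom,
                    start=start,
                    end=end,
                    has_gap="N" in seq[start:end],
                    terminal=(end - start) < bin_size,
                )
            )
    return bins


def score_bins(
    bins: Iterable[GenomeBin], genome: Mapping[str, str], adapter: FoldingAdapter
) -> list[GenomeBin]:
    """Attach the adapter's minimum free energy to every scoreable bin.

    Gap and terminal bins are skipped; an adapter failure leaves ``dg`` absent
    and is logged. Returns the same bin objects for chaining.
    """
    bins = list(bins)
    for b in bins:
        if not b.scoreable:
            continue
        seq = genome[b.chrom][b.start : b.end]
        try:
            b.dg = adapter.fold(seq).min_dg
        except Exception as exc:  # adapter failures must not kill the scan
            logger.warning("score_bins: adapter failed on %s:%d-%d: %s", b.chrom, b.start, b.end, exc)
            b.dg = None
    return bins


@dataclass
class DGHistogram:
    """dG landscape histogram: left-closed 5 kcal/mol bins over -272.5..7.5.

    Values outside the range are clamped into the end bins and counted in
    ``n_clamped_low``/``n_clamped_high``. Summary statistics (mode-bin center,
    mean, SD, median) are computed on the raw dG values.
    """

    edges: np.ndarray
    counts: np.ndarray
    mode_center: float
    mean: float
    sd: float
    median: float
    n_clamped_low: int = 0
    n_clamped_high: int = 0

    @property
    def n_scored(self) -> int:
        return int(self.counts.sum())


def dg_histogram(
    bins: Iterable[GenomeBin],
    lo: float = HIST_LO,
    hi: float = HIST_HI,
    step: float = HIST_STEP,
) -> DGHistogram:
    """Histogram of per-bin dG values at fixed increments.

    Bins are left-closed: a value exactly on an edge belongs to the bin
    starting there. Raises on an empty (all-unscored) input.
    """
    values = np.array([b.dg for b in bins if b.dg is not None], dtype=float)
    if values.size == 0:
        raise ValueError("no scored bins to histogram")
    edges = np.arange(lo, hi + step / 2, step)
    n_bins = len(edges) - 1
    idx = np.floor((values - lo) / step).astype(int)
    n_low = int((idx < 0).sum())
    n_high = int((idx >= n_bins).sum())
    if n_low or n_high:
        logger.warning("dg_histogram: %d values below and %d above the stated range; clamped",
                       n_low, n_high)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mode_center = float(edges[int(np.argmax(counts))] + step / 2)
    return DGHistogram(
        edges=edges,
        counts=counts,
        mode_center=mode_center,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        median=float(np.median(values)),
        n_clamped_low=n_low,
        n_clamped_high=n_high,
    )


@dataclass
class HotspotLocation:
    bin: GenomeBin
    dg: float
    percentile: float  # fraction of scored bins folding at least as stably


def locate_hotspot(
    interval: tuple[str, int, int], bins: Sequence[GenomeBin]
) -> HotspotLocation:
    """Place a genomic interval in the dG landscape.

    The containing bin is the bin of the interval's midpoint when it spans a
    boundary. ``percentile`` is the fraction of scored bins with dg <= this
    bin's dg, i.e. the share of the genome folding at least as stably; the
    planted most-stable bin of n scores 1/n.
    """
    chrom, start, end = interval
    mid = (start + end) // 2
    target = None
    for b in bins:
        if b.chrom == chrom and b.start <= mid < b.end:
            target = b
            break
    if target is None:
        raise ValueError(f"interval {chrom}:{start}-{end} outside the binned genome")
    if target.dg is None:
        raise ValueError(
            f"interval {chrom}:{start}-{end} falls in an unscored (gap/terminal) bin"
        )
    scored = sorted(b.dg for b in bins if b.dg is not None)
    n_at_most = bisect_right(scored, target.dg)
    return HotspotLocation(target, target.dg, n_at_most / len(scored))


def extend_for_folding(
    hit: PG4Hit, genome: Mapping[str, str], flank: int = 20
) -> str:
    """The hit's sequence extended by ``flank`` bp on both sides, on the
    matched strand (reverse complement for minus-strand hits). Flanks are
    clipped at chromosome ends, with a log note."""
    seq = genome[hit.chrom]
    lo = hit.start - flank
    hi = hit.end + flank
    if lo < 0 or hi > len(seq):
        logger.info("extend_for_folding: flank clipped at chromosome bounds for %s:%d-%d",
                    hit.chrom, hit.start, hit.end)
        lo, hi = max(0, lo), min(len(seq), hi)
    ext = seq[lo:hi]
    return reverse_complement(ext) if hit.strand == "-" else ext
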