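"""Gene-regulatory feature derivation and intersection with pG4 hits.

From refFlat/genePred-style gene models this module derives strand-aware
features — TSS, TSS-45 (45 bp upstream of the TSS in transcript orientation),
5'/3'UTRs, exons, introns and splice sites — and intersects them with pG4
hits, EST transcription start records, and +-window splice-site neighbourhoods.

pG4 strand is deliberately ignored in every overlap: a motif on either strand
marks the locus. When several transcripts share a ``gene_id`` the gene's
features are the union over its transcripts.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .intervals import (
    GenomicInterval,
    merge_intervals,
    overlapping_segments,
    point_in_merged,
    sweep_intersect,
)
from .scan import PG4Hit, merged_hit_intervals

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("tss", "tss45", "utr5", "utr3", "exon", "intron")

_FEATURE_ALIASES = {
    "tss": "tss",
    "tss45": "tss45",
    "tss-45": "tss45",
    "5utr": "utr5",
    "utr5": "utr5",
    "3utr": "utr3",
    "utr3": "utr3",
    "exon": "exon",
    "exons": "exon",
    "intron": "intron",
    "introns": "intron",
}


def normalize_feature(name: str) -> str:
    key = name.strip().lower()
    if key not in _FEATURE_ALIASES:
        raise ValueError(
            f"unknown feature {name!r}; expected one of TSS, TSS-45, 5UTR, 3UTR, exon, intron"
        )
    return _FEATURE_ALIASES[key]


@dataclass
class GeneModel:
    """One transcript of a gene, genePred-style (0-based half-open).

    ``cds_start == cds_end`` marks a noncoding transcript.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        gid = self.gene_id
        if self.strand not in "+-":
            raise ValueError(f"gene {gid}: bad strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"gene {gid}: tx_start must be < tx_end")
        self.exon_starts = tuple(int(x) for x in self.exon_starts)
        self.exon_ends = tuple(int(x) for x in self.exon_ends)
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError(f"gene {gid}: exon start/end lists must be parallel and non-empty")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"gene {gid}: exon [{s},{e}) outside transcript bounds")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {gid}: exons unsorted or overlapping at [{s},{e})")
            prev_end = e
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"gene {gid}: CDS bounds outside transcript")

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exon_ends[i], self.exon_starts[i + 1])
            for i in range(len(self.exon_starts) - 1)
            if self.exon_starts[i + 1] > self.exon_ends[i]
        ]

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: first transcribed base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass
class FeatureSet:
    """Per-gene regulatory feature intervals, ``gene -> feature -> [(chrom, s, e)]``.

    Point features (TSS, TSS-45) are width-``point_width`` intervals.
    """

    genes: dict[str, dict[str, list[GenomicInterval]]] = field(default_factory=dict)

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def intervals(self, feature: str) -> list[tuple[str, int, int, str]]:
        """All (chrom, start, end, gene_id) intervals of one feature, sorted."""
        feature = normalize_feature(feature)
        out = [
            (c, s, e, g)
            for g, feats in self.genes.items()
            for (c, s, e) in feats.get(feature, ())
        ]
        out.sort()
        return out

    def genes_with_feature(self, feature: str) -> set[str]:
        feature = normalize_feature(feature)
        return {g for g, feats in self.genes.items() if feats.get(feature)}


def _utr_intervals(model: GeneModel) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Exonic pieces upstream/downstream of the CDS, in transcript orientation."""
    if not model.is_coding:
        return [], []
    left = [  # exonic bases before cds_start on the forward axis
        (max(s, model.tx_start), min(e, model.cds_start))
        for s, e in model.exons
        if s < model.cds_start
    ]
    left = [(s, e) for s, e in left if s < e]
    right = [
        (max(s, model.cds_end), e) for s, e in model.exons if e > model.cds_end
    ]
    right = [(s, e) for s, e in right if s < e]
    return (left, right) if model.strand == "+" else (right, left)


def derive_features(
    models: Iterable[GeneModel],
    tss45_offset: int = 45,
    point_width: int = 1,
) -> FeatureSet:
    """Derive strand-aware feature intervals, unioned over transcripts per gene.

    TSS-45 is the single position ``tss45_offset`` bp upstream of the TSS in
    transcript orientation (a point, not a window); ``point_width`` widens both
    point features symmetrically downstream if set > 1.
    """
    raw: dict[str, dict[str, list[GenomicInterval]]] = defaultdict(lambda: defaultdict(list))
    for m in models:
        feats = raw[m.gene_id]
        tss = m.tss
        feats["tss"].append((m.chrom, tss, tss + point_width))
        t45 = tss - tss45_offset if m.strand == "+" else tss + tss45_offset
        if t45 < 0:
            logger.warning("gene %s: TSS-%d position %d before chromosome start; dropped",
                           m.gene_id, tss45_offset, t45)
        else:
            feats["tss45"].append((m.chrom, t45, t45 + point_width))
        utr5, utr3 = _utr_intervals(m)
        feats["utr5"].extend((m.chrom, s, e) for s, e in utr5)
        feats["utr3"].extend((m.chrom, s, e) for s, e in utr3)
        feats["exon"].extend((m.chrom, s, e) for s, e in m.exons)
        feats["intron"].extend((m.chrom, s, e) for s, e in m.introns)

    out = FeatureSet()
    for gene, feats in raw.items():
        merged_feats: dict[str, list[GenomicInterval]] = {}
        for name, ivs in feats.items():
            per_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
            for c, s, e in ivs:
                per_chrom[c].append((s, e))
            merged_feats[name] = sorted(
                (c, s, e) for c, v in per_chrom.items() for s, e in merge_intervals(v)
            )
        out.genes[gene] = merged_feats
    return out


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int, int]]:
    """bedtools-intersect-like overlap pairs; see :func:`intervals.sweep_intersect`."""
    return sweep_intersect(a, b)


def partition_genes(
    models: Iterable[GeneModel],
    hits: Iterable[PG4Hit],
    feature: str,
    feature_set: FeatureSet | None = None,
) -> tuple[set[str], set[str]]:
    """Split genes possessing ``feature`` into (with pG4, without pG4) sets.

    A gene is "with pG4" iff any hit on either strand overlaps >= 1 bp of that
    gene's feature intervals. The two sets are disjoint and exhaustive over
    genes that have the feature at all.
    """
    feature = normalize_feature(feature)
    fs = feature_set if feature_set is not None else derive_features(models)
    merged = merged_hit_intervals(hits)
    with_set: set[str] = set()
    without_set: set[str] = set()
    for gene in fs.genes:
        ivs = fs.genes[gene].get(feature)
        if not ivs:
            continue
        hit = any(
            overlapping_segments(merged.get(c, []), s, e) for c, s, e in ivs
        )
        (with_set if hit else without_set).add(gene)
    return with_set, without_set


@dataclass
class ESTRecord:
    """An expressed-sequence-tag transcription start: the strand-aware 5' end."""

    chrom: str
    strand: str
    start_site: int


def est_tss_overlap(
    ests: Iterable[ESTRecord], hits: Iterable[PG4Hit]
) -> tuple[int, int]:
    """Count EST start sites falling inside merged pG4 intervals.

    pG4 strand is ignored; containment is half-open. Returns
    ``(n_in_pg4, n_total)``.
    """
    merged = merged_hit_intervals(hits)
    n_in = n_total = 0
    for est in ests:
        n_total += 1
        if point_in_merged(merged.get(est.chrom, []), est.start_site):
            n_in += 1
    return n_in, n_total


@dataclass
class SpliceProfile:
    """Per-offset pG4 base counts around 5' and 3' splice sites.

    Offsets are signed and transcript-oriented: negative = upstream of the
    site ("before"), offset 0 = the first base at/past the junction on that
    side. Arrays have length ``2*window + 1`` for offsets -window..+window.
    """

    window: int
    counts_5p: np.ndarray
    counts_3p: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    @property
    def total(self) -> int:
        return int(self.counts_5p.sum() + self.counts_3p.sum())


def _splice_sites(models: Iterable[GeneModel]) -> set[tuple[str, int, str, str]]:
    """Unique (chrom, anchor, strand, side) splice sites over all transcripts.

    5' site anchor = first intronic base in transcript orientation;
    3' site anchor = first exonic base past the intron.
    """
    sites: set[tuple[str, int, str, str]] = set()
    for m in models:
        for s, e in m.introns:
            if m.strand == "+":
                sites.add((m.chrom, s, "+", "5p"))
                sites.add((m.chrom, e, "+", "3p"))
            else:
                sites.add((m.chrom, e - 1, "-", "5p"))
                sites.add((m.chrom, s - 1, "-", "3p"))
    return sites


def splice_profile(
    models: Iterable[GeneModel],
    hits: Iterable[PG4Hit],
    window: int = 2500,
) -> SpliceProfile:
    """Count merged pG4 bases at each signed offset around every splice site.

    Each genomic base covered by a merged pG4 interval within +-window of a
    site adds 1 at its transcript-oriented offset; minus-strand genes mirror,
    so "before the site" is negative on both strands.
    """
    models = list(models)
    counts_5p = np.zeros(2 * window + 1, dtype=np.int64)
    counts_3p = np.zeros(2 * window + 1, dtype=np.int64)
    sites = _splice_sites(models)
    if not sites:
        logger.warning("splice_profile: no introns in the supplied gene models; zero profile")
        return SpliceProfile(window, counts_5p, counts_3p)
    merged = merged_hit_intervals(hits)
    for chrom, anchor, strand, side in sites:
        arr = counts_5p if side == "5p" else counts_3p
        for lo, hi in overlapping_segments(
            merged.get(chrom, []), anchor - window, anchor + window + 1
        ):
            if strand == "+":
                arr[lo - anchor + window : hi - anchor + window] += 1
            else:
                arr[anchor - hi + 1 + window : anchor - lo + window + 1] += 1
    return SpliceProfile(window, counts_5p, counts_3p)


@dataclass
class ProfileEnrichment:
    """Per-offset fold over the profile-wide mean, with the peak offset per side."""

    fold_5p: np.ndarray | None
    fold_3p: np.ndarray | None
    peak_5p_offset: int | None
    peak_3p_offset: int | None


def profile_enrichment(profile: SpliceProfile) -> ProfileEnrichment:
    """Fold enrichment fold[o] = counts[o] / mean(counts), per side.

    A side with all-zero counts yields undefined folds (``None``) and a
    warning. Peak ties break toward the most negative offset.
    """
    offsets = profile.offsets

    def one_side(counts: np.ndarray, label: str):
        mean = counts.mean()
        if mean == 0:
            logger.warning("profile_enrichment: all-zero %s profile; folds undefined", label)
            return None, None
        fold = counts / mean
        return fold, int(offsets[int(np.argmax(counts))])

    fold5, peak5 = one_side(profile.counts_5p, "5'")
    fold3, peak3 = one_side(profile.counts_3p, "3'")
    return ProfileEnrichment(fold5, fold3, peak5, peak3)
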