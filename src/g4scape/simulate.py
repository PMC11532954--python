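"""Synthetic data with planted ground truth for every downstream stage.

The generator emulates the statistical structure of the real study inputs at
desk scale: a genome with canonical pG4 motifs planted to a target base-pair
density, non-overlapping gene models with exon/intron structure, EST start
sites with a controllable pG4-overlap fraction, paired tumor/normal
log-normal expression with group-specific means and coefficients of
variation, and mutation catalogs with a tunable pG4 enrichment fold and
planted recurrent hotspots.

Every dataset is a deterministic function of the :class:`SimConfig` (one root
seed streams per-component sub-seeds), and every generator returns the
machine-readable truth alongside the data so downstream modules have
closed-loop recovery tests.
"""
from __future__ import annotations

import re
from collections.abc import Sequence
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .features import ESTRecord, GeneModel
from .intervals import merge_intervals, point_in_merged
from .mutations import MutationRecord
from .scan import reverse_complement

_BASES = np.array(list("ACGT"))

#: sub-seed offsets: one root seed, independent streams per component
_STREAMS = {"genome": 0, "annotation": 1, "expression": 2, "mutations": 3}


def _rng(cfg: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class HotspotSpec:
    """A planted recurrent mutation site: ``recurrence`` somatic records with
    distinct sample ids at one coordinate."""

    chrom: str
    pos: int
    recurrence: int
    mut_type: str = "deletion"
    ref_len: int = 2


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic datasets.

    Defaults encode the regimes the analysis assumes: ~0.34% of bases in pG4,
    0.63% of EST starts inside pG4, target per-gene CVs of 30% (pG4 set) and
    60% (background set) over 200 paired patients, a milder tumor shift and a
    tumor g-CV contraction for the pG4 set, and a 1.5x germline mutation
    enrichment inside pG4.
    """

    seed: int = 0
    # genome
    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 100_000),)
    gc_content: float = 0.41
    pg4_density: float = 0.0034
    # annotation
    n_genes: int = 40
    exons_per_gene_mean: float = 4.0
    tx_length: tuple[int, int] = (1_000, 3_000)
    n_ests: int = 10_000
    est_pg4_overlap_fraction: float = 0.0063
    # expression
    n_genes_per_expr_set: int = 200
    n_patients: int = 200
    mean_fpkm_pg4: float = 6.0
    mean_fpkm_non: float = 4.0
    gene_log_sd_pg4: float = 0.8
    gene_log_sd_non: float = 1.0
    cv_pg4_pct: float = 30.0
    cv_non_pct: float = 60.0
    tumor_log2fc_mean_pg4: float = 0.25
    tumor_log2fc_mean_non: float = 0.5
    tumor_log2fc_sd: float = 0.25
    tumor_dispersion: float = 1.25
    tumor_gcv_scale_pg4: float = 0.85
    tumor_gcv_scale_non: float = 1.0
    # mutations
    n_mutations: int = 5_000
    mutation_pg4_fold: float = 1.5
    mutation_source: str = "germline"
    hotspots: tuple[HotspotSpec, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        for frac in (self.pg4_density, self.est_pg4_overlap_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if any(l <= 0 for _, l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        for cv in (self.cv_pg4_pct, self.cv_non_pct):
            if cv < 0:
                raise ValueError("target CV must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chrom_lengths"] = [list(x) for x in self.chrom_lengths]
        d["hotspots"] = [asdict(h) for h in self.hotspots]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "chrom_lengths" in d:
            d["chrom_lengths"] = tuple((c, int(l)) for c, l in d["chrom_lengths"])
        if "hotspots" in d:
            d["hotspots"] = tuple(HotspotSpec(**h) for h in d["hotspots"])
        return cls(**d)


@dataclass
class GenomeTruth:
    """A synthetic genome plus its planted-motif truth set.

    ``planted`` holds exact plus-strand coordinates of every planted motif;
    ``truth_intervals`` additionally includes any spurious background motif
    found by the oracle regex post-hoc, merged per chromosome.
    """

    genome: dict[str, str]
    planted: list[tuple[str, int, int, str]]  # (chrom, start, end, motif)
    truth_intervals: dict[str, list[tuple[int, int]]]
    config: SimConfig


# the canonical-motif oracle: maximal G-runs (possessive), 1-7 bp lazy loops
_ORACLE_RE = re.compile(r"G{3,}+(?:[ACGT]{1,7}?G{3,}+){3,}")


def _oracle_intervals(seq: str) -> list[tuple[int, int]]:
    fwd = [(m.start(), m.end()) for m in _ORACLE_RE.finditer(seq)]
    rc = reverse_complement(seq)
    n = len(seq)
    rev = [(n - m.end(), n - m.start()) for m in _ORACLE_RE.finditer(rc)]
    return merge_intervals(fwd + rev) if fwd or rev else []


def _sample_motif(rng: np.random.Generator, max_len: int | None = None) -> str:
    """A canonical pG4 motif: 4(+) runs of >= 3 G, loops 1-7 drawn from
    {A,C,T} so a planted motif can never extend by accident."""
    for _ in range(100):
        n_runs = 4 + rng.poisson(0.3)
        run_lens = 3 + (rng.random(n_runs) < 0.2).astype(int)
        loop_lens = rng.integers(1, 8, size=n_runs - 1)
        parts = []
        for i, rl in enumerate(run_lens):
            parts.append("G" * int(rl))
            if i < n_runs - 1:
                loop = rng.choice(list("ACT"), size=int(loop_lens[i]))
                parts.append("".join(loop))
        motif = "".join(parts)
        if max_len is None or len(motif) <= max_len:
            return motif
    # fall back to the minimal canonical motif
    return "GGG" + "T" + "GGG" + "T" + "GGG" + "T" + "GGG"


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=length, p=p)


_GGG = re.compile("GGG|CCC")


def gen_genome(cfg: SimConfig) -> GenomeTruth:
    """Random-background genome with canonical motifs planted to the target
    density; same config (incl. seed) reproduces it byte-for-byte."""
    rng = _rng(cfg, "genome")
    genome: dict[str, str] = {}
    planted: list[tuple[str, int, int, str]] = []
    total_len = sum(l for _, l in cfg.chrom_lengths)
    target_total = cfg.pg4_density * total_len

    for chrom, length in cfg.chrom_lengths:
        codes = _random_background(rng, length, cfg.gc_content)
        seq = list("".join(_BASES[codes]))
        target_bp = cfg.pg4_density * length
        if target_bp > 0.5 * length:
            raise ValueError(
                f"pg4_density {cfg.pg4_density} infeasible for length {length}"
            )
        occupied: list[tuple[int, int]] = []
        planted_bp = 0
        attempts = 0
        margin = 10  # keep flanks clear of chainable runs on either strand
        while planted_bp < target_bp:
            remaining = target_bp - planted_bp
            motif = _sample_motif(rng, max_len=int(remaining) + 10)
            attempts += 1
            if attempts > 200 * max(1, int(target_bp / 15)):
                raise ValueError("could not place motifs at the requested density")
            if length < len(motif) + 2 * margin:
                raise ValueError(f"chromosome {chrom} too short for motif planting")
            start = int(rng.integers(margin, length - len(motif) - margin))
            end = start + len(motif)
            if any(s < end + margin and start - margin < e for s, e in occupied):
                continue
            flank_l = "".join(seq[start - margin : start])
            flank_r = "".join(seq[end : end + margin])
            if _GGG.search(flank_l) or _GGG.search(flank_r):
                continue
            if seq[start - 1] == "G" or seq[end] == "G":
                continue
            seq[start:end] = motif
            occupied.append((start, end))
            planted.append((chrom, start, end, motif))
            planted_bp += len(motif)
        genome[chrom] = "".join(seq)

    del target_total
    planted.sort()
    truth = {
        chrom: _oracle_intervals(genome[chrom]) for chrom in genome
    }
    truth = {c: v for c, v in truth.items() if v}
    return GenomeTruth(genome, planted, truth, cfg)


@dataclass
class AnnotationTruth:
    models: list[GeneModel]
    ests: list[ESTRecord]
    #: EST indices whose start was planted inside a pG4 interval
    ests_in_pg4: list[int]


def gen_annotation(cfg: SimConfig, truth: GenomeTruth) -> AnnotationTruth:
    """Non-overlapping gene models plus EST start records where a fraction
    ``est_pg4_overlap_fraction`` of starts fall inside pG4 truth intervals."""
    rng = _rng(cfg, "annotation")
    chroms = [c for c, _ in cfg.chrom_lengths]
    lengths = dict(cfg.chrom_lengths)

    # genes: carve non-overlapping territories left to right
    models: list[GeneModel] = []
    per_chrom = -(-cfg.n_genes // len(chroms))  # ceil
    gene_no = 0
    for chrom in chroms:
        cursor = 100
        for _ in range(per_chrom):
            if gene_no >= cfg.n_genes:
                break
            tx_len = int(rng.integers(cfg.tx_length[0], cfg.tx_length[1] + 1))
            if cursor + tx_len + 100 > lengths[chrom]:
                break
            tx_start = cursor
            tx_end = tx_start + tx_len
            cursor = tx_end + int(rng.integers(100, 500))
            n_exons = 1 + int(rng.poisson(max(cfg.exons_per_gene_mean - 1, 0)))
            cuts = np.sort(rng.choice(
                np.arange(tx_start + 50, tx_end - 50), size=2 * (n_exons - 1), replace=False,
            )) if n_exons > 1 else np.array([], dtype=int)
            bounds = [tx_start, *cuts.tolist(), tx_end]
            exon_starts = tuple(bounds[0::2])
            exon_ends = tuple(bounds[1::2])
            strand = "+" if rng.random() < 0.5 else "-"
            cds_start = exon_starts[0] + 10
            cds_end = exon_ends[-1] - 10
            models.append(GeneModel(
                gene_id=f"gene{gene_no:04d}",
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                cds_end=cds_end,
                exon_starts=exon_starts,
                exon_ends=exon_ends,
            ))
            gene_no += 1
    if gene_no < cfg.n_genes:
        raise ValueError(
            f"could only place {gene_no} of {cfg.n_genes} genes in the genome"
        )

    # ESTs: Bernoulli(f) starts inside planted pG4 intervals
    pg4_ivs = [
        (chrom, s, e) for chrom, ivs in truth.truth_intervals.items() for s, e in ivs
    ]
    if cfg.est_pg4_overlap_fraction > 0 and not pg4_ivs:
        raise ValueError("cannot place EST starts in pG4: genome has no pG4 intervals")
    merged_by_chrom = {c: merge_intervals(ivs) for c, ivs in truth.truth_intervals.items()}
    ests: list[ESTRecord] = []
    in_pg4: list[int] = []
    for i in range(cfg.n_ests):
        strand = "+" if rng.random() < 0.5 else "-"
        if pg4_ivs and rng.random() < cfg.est_pg4_overlap_fraction:
            chrom, s, e = pg4_ivs[int(rng.integers(len(pg4_ivs)))]
            pos = int(rng.integers(s, e))
            in_pg4.append(i)
        else:
            while True:
                chrom = chroms[int(rng.integers(len(chroms)))]
                pos = int(rng.integers(0, lengths[chrom]))
                if not point_in_merged(merged_by_chrom.get(chrom, []), pos):
                    break
        ests.append(ESTRecord(chrom=chrom, strand=strand, start_site=pos))
    return AnnotationTruth(models, ests, in_pg4)


@dataclass
class ExpressionTruth:
    matrix: ExpressionMatrix
    pg4_genes: list[str]
    non_pg4_genes: list[str]
    pairing: list[tuple[str, str]]  # (normal sample, tumor sample)


def _cv_to_sigma(cv_pct: float) -> float:
    c = cv_pct / 100.0
    return float(np.sqrt(np.log1p(c * c)))


def gen_expression(
    cfg: SimConfig,
    pg4_genes: Sequence[str] | None = None,
    non_pg4_genes: Sequence[str] | None = None,
) -> ExpressionTruth:
    """Paired normal/tumor log-normal fpkm matrix.

    Per gene set: linear mean ``mean_fpkm_*``, group-specific between-gene
    spread ``gene_log_sd_*`` (natural-log SD of gene means; lower for the pG4
    set, planting its tighter transcriptome coordination), and a within-gene
    across-patient sigma from the target CV. Tumor samples apply a per-gene log2 shift, an
    extra dispersion factor, and a contraction of the between-gene spread
    (``tumor_gcv_scale_*``) that plants the tumor g-CV change.
    """
    rng = _rng(cfg, "expression")
    n = cfg.n_genes_per_expr_set
    if pg4_genes is None:
        pg4_genes = [f"pg4_gene{i:04d}" for i in range(n)]
    if non_pg4_genes is None:
        non_pg4_genes = [f"bg_gene{i:04d}" for i in range(n)]
    if set(pg4_genes) & set(non_pg4_genes):
        raise ValueError("pG4 and non-pG4 gene sets must be disjoint")

    n_pat = cfg.n_patients
    normal_ids = [f"pt{i:03d}_normal" for i in range(n_pat)]
    tumor_ids = [f"pt{i:03d}_tumor" for i in range(n_pat)]

    blocks = []
    index: list[str] = []
    for genes, mean_fpkm, cv_pct, fc_mean, gcv_scale, log_sd in (
        (pg4_genes, cfg.mean_fpkm_pg4, cfg.cv_pg4_pct, cfg.tumor_log2fc_mean_pg4,
         cfg.tumor_gcv_scale_pg4, cfg.gene_log_sd_pg4),
        (non_pg4_genes, cfg.mean_fpkm_non, cfg.cv_non_pct, cfg.tumor_log2fc_mean_non,
         cfg.tumor_gcv_scale_non, cfg.gene_log_sd_non),
    ):
        g = len(genes)
        sigma = _cv_to_sigma(cv_pct)
        sigma_t = sigma * cfg.tumor_dispersion
        a = np.log(mean_fpkm) + log_sd * rng.standard_normal(g)
        a_center = a.mean()
        a_tumor = a_center + gcv_scale * (a - a_center)
        shift = np.log(2.0) * (
            fc_mean + cfg.tumor_log2fc_sd * rng.standard_normal(g)
        )
        zn = rng.standard_normal((g, n_pat))
        zt = rng.standard_normal((g, n_pat))
        vn = np.exp(a[:, None]) * np.exp(sigma * zn - sigma**2 / 2)
        vt = np.exp(a_tumor[:, None] + shift[:, None]) * np.exp(
            sigma_t * zt - sigma_t**2 / 2
        )
        blocks.append(np.hstack([vn, vt]))
        index.extend(genes)

    values = pd.DataFrame(
        np.vstack(blocks), index=index, columns=normal_ids + tumor_ids
    )
    meta = pd.DataFrame(
        {
            "tissue": ["synthetic"] * 2 * n_pat,
            "condition": ["normal"] * n_pat + ["tumor"] * n_pat,
            "patient_id": [f"pt{i:03d}" for i in range(n_pat)] * 2,
        },
        index=normal_ids + tumor_ids,
    )
    matrix = ExpressionMatrix(values, meta)
    pairing = list(zip(normal_ids, tumor_ids))
    return ExpressionTruth(matrix, list(pg4_genes), list(non_pg4_genes), pairing)


def gen_mutations(cfg: SimConfig, truth: GenomeTruth) -> list[MutationRecord]:
    """Mutation catalog: uniform background over non-N bases with the per-base
    rate inside pG4 inflated by ``mutation_pg4_fold``, plus planted hotspots
    (exact recurrences with distinct sample ids)."""
    rng = _rng(cfg, "mutations")
    lengths = dict(cfg.chrom_lengths)
    pg4_positions: list[tuple[str, int]] = [
        (chrom, p)
        for chrom, ivs in truth.truth_intervals.items()
        for s, e in ivs
        for p in range(s, e)
    ]
    merged = {c: merge_intervals(ivs) for c, ivs in truth.truth_intervals.items()}
    total_len = sum(lengths.values())
    bp_in = len(pg4_positions)
    fold = cfg.mutation_pg4_fold
    p_in = fold * bp_in / (fold * bp_in + (total_len - bp_in)) if bp_in else 0.0

    chroms = list(lengths)
    records: list[MutationRecord] = []
    type_p = {"substitution": 0.9, "deletion": 0.05, "insertion": 0.03, "duplication": 0.02}
    type_names = list(type_p)
    type_probs = np.array(list(type_p.values()))
    for i in range(cfg.n_mutations):
        if pg4_positions and rng.random() < p_in:
            chrom, pos = pg4_positions[int(rng.integers(bp_in))]
        else:
            while True:
                chrom = chroms[int(rng.integers(len(chroms)))]
                pos = int(rng.integers(0, lengths[chrom]))
                base = truth.genome[chrom][pos].upper()
                if base != "N" and not point_in_merged(merged.get(chrom, []), pos):
                    break
        mut_type = type_names[int(rng.choice(len(type_names), p=type_probs))]
        ref = truth.genome[chrom][pos].upper()
        if mut_type == "substitution":
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        elif mut_type == "deletion":
            ref = truth.genome[chrom][pos : pos + 2].upper()
            alt = ""
        else:
            alt = ref + str(rng.choice(list("ACGT")))
        records.append(
            MutationRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                mut_type=mut_type,
                source=cfg.mutation_source,
                label="synthetic",
                sample_id=f"S{i:06d}" if cfg.mutation_source == "somatic" else "",
            )
        )

    for h_no, spec in enumerate(cfg.hotspots):
        if spec.chrom not in lengths or not (0 <= spec.pos < lengths[spec.chrom]):
            raise ValueError(f"hotspot at {spec.chrom}:{spec.pos} outside the genome")
        ref = truth.genome[spec.chrom][spec.pos : spec.pos + spec.ref_len].upper()
        for k in range(spec.recurrence):
            records.append(
                MutationRecord(
                    chrom=spec.chrom,
                    pos=spec.pos,
                    ref=ref,
                    alt="" if spec.mut_type == "deletion" else ref,
                    mut_type=spec.mut_type,
                    source="somatic",
                    label="hotspot",
                    sample_id=f"H{h_no}_{k:05d}",
                )
            )
    return records


def gen_splice_peak_dataset(
    n_genes: int = 50,
    offset: int = -56,
    motif: str = "GGGTGGGTGGGTGGG",
    seed: int = 0,
    spacing: int = 12_000,
) -> tuple[dict[str, str], list[GeneModel]]:
    """A genome where the same motif sits at a fixed transcript-oriented
    offset from every 5' splice site — planted truth for the splice
    metaprofile peak."""
    rng = np.random.default_rng(seed)
    mlen = len(motif)
    length = (n_genes + 1) * spacing
    # AT-only background: no spurious G runs
    seq = list("".join(np.where(rng.random(length) < 0.5, "A", "T")))
    models: list[GeneModel] = []
    for i in range(n_genes):
        base = (i + 1) * spacing
        strand = "+" if i % 2 == 0 else "-"
        tx_start, tx_end = base - 4_000, base + 4_000
        if strand == "+":
            ss5 = base  # intron start
            exon_starts = (tx_start, base + 2_000)
            exon_ends = (base, tx_end)
            m_start = ss5 + offset
        else:
            ss5 = base - 1  # first intron base in transcript orientation
            exon_starts = (tx_start, base)
            exon_ends = (base - 2_000, tx_end)
            # offset o maps to genomic position anchor - o on the minus strand
            m_start = ss5 - offset - mlen + 1
        seq[m_start : m_start + mlen] = motif
        models.append(GeneModel(
            gene_id=f"sgene{i:03d}",
            chrom="chrS",
            strand=strand,
            tx_start=tx_start,
            tx_end=tx_end,
            cds_start=tx_start + 10,
            cds_end=tx_end - 10,
            exon_starts=exon_starts,
            exon_ends=exon_ends,
        ))
    return {"chrS": "".join(seq)}, models


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """A copy of ``cfg`` with a different root seed (replicate helper)."""
    return replace(cfg, seed=seed)
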