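"""End-to-end synthetic replay: simulate -> scan -> enrichment -> features ->
expression -> mutations -> hairpin context, with a run manifest.

Each stage consumes the previous stage's outputs, writes TSV/JSON reports
into the output directory, and a failure halts the run with a stage-named
error. Reruns with the same config are numerically identical.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .expression import (
    g_cv,
    group_compare,
    indiv_cv,
    log2fc_set_contrast,
    log_mean_expression,
    paired_condition_test,
    tumor_normal_log2fc,
)
from .features import (
    FEATURE_NAMES,
    derive_features,
    est_tss_overlap,
    partition_genes,
    profile_enrichment,
    splice_profile,
)
from .folding import NaiveHairpinFolder
from .hairpin import bin_genome, dg_histogram, locate_hotspot, score_bins
from .mutations import (
    hotspot_rank,
    indel_recurrence_table,
    intersect_mutations,
    stability_stratify,
)
from .scan import ScanParams, merged_pg4_bp, pg4_fraction, scan_genome, ungapped_length
from .simulate import SimConfig, gen_annotation, gen_expression, gen_genome, gen_mutations
from .stats import enrichment_factor, fisher_2x2, overlap_enrichment

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass
class RunManifest:
    command: str
    parameters: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    tool_version: str = __version__
    seed: int | None = None
    started: str = ""
    finished: str = ""

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"{name}: {exc}") from exc
            logger.info("stage %s: done", name)
            return out
        return wrapper
    return deco


def run_pipeline(config: SimConfig, out_dir, splice_window: int = 2500,
                 q_threshold: float = 19.0, bin_size: int = 500) -> dict:
    """Run the full synthetic replay; returns the report dict (also written
    to ``out_dir`` as JSON/TSV files plus a run manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command="replay",
        parameters={"config": config.to_dict(), "splice_window": splice_window,
                    "q_threshold": q_threshold, "bin_size": bin_size},
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    report: dict = {}

    truth = _stage("simulate")(gen_genome)(config)
    annot = _stage("simulate")(gen_annotation)(config, truth)
    io.write_fasta(truth.genome, out / "genome.fa")
    with open(out / "truth_pg4.bed", "w") as fh:
        for chrom, s, e, motif in truth.planted:
            fh.write(f"{chrom}\t{s}\t{e}\tplanted\t0\t+\n")
    io.write_gene_models(annot.models, out / "genes.refflat.tsv")
    io.write_ests(annot.ests, out / "ests.tsv")

    hits = _stage("scan")(scan_genome)(truth.genome, ScanParams())
    # synthetic stability scores: external-engine stand-in, ~half stable at 19
    qrng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(7,)))
    for h in hits:
        h.q_score = float(np.round(qrng.normal(19.0, 5.0), 2))
    io.write_hits_bed(hits, out / "hits.bed")
    io.write_hits_decomposition(hits, out / "hits_decomposition.tsv")

    @_stage("enrichment")
    def _enrich():
        pg4_bp = merged_pg4_bp(hits)
        genome_bp = ungapped_length(truth.genome)
        n_in, n_total = est_tss_overlap(annot.ests, hits)
        pg4_pct = pg4_fraction(truth.genome, hits)
        est_pct = round(100.0 * n_in / n_total, 2) if n_total else 0.0
        p = fisher_2x2([[n_in, n_total - n_in], [pg4_bp, genome_bp - pg4_bp]])
        return {
            "pg4_bp": pg4_bp,
            "genome_ungapped_bp": genome_bp,
            "n_hits": len(hits),
            "pg4_pct_of_genome": pg4_pct,
            "est_starts_in_pg4": n_in,
            "est_total": n_total,
            "est_pct_in_pg4": est_pct,
            "est_fisher_p": p,
            "tss_enrichment_factor": enrichment_factor(est_pct, pg4_pct)
            if est_pct > 0 else None,
            "note": "Fisher table mixes EST counts (row 1) with base counts (row 2)",
        }

    report["enrichment"] = _enrich()

    @_stage("features")
    def _features():
        fs = derive_features(annot.models)
        parts = {}
        for feature in FEATURE_NAMES:
            with_set, without_set = partition_genes(
                annot.models, hits, feature, feature_set=fs
            )
            parts[feature] = {"with_pg4": len(with_set), "without_pg4": len(without_set)}
        prof = splice_profile(annot.models, hits, window=splice_window)
        enr = profile_enrichment(prof)
        pd.DataFrame({
            "offset": prof.offsets, "counts_5p": prof.counts_5p, "counts_3p": prof.counts_3p,
        }).to_csv(out / "splice_profile.tsv", sep="\t", index=False)
        return {
            "partitions": parts,
            "splice_profile_total_bp": prof.total,
            "splice_peak_5p_offset": enr.peak_5p_offset,
            "splice_peak_3p_offset": enr.peak_3p_offset,
        }

    report["features"] = _features()

    @_stage("expression")
    def _expression():
        expr = gen_expression(config)
        io.write_expression(expr.matrix, out / "fpkm.tsv", out / "samples.tsv")
        lm = log_mean_expression(expr.matrix)
        cmp_levels = group_compare(
            lm.loc[expr.pg4_genes], lm.loc[expr.non_pg4_genes]
        )
        fc = tumor_normal_log2fc(expr.matrix)
        contrast = log2fc_set_contrast(fc, expr.pg4_genes, expr.non_pg4_genes)
        icv_n = indiv_cv(expr.matrix, "normal")
        icv_t = indiv_cv(expr.matrix, "tumor")
        gcv_rows = {}
        for label, genes in (("pg4", expr.pg4_genes), ("non_pg4", expr.non_pg4_genes)):
            cv = g_cv(expr.matrix, genes).cv
            paired = paired_condition_test(
                cv.loc[[n for n, _ in expr.pairing]].to_numpy(),
                cv.loc[[t for _, t in expr.pairing]].to_numpy(),
            )
            gcv_rows[label] = {
                "median_normal": float(cv.loc[[n for n, _ in expr.pairing]].median()),
                "median_tumor": float(cv.loc[[t for _, t in expr.pairing]].median()),
                "paired_p": paired.p_value,
                "direction": paired.direction,
            }
        return {
            "median_log_mean_pg4": cmp_levels.median_with,
            "median_log_mean_non_pg4": cmp_levels.median_without,
            "levels_wilcoxon_p": cmp_levels.p_value,
            "log2fc_mean_pg4": contrast.mean_with,
            "log2fc_mean_non_pg4": contrast.mean_without,
            "log2fc_welch_p": contrast.p_value,
            "median_indiv_cv_normal_pg4": float(icv_n.cv.loc[expr.pg4_genes].median()),
            "median_indiv_cv_normal_non_pg4": float(icv_n.cv.loc[expr.non_pg4_genes].median()),
            "median_indiv_cv_tumor_pg4": float(icv_t.cv.loc[expr.pg4_genes].median()),
            "median_indiv_cv_tumor_non_pg4": float(icv_t.cv.loc[expr.non_pg4_genes].median()),
            "g_cv": gcv_rows,
            "note": "CVs computed on linear fpkm (see docs); log2(fpkm+1) used for levels",
        }

    report["expression"] = _expression()

    @_stage("mutations")
    def _mutations():
        muts = gen_mutations(config, truth)
        io.write_mutations(muts, out / "mutations.tsv")
        annotated = intersect_mutations(muts, hits)
        n_in = sum(a.in_pg4 for a in annotated)
        fold, p = overlap_enrichment(
            n_in, len(muts), merged_pg4_bp(hits), ungapped_length(truth.genome)
        )
        strata = stability_stratify(hits, threshold=q_threshold)
        ranked = hotspot_rank(annotated, hits)
        pd.DataFrame(
            [
                {"pg4": f"pG4_{i}", "chrom": h.chrom, "start": h.start,
                 "end": h.end, "n_unique_mutations": n}
                for i, h, n in ranked
            ]
        ).to_csv(out / "hotspots.tsv", sep="\t", index=False)
        indel_recurrence_table(muts).to_csv(out / "indel_recurrence.tsv", sep="\t", index=False)
        return {
            "n_mutations": len(muts),
            "n_in_pg4": int(n_in),
            "pg4_overlap_fold": fold,
            "pg4_overlap_p": p,
            "stable_fraction": strata.stable_fraction,
            "top_hotspot_count": ranked[0][2] if ranked else 0,
            "note": "enrichment table mixes mutation counts with base counts",
        }

    report["mutations"] = _mutations()

    @_stage("hairpin")
    def _hairpin():
        bins = score_bins(
            bin_genome(truth.genome, bin_size), truth.genome, NaiveHairpinFolder()
        )
        hist = dg_histogram(bins)
        pd.DataFrame({
            "edge_lo": hist.edges[:-1], "edge_hi": hist.edges[1:], "count": hist.counts,
        }).to_csv(out / "dg_histogram.tsv", sep="\t", index=False)
        hotspot = None
        if truth.planted:
            chrom, s, e, _m = truth.planted[0]
            try:
                loc = locate_hotspot((chrom, s, e), bins)
                hotspot = {"dg": loc.dg, "percentile": loc.percentile}
            except ValueError:
                hotspot = None
        return {
            "n_scored_bins": hist.n_scored,
            "dg_mode": hist.mode_center,
            "dg_mean": hist.mean,
            "dg_sd": hist.sd,
            "dg_median": hist.median,
            "first_planted_pg4_bin": hotspot,
        }

    report["hairpin"] = _hairpin()

    for name in ("genome.fa", "hits.bed", "genes.refflat.tsv", "ests.tsv",
                 "fpkm.tsv", "mutations.tsv"):
        manifest.input_checksums[name] = io.sha256_of(out / name)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
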