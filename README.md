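# g4scape

Putative G-quadruplex (pG4) motifs — runs of guanines that can fold into
four-stranded non-B DNA structures — cluster at gene-regulatory loci and are
statistically tied to how strongly and how consistently genes are expressed,
and to where germline and somatic mutations recur. `g4scape` is a toolkit for
quantifying those associations genome-wide:

* **Scanning** — find pG4 motifs matching `[G3 N1–7]≥3 G3` (at least four runs
  of ≥3 G separated by 1–7 bp loops) on both strands, with maximal-run,
  leftmost-greedy, non-overlapping semantics, and account for motif-covered
  base pairs as a fraction of the ungapped genome.
* **Regulatory features** — derive TSS, TSS−45, 5′/3′UTR, exon, intron and
  splice-site coordinates from refFlat/genePred gene models, partition genes
  by pG4 presence at each feature, count EST transcription starts falling in
  pG4, and build ±2500 bp splice-site metaprofiles of pG4 base counts.
* **Enrichment statistics** — two-sided Fisher exact tests computed in log
  space (with a chi-squared fallback at genome-scale counts) and enrichment
  factors such as `0.63% / 0.34% = 1.85` for EST starts at pG4 versus the
  genomic background.
* **Expression variability** — log2(fpkm+1) level comparisons (Wilcoxon),
  tumor/normal log2 fold changes (Welch contrast between gene sets), and two
  coefficient-of-variation statistics: indiv-CV (per gene across patients)
  and g-CV (per sample across a gene set), with paired tumor/normal t tests
  restricted to cohorts with ≥15 matched pairs.
* **Mutation overlap** — intersect HGMD-like germline and COSMIC-like somatic
  catalogs with pG4 hits, deduplicate by the source-appropriate key, stratify
  by stability score (Q-score ≥ 19 ⇒ stable, "s-pG4"), rank mutation
  hotspots, and call the direction of change of folding metrics (min ΔG,
  max Tm, structure count) for substitutions via a pluggable folding adapter.
* **Hairpin context** — 500-bp genome bins scored with a hairpin free energy
  (adapter-driven; a naive deterministic folder ships in-repo), the ΔG
  landscape histogram (5 kcal/mol steps, −272.5…7.5), and localization of
  pG4 hotspots within that landscape.
* **Synthetic data** — a generator that emulates the statistical structure of
  the real inputs (motif density ≈0.34% of bases, EST-start overlap fraction,
  paired log-normal tumor/normal expression with target CVs, mutation
  catalogs with planted enrichment and recurrent hotspots), with
  machine-readable ground truth for closed-loop validation of every stage.

## Worked example

```sh
g4scape simulate --seed 1 --out sim/
g4scape scan --fasta sim/genome.fa --out sim/hits.bed
# 12 hits; 341 merged pG4 bp; 0.34% of ungapped genome
g4scape annotate --genes sim/genes.refflat.tsv --hits sim/hits.bed --feature intron | head -1
# feature=intron	with_pg4=6	without_pg4=32
g4scape enrich --focal sim/ests.tsv --hits sim/hits.bed --genome-bp 100000 \
    --mutations sim/mutations.tsv
# est_in_pg4=78	est_total=10000	pg4_bp=341	p=1.254e-09
# mut_in_pg4=29	mut_total=5000	fold=1.701	p=0.009544
```

The simulated genome plants canonical motifs to a 0.34% base-pair density
(the human genome-wide regime); the scanner recovers all of them exactly.
0.78% of the 10,000 synthetic EST starts fall inside pG4 against a 0.34%
background expectation (Fisher p ≈ 1.3×10⁻⁹), and the mutation catalog
planted at 1.5× pG4 enrichment is recovered at 1.70× (within sampling error
of its planted fold; Fisher p ≈ 0.01).

The same flow is available as one command, `g4scape replay --seed 1 --out
run/`, which writes per-stage TSV/JSON reports plus a manifest with input
checksums.

As a library:

```python
from g4scape import ScanParams, scan_genome, merged_pg4_bp, pg4_fraction
hits = scan_genome({"chr1": "GGGTGGGTGGGTGGG"})
# [PG4Hit(chrom='chr1', start=0, end=15, strand='+', n_runs=4, ...)]
```

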