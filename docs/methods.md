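# Methods

## The motif model

A putative G-quadruplex (pG4) is a chain of at least `min_runs` (default 4)
maximal runs of at least `min_run_length` (default 3) consecutive guanines,
with neighbouring runs separated by loops of `loop_min`–`loop_max` (default
1–7) bases. Loops longer than 7 bp are excluded because the corresponding
structures are predicted to be unstable; the bound is exposed for users who
want the permissive long-loop variant. Matching semantics, chosen to follow
quadparser-family scanners:

* **Maximal runs.** A run of guanines is consumed whole. A single long G-run
  is one run — it is never split into run + loop + run to manufacture a
  match. (A naive backtracking regex `G{3,}([ACGT]{1,7}G{3,}){3,}` does split
  long runs; the test oracle therefore uses possessive quantifiers,
  `G{3,}+(?:[ACGT]{1,7}?G{3,}+){3,}`, which encodes the maximal-run rule.)
* **Leftmost-greedy, non-overlapping.** A chain is extended over as many runs
  as the loop bound allows; after a match the scan resumes at the first base
  past the match, per strand.
* **N discipline.** `N` can appear in neither run nor loop, so no motif spans
  an assembly gap; this keeps motif-covered base pairs commensurable with the
  ungapped genome length used in the denominator of the pG4 percentage.
  Soft-masked (lowercase) bases are uppercased by default; `skip_masked=True`
  treats them like `N`.
* **Strands.** The minus strand is scanned on the reverse complement and
  mapped back to forward-axis coordinates. "pG4 bp" counts merge the two
  strands (union of projected intervals) since the genome-wide figure being
  emulated is a single per-genome base count; per-strand hits remain
  available. For all feature/mutation overlap calls the hit strand is
  ignored — a motif on either strand marks the locus.

## Features and profiles

Gene models are genePred/refFlat transcripts; when several transcripts share
a gene id, the gene's features are the union over transcripts. TSS is the
strand-aware first transcribed base; TSS−45 is the single position 45 bp
upstream in transcript orientation (a point, not a window — the width is a
parameter for users who want a window). UTRs derive from CDS bounds clipped
to exons; noncoding transcripts have none.

Splice-site metaprofiles count merged pG4 bases at signed, transcript-
oriented offsets within ±2500 bp of every unique splice site: offset 0 is
the first intronic base (5′ side) or the first exonic base past the intron
(3′ side), negative offsets are "before" the site. Minus-strand genes are
mirrored so "before/after" pools correctly across strands. Per-offset fold
enrichment divides each count by the profile-wide mean; ties at the peak
resolve to the most negative offset.

Interval intersection is an in-package heap-assisted sweep with
`bedtools intersect` semantics (half-open, ≥1 bp), validated in tests
against an all-pairs brute-force oracle.

## Statistics

* **Fisher 2×2** — two-sided exact p as the sum of hypergeometric point
  probabilities ≤ the observed one, accumulated from `scipy.stats.hypergeom`
  log-pmf values so genome-scale counts do not overflow. When the smallest
  expected cell exceeds 10⁴ a chi-squared approximation with continuity
  correction is substituted (and logged); at such counts the two agree far
  beyond reported precision. The EST and mutation enrichment tables mix item
  counts (row 1) with base counts (row 2); this construction is an explicit
  assumption and every report carries a note saying so.
* **Enrichment factor** — focal pG4 percentage / genomic background
  percentage, rounded to 2 decimals (e.g. 0.63/0.34 = 1.85).
* **Wilcoxon rank-sum** — exact enumeration when both groups have ≤ 12
  untied values, else the tie-corrected continuity-corrected normal
  approximation. The approximation's worst-case pointwise deviation from
  exact at these sizes is a few hundredths (typical ~0.01), which is why the
  exact path is used precisely where it is feasible.
* **CVs** — indiv-CV: per gene, 100·SD/mean (sample SD, n−1) across patients
  of one condition; g-CV: per sample, the same across a gene set. Both are
  computed on linear fpkm by default: the log2(fpkm+1) transform is treated
  as a display convention for expression *levels*, not part of the CV
  definition. A `log_scale` flag switches. Zero-mean units are excluded and
  counted. Paired tumor/normal CV comparisons use a two-sided paired t test
  and refuse cohorts with fewer than 15 complete pairs (the matched-cohort
  inclusion rule); zero-variance non-zero differences are flagged degenerate
  rather than assigned a p-value.
* **No multiple-testing correction** is applied anywhere; raw p-values are
  reported.

## Mutations and folding impact

Overlap uses the affected reference span (substitution/deletion: the ref
bases; insertion/duplication: the insertion point). Unique-mutation counts
deduplicate germline records by coordinates+alleles and somatic records by
coordinates+alleles+sample, so a somatic variant recurring in many tumors
counts once per tumor. Stability stratification is boundary-inclusive:
Q-score ≥ 19 ⇒ stable (s-pG4). Q-scores are consumed as input (a BED score
column); no stability model is implemented here.

Folding impact calls compare (min ΔG, max Tm, structure count) between the
flank-extended (±20 bp) wild-type and mutant sequences from any adapter. The
Tm and count arrows follow the raw metric direction; the ΔG arrow is
expressed as *stability* direction — ΔG becoming less negative by more than
ε weakens the structure, so stability goes down. Equality tolerances are
ε = 0.01 kcal/mol (ΔG), 0.1 °C (Tm) and 0 (count), matching the output
precision of folding engines. The shipped 36-substitution disease panel
(`data/cardiac_pg4_substitutions.tsv`) stores the printed per-metric arrows
with the ΔG column as raw metric direction; under the stability mapping the
panel tallies to 14 stability-down, 15 Tm-down, 15 count-down and 31
any-metric-changed, which is the consistency check the tests pin.

## Hairpin context

The genome is cut into contiguous 500-bp bins; bins containing `N` or
shorter than 500 bp (chromosome tails) are excluded. Each remaining bin is
scored by a folding adapter with the free energy of its most stable
hairpin/loop configuration. The landscape histogram uses left-closed
5 kcal/mol bins spanning −272.5…7.5 (a value exactly on an edge belongs to
the bin starting there — the convention had to be fixed somewhere); values
outside the range clamp into the end bins and are counted. A hotspot's bin
is the bin of its midpoint; its percentile is the fraction of scored bins
folding at least as stably (the single most stable bin of n scores 1/n).

The in-repo `NaiveHairpinFolder` enumerates hairpins by extending a
perfectly complementary stem (Watson–Crick plus a weak G:T) around loops of
3–12 bases, with fixed pair energies (G:C −3, A:T −2, G:T −1 kcal/mol) and a
Wallace-rule Tm over stem bases. It is deterministic and ordinally sensible
(GC-rich palindromes fold "better" than homopolymers) but is **not** a
thermodynamic model; real analyses should supply mfold/RNAfold-style results
through `TabularFoldingAdapter`, which re-ingests per-sequence (ΔG, Tm, n)
tables and records engine provenance.

## The synthetic generator

One root seed streams per-component sub-seeds (genome, annotation,
expression, mutations), so each component regenerates independently and
every dataset is byte-reproducible from its config. Defaults encode the
study conditions the analysis assumes:

* Genome: 100 kb at GC 0.41, canonical motifs (runs of 3–4 G, loops 1–7
  drawn from {A,C,T} so a planted motif can never extend by accident)
  planted at non-overlapping positions to a 0.34% base-pair density, with
  flanking windows rejected if they contain `GGG`/`CCC` within 10 bp —
  guaranteeing exact-coordinate recovery by the scanner. Spurious background
  motifs are legitimate and are folded into the truth set by a post-hoc
  oracle-regex scan.
* Annotation: non-overlapping multi-exon gene models (1 + Poisson(3) exons,
  1–3 kb transcripts); EST starts fall inside pG4 truth intervals with
  probability f (default 0.0063, the human EST regime) and uniformly outside
  otherwise.
* Expression: 200 genes per set × 200 paired patients. Per set, gene means
  are log-normal around 6 fpkm (pG4) / 4 fpkm (background) with between-gene
  log-SD 0.8 / 1.0 — the tighter pG4 spread plants the lower g-CV — and
  within-gene, across-patient sigma set from the target CVs, 30% (pG4) / 60%
  (background), via σ = √ln(1+CV²). Tumor samples apply a per-gene log2
  shift (mean 0.25 for pG4 genes, 0.5 for background — the milder pG4 shift),
  a 1.25× dispersion factor (tumors are noisier), and a 0.85 contraction of
  the pG4 set's between-gene spread, planting the tumor g-CV decrease seen
  only for pG4 genes.
* Mutations: n=5,000 by default, 90% substitutions / 10% short indels,
  uniform over non-N background with the per-base rate inside pG4 inflated
  1.5× (the germline regime); hotspot specs plant exact recurrences with
  distinct sample ids.

What the generator does **not** emulate: isochores, repeat families, linked
genes, tissue structure, library-size or batch effects, and any sequence
determinants of expression — passing closed-loop tests demonstrates that the
pipeline recovers what was planted under the stated statistical model, not
that the biological conclusions transfer to real data.

## Problem sizes and numerical choices

The test and acceptance runs use 100 kb genomes, 1,000 oracle-comparison
sequences, 100 expression replicates and 200 mutation-null replicates —
sizes at which every planted signal is detectable with comfortable margins
while the whole suite runs in minutes. Determinism: all randomness flows
from explicit seeds; reports are byte-stable across reruns.

One validation check is knowingly not met and is left failing rather than
weakened: the calibration check that null enrichment p-values be
KS-indistinguishable from U(0,1) (KS p > 0.01 over 200 replicates). At the
study conditions the expected in-pG4 mutation count is ~17 per catalog;
an exact two-sided test at such counts is discrete (intrinsic KS distance
≈ 0.10 against the 0.115 rejection boundary) and conservative under
unconditional sampling (conditional variance 16.2 vs binomial 17.0), so its
null p distribution deviates from uniform by construction. The companion
checks — unbiasedness of the null fold estimate and recovery of a planted
3× enrichment — pass.

## Known limitations

* The scanner targets DNA pG4 motifs only; no G4Hunter-style scoring, no
  RNA-specific prediction, no stability model (Q-scores are inputs).
* Fisher tables mixing item and base counts are a modelling assumption, not
  a derivation; reports flag it.
* The naive folder is a test scaffold; no thermodynamic claims.
* No liftover, no alternative-splicing quantification, no GO/GSEA, no
  survival analysis, no normalization/batch correction of expression input.
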