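"""Feature derivation, interval intersection, gene partitioning, EST overlap
and splice-site metaprofiles."""
import numpy as np
import pytest

from g4scape.features import (
    ESTRecord,
    GeneModel,
    derive_features,
    est_tss_overlap,
    intersect,
    partition_genes,
    profile_enrichment,
    splice_profile,
)
from g4scape.scan import PG4Hit, scan_genome
from g4scape.simulate import (
    SimConfig,
    gen_annotation,
    gen_genome,
    gen_splice_peak_dataset,
)


def make_gene(gene_id="g1", chrom="c1", strand="+", tx=(100, 200),
              cds=None, exons=None):
    exons = exons or [tx]
    cds = cds or tx
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        tx_start=tx[0], tx_end=tx[1], cds_start=cds[0], cds_end=cds[1],
        exon_starts=tuple(s for s, _ in exons), exon_ends=tuple(e for _, e in exons),
    )


def hit(start, end, chrom="c1", strand="+"):
    return PG4Hit(chrom, start, end, strand, 4, "")


class TestDeriveFeatures:
    def test_plus_strand_single_exon(self):
        fs = derive_features([make_gene(strand="+", tx=(100, 200))])
        g = fs.genes["g1"]
        assert g["tss"] == [("c1", 100, 101)]
        assert g["tss45"] == [("c1", 55, 56)]
        assert g.get("intron", []) == []

    def test_minus_strand_mirror(self):
        fs = derive_features([make_gene(strand="-", tx=(100, 200))])
        g = fs.genes["g1"]
        assert g["tss"] == [("c1", 199, 200)]
        assert g["tss45"] == [("c1", 244, 245)]

    def test_two_exon_gene_intron_and_splice_sites(self):
        m = make_gene(exons=[(100, 150), (180, 200)], tx=(100, 200))
        assert m.introns == [(150, 180)]
        fs = derive_features([m])
        assert fs.genes["g1"]["intron"] == [("c1", 150, 180)]

    def test_utrs_from_cds_bounds(self):
        m = make_gene(tx=(100, 200), cds=(120, 180))
        fs = derive_features([m])
        assert fs.genes["g1"]["utr5"] == [("c1", 100, 120)]
        assert fs.genes["g1"]["utr3"] == [("c1", 180, 200)]
        # minus strand: the 5'UTR is the high-coordinate side
        fs2 = derive_features([make_gene(strand="-", tx=(100, 200), cds=(120, 180))])
        assert fs2.genes["g1"]["utr5"] == [("c1", 180, 200)]

    def test_noncoding_transcript_has_no_utrs(self):
        fs = derive_features([make_gene(tx=(100, 200), cds=(100, 100))])
        assert fs.genes["g1"].get("utr5", []) == []
        assert fs.genes["g1"].get("utr3", []) == []

    def test_multi_transcript_union(self):
        models = [
            make_gene(tx=(100, 200)),
            make_gene(tx=(150, 300), exons=[(150, 300)]),
        ]
        fs = derive_features(models)
        assert fs.genes["g1"]["exon"] == [("c1", 100, 300)]
        assert fs.genes["g1"]["tss"] == [("c1", 100, 101), ("c1", 150, 151)]

    def test_malformed_exons_name_the_gene(self):
        with pytest.raises(ValueError, match="gBAD"):
            make_gene(gene_id="gBAD", exons=[(150, 140)])


class TestIntersect:
    def test_basic_overlap(self):
        assert intersect([("c1", 0, 10)], [("c1", 5, 15)]) == [(0, 0, 5)]

    def test_half_open_abutment_is_no_overlap(self):
        assert intersect([("c1", 0, 10)], [("c1", 10, 20)]) == []

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)

        def random_intervals(n):
            out = []
            for _ in range(n):
                c = f"c{rng.integers(3)}"
                s = int(rng.integers(0, 2000))
                out.append((c, s, s + int(rng.integers(1, 100))))
            return sorted(out)

        a, b = random_intervals(500), random_intervals(500)
        expected = sorted(
            (i, j, min(ae, be) - max(as_, bs))
            for i, (ac, as_, ae) in enumerate(a)
            for j, (bc, bs, be) in enumerate(b)
            if ac == bc and min(ae, be) > max(as_, bs)
        )
        assert intersect(a, b) == expected
        # symmetric overlap lengths
        assert sorted((j, i, o) for i, j, o in intersect(a, b)) == intersect(b, a)

    def test_unsorted_input_is_sorted_internally(self, caplog):
        with caplog.at_level("WARNING"):
            out = intersect([("c1", 50, 60), ("c1", 0, 10)], [("c1", 5, 55)])
        assert {(o,) for *_ , o in out} == {(5,), (5,)}
        assert any("not sorted" in r.message for r in caplog.records)


class TestPartitionGenes:
    def test_tss_point_containment(self):
        models = [make_gene(tx=(55, 200), gene_id="gA"), make_gene(tx=(300, 400), gene_id="gB")]
        with_set, without_set = partition_genes(models, [hit(50, 65)], "TSS")
        assert with_set == {"gA"}
        assert without_set == {"gB"}

    def test_no_hits_gives_empty_with_set(self):
        models = [make_gene(gene_id="gA")]
        with_set, without_set = partition_genes(models, [], "exon")
        assert with_set == set()
        assert without_set == {"gA"}

    def test_unknown_feature_errors(self):
        with pytest.raises(ValueError, match="unknown feature"):
            partition_genes([make_gene()], [], "enhancer")

    def test_partition_is_disjoint_and_exhaustive(self):
        cfg = SimConfig(seed=5, chrom_lengths=(("chr1", 40_000),), n_genes=10,
                        n_ests=10)
        truth = gen_genome(cfg)
        annot = gen_annotation(cfg, truth)
        hits = scan_genome(truth.genome)
        for feature in ("tss", "exon", "intron"):
            w, wo = partition_genes(annot.models, hits, feature)
            assert w & wo == set()
            from g4scape.features import derive_features as df
            assert w | wo == df(annot.models).genes_with_feature(feature)

    def test_planted_intron_hits_recovered(self):
        # plant a motif inside the intron of exactly k of n genes
        motif = "GGGTGGGTGGGTGGG"
        n, k = 6, 3
        chrom_seq = ["T"] * 20_000
        models = []
        for i in range(n):
            base = 1000 + i * 3000
            models.append(make_gene(
                gene_id=f"g{i}", tx=(base, base + 2000),
                exons=[(base, base + 500), (base + 1500, base + 2000)],
            ))
            if i < k:
                pos = base + 800
                chrom_seq[pos : pos + len(motif)] = motif
        genome = {"c1": "".join(chrom_seq)}
        hits = scan_genome(genome)
        with_set, without_set = partition_genes(models, hits, "intron")
        assert with_set == {f"g{i}" for i in range(k)}
        assert len(without_set) == n - k


class TestESTOverlap:
    def test_half_open_containment(self):
        hits = [hit(0, 15)]
        inside = ESTRecord("c1", "+", 7)
        boundary = ESTRecord("c1", "+", 15)
        assert est_tss_overlap([inside, boundary], hits) == (1, 2)

    def test_planted_overlap_fraction_binomial(self):
        cfg = SimConfig(seed=7, chrom_lengths=(("chr1", 100_000),), n_ests=10_000,
                        est_pg4_overlap_fraction=0.2, n_genes=5)
        truth = gen_genome(cfg)
        annot = gen_annotation(cfg, truth)
        hits = scan_genome(truth.genome)
        n_in, n_total = est_tss_overlap(annot.ests, hits)
        f = 0.2
        sd = np.sqrt(f * (1 - f) / n_total)
        assert abs(n_in / n_total - f) < 3 * sd


class TestSpliceProfile:
    def _gene(self, strand="+", chrom="c1"):
        # intron [1000, 3000); 5' site anchor 1000 (+) / 2999 (-)
        return make_gene(
            strand=strand, chrom=chrom, tx=(500, 3500),
            exons=[(500, 1000), (3000, 3500)],
        )

    def test_no_hits_zero_profile(self):
        prof = splice_profile([self._gene()], [], window=100)
        assert prof.total == 0
        assert len(prof.counts_5p) == 201

    def test_no_introns_warns_and_zeroes(self, caplog):
        with caplog.at_level("WARNING"):
            prof = splice_profile([make_gene()], [hit(0, 15)], window=50)
        assert prof.total == 0
        assert any("no introns" in r.message for r in caplog.records)

    def test_single_motif_upstream_of_5p_site(self):
        prof = splice_profile([self._gene()], [hit(940, 955)], window=2500)
        offsets = prof.offsets
        nonzero = offsets[prof.counts_5p > 0]
        assert nonzero.tolist() == list(range(-60, -45))
        assert prof.counts_5p.max() == 1

    def test_minus_strand_mirroring(self):
        # motif downstream on the forward axis but upstream in transcript
        # orientation of the minus-strand 5' site (anchor 2999)
        prof = splice_profile([self._gene(strand="-")], [hit(3045, 3060)], window=2500)
        nonzero = prof.offsets[prof.counts_5p > 0]
        assert (nonzero < 0).all()
        assert nonzero.tolist() == list(range(-60, -45))

    def test_translation_invariance(self):
        shift = 12345
        g1 = self._gene()
        g2 = make_gene(
            tx=(500 + shift, 3500 + shift),
            exons=[(500 + shift, 1000 + shift), (3000 + shift, 3500 + shift)],
        )
        p1 = splice_profile([g1], [hit(940, 955)], window=300)
        p2 = splice_profile([g2], [hit(940 + shift, 955 + shift)], window=300)
        assert (p1.counts_5p == p2.counts_5p).all()
        assert (p1.counts_3p == p2.counts_3p).all()

    def test_total_conservation(self):
        """Profile total equals the overlap bp between merged hits and the
        union of +-window site neighbourhoods, counted per site."""
        g = self._gene()
        hits = [hit(940, 1100), hit(2900, 3100)]
        w = 200
        prof = splice_profile([g], hits, window=w)
        total = 0
        for anchor in (1000, 3000):  # 5' and 3' anchors of the + strand gene
            for s, e in [(940, 1100), (2900, 3100)]:
                lo, hi = max(s, anchor - w), min(e, anchor + w + 1)
                total += max(0, hi - lo)
        assert prof.total == total


class TestProfileEnrichment:
    def test_uniform_counts_fold_one(self):
        prof = splice_profile([], [], window=2)
        prof.counts_5p[:] = 7
        prof.counts_3p[:] = 3
        enr = profile_enrichment(prof)
        assert np.allclose(enr.fold_5p, 1.0)
        assert np.allclose(enr.fold_3p, 1.0)

    def test_analytic_fold(self):
        prof = splice_profile([], [], window=2)
        prof.counts_5p[:] = [0, 0, 4, 0, 0]
        enr = profile_enrichment(prof)
        assert enr.fold_5p.tolist() == [0, 0, 5, 0, 0]
        assert enr.peak_5p_offset == 0

    def test_all_zero_flags_undefined(self, caplog):
        prof = splice_profile([], [], window=2)
        with caplog.at_level("WARNING"):
            enr = profile_enrichment(prof)
        assert enr.fold_5p is None and enr.peak_5p_offset is None

    def test_planted_peak_at_minus_56(self):
        genome, models = gen_splice_peak_dataset(n_genes=20, offset=-56, seed=3)
        hits = scan_genome(genome)
        prof = splice_profile(models, hits, window=2500)
        enr = profile_enrichment(prof)
        assert enr.peak_5p_offset == -56
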