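import numpy as np
import pytest

from helpers_oracles import (
    pairwise_extension_oracle,
    random_annotation,
    walk_extension_oracle,
)
from sc3kit.annotation import (
    AnnotationSet,
    ExtensionConfig,
    GeneModel,
    GenomeLayout,
    apply_name_mapping,
    compute_extended_tts,
    dedupe_identical_tts,
    extend_all,
    filter_biotypes,
    read_gff3,
    read_name_mapping,
    write_gff3,
)
from sc3kit.errors import GffParseError, Sc3kitError, UnknownChromosomeError


class TestGenomeLayout:
    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            GenomeLayout({"chr1": 0})

    def test_tsv_round_trip(self, layout, tmp_path):
        p = tmp_path / "sizes.tsv"
        layout.to_tsv(p)
        assert GenomeLayout.from_tsv(p).lengths == dict(layout.lengths)

    def test_duplicate_chromosome_rejected(self, tmp_path):
        p = tmp_path / "sizes.tsv"
        p.write_text("chr1\t100\nchr1\t200\n")
        with pytest.raises(Sc3kitError, match="duplicate"):
            GenomeLayout.from_tsv(p)


class TestGeneModel:
    def test_strand_dependent_termini(self):
        plus = GeneModel("a", "a", "chr1", "+", 100, 200)
        minus = GeneModel("b", "b", "chr1", "-", 100, 200)
        assert (plus.tss, plus.tts) == (100, 200)
        assert (minus.tss, minus.tts) == (200, 100)

    def test_invalid_span(self):
        with pytest.raises(ValueError, match="start"):
            GeneModel("a", "a", "chr1", "+", 200, 100)

    def test_exon_outside_span(self):
        with pytest.raises(ValueError, match="outside"):
            GeneModel("a", "a", "chr1", "+", 100, 200, exons=((50, 150),))

    def test_overlapping_exons(self):
        with pytest.raises(ValueError, match="unsorted or overlapping"):
            GeneModel("a", "a", "chr1", "+", 100, 300, exons=((100, 200), (150, 300)))

    def test_default_single_exon(self):
        g = GeneModel("a", "a", "chr1", "+", 100, 200)
        assert g.exons == ((100, 200),)


class TestGff3IO:
    def test_round_trip_identity(self, toy_annotation, layout, tmp_path):
        p = tmp_path / "toy.gff3"
        write_gff3(toy_annotation, p)
        back = read_gff3(p, layout)
        assert len(back) == 3
        assert sorted(back.genes, key=lambda g: g.gene_id) == sorted(
            toy_annotation.genes, key=lambda g: g.gene_id)

    def test_pseudo_attribute_sets_biotype(self, layout, tmp_path):
        p = tmp_path / "ps.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t100\t200\t.\t+\t.\tID=g1;pseudo=True\n"
        )
        ann = read_gff3(p, layout)
        assert ann.get("g1").biotype == "pseudogene"

    def test_empty_file(self, layout, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("")
        assert len(read_gff3(p, layout)) == 0

    def test_malformed_line_reports_line_number(self, layout, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nchr1\tgene\tonly-three-cols\n")
        with pytest.raises(GffParseError, match="line 2"):
            read_gff3(p, layout)

    def test_unknown_chromosome_named_in_error(self, layout, tmp_path):
        p = tmp_path / "chr.gff3"
        p.write_text("chrMYSTERY\tx\tgene\t1\t10\t.\t+\t.\tID=g1\n")
        with pytest.raises(UnknownChromosomeError, match="chrMYSTERY"):
            read_gff3(p, layout)

    def test_gene_with_exons_writes_all_feature_rows(self, layout, tmp_path):
        g = GeneModel("g1", "g1", "chr1", "+", 100, 900,
                      exons=((100, 200), (300, 400), (500, 900)))
        p = tmp_path / "rows.gff3"
        write_gff3(AnnotationSet(layout, [g]), p)
        rows = [l.split("\t") for l in p.read_text().splitlines()
                if l and not l.startswith("#")]
        types = [r[2] for r in rows]
        assert types == ["gene", "mRNA", "exon", "exon", "exon"]

    def test_extended_coordinates_in_gene_transcript_and_exon(self, layout, tmp_path):
        g = GeneModel("g1", "g1", "chr1", "+", 10_001, 15_000)
        ext = extend_all(AnnotationSet(layout, [g]))
        p = tmp_path / "ext.gff3"
        write_gff3(ext, p)
        rows = [l.split("\t") for l in p.read_text().splitlines()
                if l and not l.startswith("#")]
        assert all(int(r[4]) == 25_000 for r in rows), rows


class TestFilterBiotypes:
    def test_default_removal(self, layout):
        genes = [
            GeneModel("c", "c", "chr1", "+", 100, 200),
            GeneModel("p", "p", "chr1", "+", 300, 400, biotype="pseudogene"),
            GeneModel("t", "t", "chr1", "+", 500, 600, biotype="tRNA"),
        ]
        out = filter_biotypes(AnnotationSet(layout, genes), ExtensionConfig())
        assert [g.gene_id for g in out] == ["c"]

    def test_empty_removal_set_is_identity(self, toy_annotation):
        cfg = ExtensionConfig(removed_biotypes=frozenset())
        assert len(filter_biotypes(toy_annotation, cfg)) == len(toy_annotation)

    def test_all_removable(self, layout):
        genes = [GeneModel("p", "p", "chr1", "+", 1, 10, biotype="tRNA")]
        out = filter_biotypes(AnnotationSet(layout, genes), ExtensionConfig())
        assert len(out) == 0

    def test_input_unmodified(self, toy_annotation):
        filter_biotypes(toy_annotation, ExtensionConfig())
        assert len(toy_annotation) == 3


class TestDedupeIdenticalTts:
    def _pair(self, layout, order):
        long = GeneModel("gLong", "gLong", "chr1", "+", 1_001, 5_000)
        short = GeneModel("gShort", "gShort", "chr1", "+", 3_001, 5_000)
        genes = [long, short] if order else [short, long]
        return AnnotationSet(layout, genes)

    @pytest.mark.parametrize("order", [True, False])
    def test_longest_span_kept_order_independent(self, layout, order):
        out = dedupe_identical_tts(self._pair(layout, order))
        assert [g.gene_id for g in out] == ["gLong"]

    def test_distinct_tts_identity(self, toy_annotation):
        assert len(dedupe_identical_tts(toy_annotation)) == 3

    def test_three_sharing_one_survivor(self, layout):
        genes = [GeneModel(f"g{i}", f"g{i}", "chr1", "+", 1_000 * i + 1, 9_000)
                 for i in range(1, 4)]
        out = dedupe_identical_tts(AnnotationSet(layout, genes))
        assert len(out) == 1
        assert out.genes[0].gene_id == "g1"  # longest span

    def test_tie_broken_by_smallest_gene_id(self, layout):
        a = GeneModel("zeta", "zeta", "chr1", "+", 1_001, 5_000)
        b = GeneModel("alpha", "alpha", "chr1", "+", 1_001, 5_000)
        out = dedupe_identical_tts(AnnotationSet(layout, [a, b]))
        assert [g.gene_id for g in out] == ["alpha"]

    def test_same_tts_different_strand_both_kept(self, layout):
        a = GeneModel("a", "a", "chr1", "+", 1_001, 5_000)
        b = GeneModel("b", "b", "chr1", "-", 5_000, 9_000)
        assert len(dedupe_identical_tts(AnnotationSet(layout, [a, b]))) == 2

    def test_permutation_invariance_random(self, layout, rng):
        ann = random_annotation(rng, 60, chrom_len=100_000)
        kept = {g.gene_id for g in dedupe_identical_tts(ann)}
        for _ in range(5):
            perm = list(ann.genes)
            rng.shuffle(perm)
            kept2 = {g.gene_id for g in dedupe_identical_tts(ann.with_genes(perm))}
            assert kept2 == kept


class TestComputeExtendedTts:
    CFG = ExtensionConfig()

    def test_isolated_full_extension(self, layout):
        g = GeneModel("a", "a", "chr1", "+", 40_001, 50_000)
        ann = AnnotationSet(layout, [g])
        assert compute_extended_tts(g, ann, self.CFG) == 60_000

    def test_downstream_tss_stops_one_bp_upstream(self, layout):
        g = GeneModel("a", "a", "chr1", "+", 40_001, 50_000)
        o = GeneModel("b", "b", "chr1", "+", 53_000, 56_000)
        ann = AnnotationSet(layout, [g, o])
        assert compute_extended_tts(g, ann, self.CFG) == 52_999

    def test_convergent_midpoint_disjoint(self, layout):
        gp = GeneModel("p", "p", "chr1", "+", 40_001, 50_000)
        gm = GeneModel("m", "m", "chr1", "-", 56_000, 60_000)
        ann = AnnotationSet(layout, [gp, gm])
        assert compute_extended_tts(gp, ann, self.CFG) == 53_000
        assert compute_extended_tts(gm, ann, self.CFG) == 53_001

    def test_clamped_at_chromosome_end(self, layout):
        g = GeneModel("a", "a", "chr1", "+", 990_001, 995_000)
        ann = AnnotationSet(layout, [g])
        assert compute_extended_tts(g, ann, self.CFG) == 1_000_000

    def test_minus_strand_mirror(self, layout):
        g = GeneModel("a", "a", "chr1", "-", 50_000, 60_000)
        o = GeneModel("b", "b", "chr1", "-", 44_000, 47_000)  # tss at 47,000
        ann = AnnotationSet(layout, [g, o])
        assert compute_extended_tts(g, ann, self.CFG) == 47_001

    def test_adjacent_body_zero_extension(self, layout):
        g = GeneModel("a", "a", "chr1", "+", 40_001, 50_000)
        o = GeneModel("b", "b", "chr1", "+", 50_001, 52_000)
        ann = AnnotationSet(layout, [g, o])
        assert compute_extended_tts(g, ann, self.CFG) == 50_000

    def test_non_member_rejected(self, layout):
        g = GeneModel("a", "a", "chr1", "+", 40_001, 50_000)
        stranger = GeneModel("x", "x", "chr1", "+", 1, 100)
        ann = AnnotationSet(layout, [g])
        with pytest.raises(Sc3kitError, match="not a member"):
            compute_extended_tts(stranger, ann, self.CFG)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_base_walk_oracle_small(self, seed):
        rng = np.random.default_rng(seed)
        ann = random_annotation(rng, 20, chrom_len=120_000)
        cfg = ExtensionConfig(removed_biotypes=frozenset())
        work = dedupe_identical_tts(ann)
        for g in work:
            got = compute_extended_tts(g, work, cfg)
            want = walk_extension_oracle(
                g, work.genes, work.layout.lengths, cfg.max_extension)
            assert got == want, g


class TestExtendAll:
    def test_zero_extension_is_identity(self, layout):
        g = GeneModel("a", "a", "chr1", "+", 40_001, 50_000)
        out = extend_all(AnnotationSet(layout, [g]), ExtensionConfig(max_extension=0))
        assert out.get("a").end == 50_000

    def test_planted_scenarios_match_pairwise_oracle(self, rng):
        from sc3kit.simulate import make_annotation

        layout = GenomeLayout({"chr1": 2_000_000})
        ann, _ = make_annotation(
            layout, {s: 3 for s in ("isolated", "shared_tts", "tandem_same_strand",
                                    "convergent", "body_intrusion",
                                    "pseudogene_neighbor")}, seed=7)
        cfg = ExtensionConfig()
        out = extend_all(ann, cfg)
        retained = dedupe_identical_tts(filter_biotypes(ann, cfg))
        for g in retained:
            want = pairwise_extension_oracle(
                g, retained.genes, layout.lengths, cfg.max_extension)
            assert out.get(g.gene_id).tts == want

    def test_extension_extends_three_prime_exon(self, layout):
        g = GeneModel("a", "a", "chr1", "+", 10_001, 15_000,
                      exons=((10_001, 11_000), (12_001, 15_000)))
        out = extend_all(AnnotationSet(layout, [g]))
        assert out.get("a").exons == ((10_001, 11_000), (12_001, 25_000))

    def test_pseudogene_blocks_only_with_after_order(self, layout):
        g = GeneModel("a", "a", "chr1", "+", 40_001, 50_000)
        ps = GeneModel("ps", "ps", "chr1", "+", 53_000, 55_000, biotype="pseudogene")
        ann = AnnotationSet(layout, [g, ps])
        before = extend_all(ann, ExtensionConfig(biotype_filter_order="before_extension"))
        after = extend_all(ann, ExtensionConfig(biotype_filter_order="after_extension"))
        assert before.get("a").tts == 60_000
        assert after.get("a").tts == 52_999
        assert "ps" not in before and "ps" not in after

    def test_rerun_respects_oracle_on_extended_coordinates(self, layout):
        # the rewrite is deliberately not idempotent; a second pass must still
        # obey the collision rules evaluated on the extended coordinates
        g1 = GeneModel("a", "a", "chr1", "+", 10_001, 15_000)
        g2 = GeneModel("b", "b", "chr1", "+", 40_001, 45_000)
        cfg = ExtensionConfig()
        once = extend_all(AnnotationSet(layout, [g1, g2]), cfg)
        twice = extend_all(once, cfg)
        for g in once:
            limit = walk_extension_oracle(g, once.genes, layout.lengths,
                                          cfg.max_extension)
            assert twice.get(g.gene_id).tts <= limit

    def test_order_independence(self, rng):
        ann = random_annotation(rng, 50, chrom_len=200_000)
        out1 = extend_all(ann)
        perm = list(ann.genes)
        rng.shuffle(perm)
        out2 = extend_all(ann.with_genes(perm))
        coords1 = {g.gene_id: (g.start, g.end) for g in out1}
        coords2 = {g.gene_id: (g.start, g.end) for g in out2}
        assert coords1 == coords2

    @pytest.mark.parametrize("seed", range(15))
    def test_invariants_on_random_annotations(self, seed):
        rng = np.random.default_rng(1000 + seed)
        ann = random_annotation(rng, 80, chrom_len=250_000)
        cfg = ExtensionConfig()
        out = extend_all(ann, cfg)
        retained = dedupe_identical_tts(filter_biotypes(ann, cfg))
        originals = {g.gene_id: g for g in retained}
        for g in out:
            orig = originals[g.gene_id]
            growth = (g.tts - orig.tts) if g.strand == "+" else (orig.tts - g.tts)
            assert 0 <= growth <= cfg.max_extension
            # the added bases never overlap another retained gene's original
            # body on the same strand
            if growth:
                lo, hi = ((orig.tts + 1, g.tts) if g.strand == "+"
                          else (g.tts, orig.tts - 1))
                for o in retained:
                    if o.gene_id == g.gene_id or o.chrom != g.chrom:
                        continue
                    if o.strand == g.strand:
                        assert not (o.start <= hi and o.end >= lo), (g, o)


class TestNameMapping:
    def test_rename_applied(self, toy_annotation):
        out = apply_name_mapping(toy_annotation, {"ALPHA": "POU5F1"})
        assert out.get("geneA").gene_name == "POU5F1"
        assert out.get("geneB").gene_name == "BETA"

    def test_empty_mapping_identity(self, toy_annotation):
        out = apply_name_mapping(toy_annotation, {})
        assert [g.gene_name for g in out] == [g.gene_name for g in toy_annotation]

    def test_unused_keys_warn(self, toy_annotation, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sc3kit.annotation"):
            out = apply_name_mapping(toy_annotation, {"NOPE": "X"})
        assert any("unused" in r.message for r in caplog.records)
        assert [g.gene_name for g in out] == [g.gene_name for g in toy_annotation]

    def test_duplicate_key_in_tsv_rejected(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("LOC1\tA\nLOC1\tB\n")
        with pytest.raises(Sc3kitError, match="duplicate"):
            read_name_mapping(p)
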