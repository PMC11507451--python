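"""Gene-model parsing and constitutive-region derivation."""

import numpy as np
import pytest

from eisa.annotation import (
    AnnotationError,
    GtfParseError,
    RegionSet,
    constitutive_exons,
    constitutive_introns,
    parse_gtf,
    pick_canonical,
    read_region_annotation,
    utr_lengths,
    utr_table,
    write_region_annotation,
)
from eisa.experiments import brute_force_regions, random_gene
from eisa.intervals import GenomicInterval

from conftest import make_gene

GTF_ONE_GENE = """\
chr1\tensembl\tgene\t1\t100\t.\t+\t.\tgene_id "G1";
chr1\tensembl\ttranscript\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tensembl\texon\t1\t100\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
"""


class TestParseGtf:
    def test_coordinates_become_zero_based_half_open(self):
        genes = parse_gtf(iter(GTF_ONE_GENE.splitlines()))
        assert len(genes) == 1
        assert genes[0].transcripts[0].exons == [(0, 100)]

    def test_transcript_source_filter_drops_havana_only_genes(self):
        gtf = GTF_ONE_GENE.replace("ensembl", "havana")
        assert parse_gtf(iter(gtf.splitlines())) == []
        # but an explicit allow-list keeps them
        kept = parse_gtf(iter(gtf.splitlines()), allowed_sources={"havana"})
        assert len(kept) == 1

    def test_simulated_gtf_round_trips_gene_and_exon_counts(self, sim_bundle):
        ann, *_ = sim_bundle
        genes = parse_gtf(iter(ann.gtf_text.splitlines()))
        assert len(genes) == len(ann.genes)
        for parsed, built in zip(genes, ann.genes):
            assert parsed.gene_id == built.gene_id
            assert [t.exons for t in parsed.transcripts] == [
                t.exons for t in built.transcripts
            ]

    def test_malformed_attributes_name_the_line(self):
        bad = GTF_ONE_GENE + 'chr1\tensembl\texon\t5\t50\t.\t+\t.\tnot an attribute\n'
        with pytest.raises(GtfParseError, match="line 4"):
            parse_gtf(iter(bad.splitlines()))

    def test_wrong_field_count_rejected(self):
        with pytest.raises(GtfParseError, match="9 tab-separated"):
            parse_gtf(iter(['chr1\texon\t1\t100']))

    def test_exon_outside_transcript_bounds_rejected(self):
        bad = GTF_ONE_GENE + 'chr1\tensembl\texon\t150\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        with pytest.raises(AnnotationError, match="outside declared transcript bounds"):
            parse_gtf(iter(bad.splitlines()))

    def test_multi_chromosome_gene_rejected(self):
        from eisa.annotation import GeneModel, TranscriptModel

        t1 = TranscriptModel("T1", "G", "ensembl", "chr1", "+", [(0, 10)])
        t2 = TranscriptModel("T2", "G", "ensembl", "chr2", "+", [(0, 10)])
        with pytest.raises(AnnotationError, match="multiple chromosomes"):
            GeneModel("G", "G", [t1, t2])


class TestConstitutiveRegions:
    def test_single_isoform_gene_keeps_its_exons_and_gaps(self):
        gene = make_gene("G", [[(0, 100), (200, 300)]])
        assert constitutive_exons(gene).intervals == [(0, 100), (200, 300)]
        assert constitutive_introns(gene).intervals == [(100, 200)]

    def test_intersection_of_isoform_exon_unions(self):
        gene = make_gene("G", [[(0, 100), (200, 300)], [(0, 100), (250, 300)]])
        assert constitutive_exons(gene).intervals == [(0, 100), (250, 300)]

    def test_disjoint_isoforms_yield_empty_exon_set(self):
        gene = make_gene("G", [[(0, 100)], [(200, 300)]])
        assert constitutive_exons(gene).intervals == []

    def test_introns_are_union_gaps(self):
        gene = make_gene("G", [[(0, 100), (200, 300)], [(0, 150), (200, 300)]])
        assert constitutive_introns(gene).intervals == [(150, 200)]

    def test_single_exon_gene_has_no_introns(self):
        gene = make_gene("G", [[(0, 500)]])
        assert constitutive_introns(gene).intervals == []

    def test_exon_and_intron_sets_are_disjoint(self, rng):
        from eisa.intervals import intersect_blocks

        for _ in range(50):
            gene = random_gene(rng)
            ex = constitutive_exons(gene).intervals
            it = constitutive_introns(gene).intervals
            assert intersect_blocks(ex, it) == []

    def test_matches_per_base_brute_force(self, rng):
        for _ in range(200):
            gene = random_gene(rng)
            exp_ex, exp_in = brute_force_regions(gene)
            assert constitutive_exons(gene).intervals == exp_ex
            assert constitutive_introns(gene).intervals == exp_in

    def test_duplicating_an_isoform_changes_nothing(self, rng):
        from eisa.annotation import GeneModel

        for _ in range(25):
            gene = random_gene(rng)
            dup = GeneModel(gene.gene_id, gene.gene_name,
                            gene.transcripts + [gene.transcripts[0]])
            assert constitutive_exons(dup).intervals == constitutive_exons(gene).intervals
            assert constitutive_introns(dup).intervals == constitutive_introns(gene).intervals


class TestUtrLengths:
    def test_plus_strand(self):
        gene = make_gene("G", [[(0, 100)]], cds=[(10, 90)])
        rec = utr_lengths(gene, "G.T1")
        assert (rec.utr5_length, rec.utr3_length) == (10, 10)

    def test_minus_strand_flips(self):
        gene = make_gene("G", [[(0, 100)]], strand="-", cds=[(10, 90)])
        rec = utr_lengths(gene, "G.T1")
        assert (rec.utr5_length, rec.utr3_length) == (10, 10)
        # asymmetric CDS to prove the flip
        gene = make_gene("G", [[(0, 100)]], strand="-", cds=[(30, 90)])
        rec = utr_lengths(gene, "G.T1")
        assert (rec.utr5_length, rec.utr3_length) == (10, 30)

    def test_utrs_sum_across_exons(self):
        gene = make_gene("G", [[(0, 50), (100, 150)]], cds=[(40, 50), (100, 110)])
        rec = utr_lengths(gene, "G.T1")
        assert (rec.utr5_length, rec.utr3_length) == (40, 40)

    def test_cds_covering_everything_gives_zero_utrs(self):
        gene = make_gene("G", [[(0, 100)]], cds=[(0, 100)])
        rec = utr_lengths(gene, "G.T1")
        assert (rec.utr5_length, rec.utr3_length) == (0, 0)

    def test_noncoding_transcript_flagged(self):
        gene = make_gene("G", [[(0, 100)]])
        rec = utr_lengths(gene, "G.T1")
        assert not rec.coding and rec.utr5_length is None

    def test_unknown_canonical_id_raises(self):
        gene = make_gene("G", [[(0, 100)]])
        with pytest.raises(KeyError):
            utr_lengths(gene, "nope")

    def test_canonical_fallback_prefers_longest_cds_then_id(self):
        from eisa.annotation import GeneModel, TranscriptModel

        t1 = TranscriptModel("T1", "G", "ensembl", "chr1", "+", [(0, 100)], cds=[(0, 50)])
        t2 = TranscriptModel("T2", "G", "ensembl", "chr1", "+", [(0, 100)], cds=[(0, 80)])
        gene = GeneModel("G", "G", [t1, t2])
        assert pick_canonical(gene) == "T2"
        assert pick_canonical(gene, {"G": "T1"}) == "T1"


class TestRegionIo:
    def test_saf_uses_one_based_inclusive(self, tmp_path):
        rs = RegionSet("G", "constitutive_exon", "chr1", "+", [(0, 100)])
        path = tmp_path / "r.tsv"
        write_region_annotation([rs], path)
        line = path.read_text().splitlines()[1]
        assert line.split("\t")[2:4] == ["1", "100"]

    def test_round_trip_identity(self, tmp_path, sim_bundle):
        ann, *_ = sim_bundle
        regionsets = [constitutive_exons(g) for g in ann.genes]
        regionsets = [r for r in regionsets if r.intervals]
        path = tmp_path / "regions.tsv"
        write_region_annotation(regionsets, path)
        back = read_region_annotation(path, "constitutive_exon")
        assert [(r.gene_id, r.intervals) for r in back] == [
            (r.gene_id, r.intervals) for r in regionsets
        ]

    def test_empty_regionset_writes_no_rows(self, tmp_path):
        rs = RegionSet("G", "constitutive_exon", "chr1", "+", [])
        path = tmp_path / "r.tsv"
        write_region_annotation([rs], path)
        assert read_region_annotation(path, "constitutive_exon") == []


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 0, 10, "*")


def test_utr_table_matches_generator_truth(sim_bundle):
    ann, *_ = sim_bundle
    table = utr_table(ann.genes, ann.canonical)
    truth = ann.truth.table
    assert (table["utr3"].reindex(truth.index) == truth["utr3"]).all()
    assert (table["utr5"].reindex(truth.index) == truth["utr5"]).all()
    assert (table["total_intron_bp"].reindex(truth.index) == truth["intron_bp"]).all()
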