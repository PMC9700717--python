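"""Coordinate systems, annotation parsing, projection, bedGraph I/O."""

import numpy as np
import pytest

from ribortc.genomics_io import (
    TranscriptModel,
    project_to_transcript,
    read_annotation,
    read_coverage_track,
    read_transcript_alignments,
    write_coverage_track,
    write_transcript_sam,
)
from conftest import write_sam

GTF_SINGLE = (
    'chr1\tt\texon\t1\t1400\t.\t+\t.\tgene_id "g1"; transcript_id "tx1";\n'
    'chr1\tt\tCDS\t11\t1192\t.\t+\t.\tgene_id "g1"; transcript_id "tx1";\n'
)

# minus strand, two exons; CDS occupies tx 9..99 (stop codon tx 96..98)
GTF_MINUS = (
    'chr1\tt\texon\t101\t150\t.\t-\t.\tgene_id "gm"; transcript_id "txm";\n'
    'chr1\tt\texon\t201\t260\t.\t-\t.\tgene_id "gm"; transcript_id "txm";\n'
    'chr1\tt\tCDS\t201\t251\t.\t-\t.\tgene_id "gm"; transcript_id "txm";\n'
    'chr1\tt\tCDS\t112\t150\t.\t-\t.\tgene_id "gm"; transcript_id "txm";\n'
)


class TestTranscriptModel:
    def test_cds_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            TranscriptModel("t", "g", "c", "+", ((0, 100),), 10, 21)

    def test_ptc_must_be_inside_cds(self):
        with pytest.raises(ValueError, match="PTC"):
            TranscriptModel("t", "g", "c", "+", ((0, 100),), 10, 40,
                            ptc_codon_index=11)

    def test_codon_indexing_matches_mutation_nomenclature(self, tp53_model):
        # codon 1 is the start codon; the PTC sits 212 codons downstream
        assert tp53_model.codon_tx(1) == tp53_model.cds_start_codon_tx
        assert tp53_model.codon_tx(213) == tp53_model.cds_start_codon_tx + 636
        assert tp53_model.stop_codon_index == 394

    def test_coordinate_round_trip_both_strands(self, two_exon_minus_model):
        plus = TranscriptModel("txp", "gp", "chr1", "+",
                               ((100, 150), (200, 260)), 9, 96)
        for m in (plus, two_exon_minus_model):
            for t in range(m.tx_length):
                g = m.tx_to_genome(t)
                assert m.genome_to_tx(g) == t

    def test_minus_strand_tx_coords_increase_5p_to_3p(self, two_exon_minus_model):
        m = two_exon_minus_model
        # genomic rightmost base of the 5'-most exon is transcript position 0
        assert m.genome_to_tx(259) == 0
        assert m.genome_to_tx(200) == 59
        assert m.genome_to_tx(149) == 60
        assert m.genome_to_tx(100) == 109
        assert m.genome_to_tx(170) is None  # intronic


class TestReadAnnotation:
    def test_single_exon_cds_fields(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_SINGLE)
        models, skipped = read_annotation(p, {"tx1": 213})
        m = models["tx1"]
        assert (m.cds_start_codon_tx, m.canonical_stop_tx, m.ptc_codon_index) == (
            10, 1189, 213)
        assert m.canonical_stop_tx - m.cds_start_codon_tx == 3 * 393
        assert not skipped

    def test_malformed_cds_skipped_with_reason(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_SINGLE.replace("\t1192\t", "\t1193\t"))
        models, skipped = read_annotation(p)
        assert "tx1" not in models
        assert "malformed CDS" in skipped["tx1"]

    def test_ptc_outside_cds_is_fatal_naming_transcript(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_SINGLE)
        with pytest.raises(ValueError, match="tx1"):
            read_annotation(p, {"tx1": 394})

    def test_minus_strand_two_exon_hand_oracle(self, tmp_path, two_exon_minus_model):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_MINUS)
        models, skipped = read_annotation(p)
        m = models["txm"]
        assert m.exons == two_exon_minus_model.exons  # transcription order
        assert m.cds_start_codon_tx == 9
        assert m.canonical_stop_tx == 96
        assert not skipped

    def test_stop_codon_feature_convention(self, tmp_path):
        # Ensembl-style: CDS excludes the stop, a stop_codon feature follows
        gtf = (
            'chr1\tt\texon\t1\t1400\t.\t+\t.\tgene_id "g1"; transcript_id "tx1";\n'
            'chr1\tt\tCDS\t11\t1189\t.\t+\t.\tgene_id "g1"; transcript_id "tx1";\n'
            'chr1\tt\tstop_codon\t1190\t1192\t.\t+\t.\tgene_id "g1"; transcript_id "tx1";\n'
        )
        p = tmp_path / "a.gtf"
        p.write_text(gtf)
        models, _ = read_annotation(p)
        assert models["tx1"].canonical_stop_tx == 1189


class TestAnnotationWriter:
    def test_gtf_round_trip_both_strands(self, tmp_path, tp53_model,
                                         two_exon_minus_model):
        from ribortc.genomics_io import write_annotation_gtf, write_ptc_table
        from ribortc.genomics_io import read_ptc_table

        models = {tp53_model.transcript_id: tp53_model,
                  "txm": two_exon_minus_model}
        gtf = tmp_path / "a.gtf"
        write_annotation_gtf(models, gtf)
        ptc = tmp_path / "ptc.tsv"
        write_ptc_table(models, ptc)
        back, skipped = read_annotation(gtf, read_ptc_table(ptc))
        assert not skipped
        for tid, m in models.items():
            b = back[tid]
            assert (b.exons, b.cds_start_codon_tx, b.canonical_stop_tx,
                    b.ptc_codon_index) == (m.exons, m.cds_start_codon_tx,
                                           m.canonical_stop_tx, m.ptc_codon_index)


class TestProjection:
    def _models(self, two_exon_minus_model):
        plus = TranscriptModel("txp", "gp", "chr1", "+", ((100, 150),), 9, 30)
        return {"txp": plus, "txm": two_exon_minus_model}

    def test_identity_projection_plus_strand(self, tmp_path, two_exon_minus_model):
        sam = write_sam(tmp_path / "r.sam", {"chr1": 2000},
                        [("r1", 0, "chr1", 100, "28M")])
        out, disc = project_to_transcript(sam, self._models(two_exon_minus_model))
        assert [a.five_prime_tx for a in out if a.transcript_id == "txp"] == [0]
        assert sum(disc.values()) + len(out) == 1

    def test_minus_strand_brute_force_table(self, tmp_path, two_exon_minus_model):
        m = two_exon_minus_model
        table = {}  # independent per-base map: exon walk in transcription order
        t = 0
        for s, e in [(200, 260), (100, 150)]:
            for g in range(e - 1, s - 1, -1):
                table[g] = t
                t += 1
        # reverse-strand read occupying genomic [230, 258): its transcript 5'
        # end is the rightmost genomic base
        sam = write_sam(tmp_path / "r.sam", {"chr1": 2000},
                        [("r1", 16, "chr1", 230, "28M")])
        out, _ = project_to_transcript(sam, {"txm": m})
        assert len(out) == 1
        assert out[0].five_prime_tx == table[257]
        assert out[0].length == 28

    def test_spliced_read_matching_intron_is_assigned(self, tmp_path,
                                                      two_exon_minus_model):
        # 14M 50N 14M crosses the txm intron (genomic 150..200) exactly
        sam = write_sam(tmp_path / "r.sam", {"chr1": 2000},
                        [("r1", 16, "chr1", 136, "14M50N14M")])
        out, disc = project_to_transcript(sam, {"txm": two_exon_minus_model})
        assert len(out) == 1 and out[0].length == 28
        assert out[0].five_prime_tx == two_exon_minus_model.genome_to_tx(213)

    def test_intron_overlapping_read_discarded(self, tmp_path, two_exon_minus_model):
        sam = write_sam(tmp_path / "r.sam", {"chr1": 2000},
                        [("r1", 16, "chr1", 140, "28M")])
        out, disc = project_to_transcript(sam, {"txm": two_exon_minus_model})
        assert not out
        assert disc["no_transcript"] == 1

    def test_strand_mismatch_discarded(self, tmp_path, two_exon_minus_model):
        sam = write_sam(tmp_path / "r.sam", {"chr1": 2000},
                        [("r1", 0, "chr1", 230, "28M")])  # forward read, minus tx
        out, disc = project_to_transcript(sam, {"txm": two_exon_minus_model})
        assert not out and disc["no_transcript"] == 1

    def test_conservation_assigned_plus_discarded(self, tmp_path,
                                                  two_exon_minus_model):
        reads = [("r%d" % i, 16, "chr1", 200 + i, "28M") for i in range(40)]
        sam = write_sam(tmp_path / "r.sam", {"chr1": 2000}, reads)
        out, disc = project_to_transcript(sam, {"txm": two_exon_minus_model})
        assert len(out) + sum(disc.values()) == 40

    def test_transcript_sam_round_trip(self, tmp_path, tp53_model):
        from ribortc.genomics_io import FootprintAlignment

        models = {tp53_model.transcript_id: tp53_model}
        alns = [FootprintAlignment(f"r{i}", tp53_model.transcript_id, 10 * i, 28)
                for i in range(5)]
        path = tmp_path / "t.sam"
        write_transcript_sam(alns, models, path)
        back, disc = read_transcript_alignments(path, models)
        assert [(a.five_prime_tx, a.length) for a in back] == [
            (a.five_prime_tx, a.length) for a in alns]
        assert not disc


class TestBedGraph:
    def test_run_length_merge(self, tmp_path):
        counts = np.zeros(12)
        counts[5] = counts[6] = 3
        counts[9] = 1
        path = tmp_path / "c.bedgraph"
        write_coverage_track(("tx1", counts), path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("track")]
        assert lines == ["tx1\t5\t7\t3", "tx1\t9\t10\t1"]

    def test_empty_profile_header_only(self, tmp_path):
        path = tmp_path / "c.bedgraph"
        write_coverage_track(("tx1", np.zeros(5)), path)
        text = path.read_text()
        assert text.startswith("track") and len(text.splitlines()) == 1

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.8, 200).astype(float)
        path = tmp_path / "c.bedgraph"
        write_coverage_track(("tx1", counts), path)
        back = read_coverage_track(path)["tx1"]
        rebuilt = np.zeros_like(counts)
        for pos, v in back.items():
            rebuilt[pos] = v
        assert np.array_equal(rebuilt, counts)
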