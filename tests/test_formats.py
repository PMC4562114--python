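"""Format parsing and writing: reads, annotations, mapper output, results."""

import gzip
import random
import re

import pysam
import pytest

from tentacle import formats
from tentacle.formats import (Annotation, FormatError, Hit, RegionResult,
                              cigar_reference_span, parse_blast8, parse_sam,
                              read_annotations, read_results, stream_reads,
                              write_annotations, write_reads, write_results)

FASTA = ">readA desc\nACGTACGT\n>readB\nTTTT\n"
FASTQ = "@readA\nACGT\n+\nIIII\n@readB\nGGGG\n+\n!!!I\n"


class TestStreamReads:
    def test_fasta_records(self, tmp_path):
        p = tmp_path / "r.fasta"
        p.write_text(FASTA)
        recs = list(stream_reads(p))
        assert [(r.id, r.sequence) for r in recs] == [
            ("readA", "ACGTACGT"), ("readB", "TTTT")]
        assert all(r.qualities is None for r in recs)

    def test_gzip_transparency(self, tmp_path):
        plain = tmp_path / "r.fasta"
        plain.write_text(FASTA)
        gz = tmp_path / "r.fasta.gz"
        gz.write_bytes(gzip.compress(FASTA.encode()))
        assert list(stream_reads(gz)) == list(stream_reads(plain))

    def test_fastq_qualities_phred33(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text(FASTQ)
        recs = list(stream_reads(p))
        assert recs[0].qualities == (40, 40, 40, 40)
        assert recs[1].qualities == (0, 0, 0, 40)

    def test_format_hint_forces_parser(self, tmp_path):
        p = tmp_path / "r.txt"
        p.write_text(FASTA)
        assert len(list(stream_reads(p, format_hint="fasta"))) == 2

    def test_malformed_fastq_reports_record(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nIII\n")  # 3 qualities for 4 bases
        with pytest.raises(FormatError) as exc:
            list(stream_reads(p))
        assert "record #1" in str(exc.value)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            list(stream_reads(p))

    def test_streaming_memory_bounded_by_one_record(self, tmp_path):
        """Iterating a large FASTQ never materializes the file."""
        import tracemalloc
        p = tmp_path / "big.fastq"
        with open(p, "w") as out:
            for i in range(50_000):
                out.write(f"@r{i}\n{'ACGT' * 15}\n+\n{'I' * 60}\n")
        file_size = p.stat().st_size
        tracemalloc.start()
        n = sum(1 for _ in stream_reads(p))
        _, peak = tracemalloc.get_traced_memory()
        tracemalloc.stop()
        assert n == 50_000
        assert peak < file_size / 10  # far below the whole file

    def test_fastq_write_read_round_trip(self, tmp_path):
        rng = random.Random(7)
        recs = [formats.SequenceRecord(
            f"r{i}", "".join(rng.choice("ACGT") for _ in range(30)),
            tuple(rng.randrange(0, 41) for _ in range(30)))
            for i in range(25)]
        p = tmp_path / "rt.fastq"
        write_reads(recs, p, "fastq")
        assert list(stream_reads(p)) == recs


class TestAnnotations:
    def test_coordinates_normalized_half_open(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("contig1\t1\t45\t+\tgeneA\n")
        (ann,) = read_annotations(p)
        assert (ann.ref_id, ann.start, ann.end, ann.strand, ann.label) == \
            ("contig1", 0, 45, "+", "geneA")

    def test_single_base_region(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("contig1\t10\t10\t-\tgeneB\n")
        (ann,) = read_annotations(p)
        assert (ann.start, ann.end) == (9, 10)

    def test_comments_skipped_order_preserved(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("# header\nc\t5\t9\t.\tg1\nc\t1\t3\t.\tg2\n")
        anns = read_annotations(p)
        assert [a.label for a in anns] == ["g1", "g2"]

    @pytest.mark.parametrize("line", [
        "c\tx\t9\t.\tg",         # non-integer
        "c\t9\t5\t.\tg",         # start > end
        "c\t0\t5\t.\tg",         # start below 1
        "c\t1\t5\t.\tg\textra",  # wrong column count
        "c\t1\t5\t?\tg",         # bad strand
    ])
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "a.tsv"
        p.write_text("c\t1\t5\t.\tok\n" + line + "\n")
        with pytest.raises(FormatError) as exc:
            read_annotations(p)
        assert exc.value.line == 2

    def test_round_trip_of_many_annotations(self, tmp_path):
        rng = random.Random(3)
        anns = []
        for i in range(100):
            start = rng.randrange(0, 500)
            anns.append(Annotation(f"ref{rng.randrange(5)}", start,
                                   start + rng.randrange(1, 300), "+",
                                   f"g{i}"))
        p = tmp_path / "many.tsv"
        write_annotations(anns, p)
        assert read_annotations(p) == anns

    def test_coordinate_conversion_is_involution(self):
        ann = Annotation("c", 9, 10, "+", "g")
        assert Annotation.from_file_coords("c", *ann.to_file_coords(),
                                           "+", "g") == ann


BLAST8_LINE = "q1\tr1\t100.00\t45\t0\t0\t1\t45\t10\t54\t1e-20\t90.0"


class TestBlast8:
    def test_forward_hit_normalized(self):
        (hit,) = parse_blast8([BLAST8_LINE])
        assert (hit.query_id, hit.ref_id, hit.ref_start, hit.ref_end,
                hit.identity_pct, hit.aln_len, hit.file_order) == \
            ("q1", "r1", 9, 54, 100.0, 45, 0)

    def test_reverse_hit_same_interval(self):
        line = BLAST8_LINE.replace("\t10\t54\t", "\t54\t10\t")
        (hit,) = parse_blast8([line])
        assert (hit.ref_start, hit.ref_end) == (9, 54)

    def test_file_order_sequential(self):
        hits = list(parse_blast8([BLAST8_LINE, BLAST8_LINE, BLAST8_LINE]))
        assert [h.file_order for h in hits] == [0, 1, 2]

    def test_malformed_line_skip_policy(self):
        hits = list(parse_blast8([BLAST8_LINE, "garbage line", BLAST8_LINE]))
        assert len(hits) == 2
        assert [h.file_order for h in hits] == [0, 1]

    def test_malformed_line_strict_policy(self):
        with pytest.raises(FormatError) as exc:
            list(parse_blast8([BLAST8_LINE, "garbage"], errors="strict"))
        assert exc.value.line == 2

    def test_ground_truth_file_parses_completely(self, small_sample):
        spike = small_sample["spike"]
        hits = list(parse_blast8(spike.mapping_path))
        n_expected = sum(s.n_reads for s in spike.spiked)
        assert len(hits) == n_expected
        read_len = small_sample["design"].read_length
        assert sum(h.ref_end - h.ref_start for h in hits) == \
            n_expected * read_len


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:r1\tLN:1000\n"


def sam_line(qname="q1", flag=0, rname="r1", pos=10, cigar="45M", seq=None,
             tags=""):
    seq = seq or "A" * sum(int(n) for n, op in
                           re.findall(r"(\d+)([MIS=X])", cigar))
    line = (f"{qname}\t{flag}\t{rname}\t{pos}\t60\t{cigar}\t*\t0\t0"
            f"\t{seq}\t*")
    return line + ("\t" + tags if tags else "")


class TestSam:
    def test_pos_and_cigar_give_interval(self):
        (hit,) = parse_sam([sam_line(pos=10, cigar="45M")])
        assert (hit.ref_start, hit.ref_end) == (9, 54)

    def test_unmapped_flag_skipped(self):
        hits = list(parse_sam([sam_line(flag=4)]))
        assert hits == []

    def test_indel_cigar_reference_span(self):
        # 20M + 20M + 5M consume 45 reference bases, 2D consumes 2, 5I none
        (hit,) = parse_sam([sam_line(pos=10, cigar="20M5I20M2D5M")])
        assert (hit.ref_start, hit.ref_end) == (9, 56)
        assert hit.ref_end - hit.ref_start == 47

    def test_identity_from_nm_tag(self):
        (hit,) = parse_sam([sam_line(cigar="50M", tags="NM:i:5")])
        assert hit.identity_pct == pytest.approx(90.0)
        (hit,) = parse_sam([sam_line(cigar="50M")])
        assert hit.identity_pct == 100.0

    def test_star_cigar_on_mapped_record_skipped(self):
        hits = list(parse_sam([sam_line(cigar="*"), sam_line()]))
        assert len(hits) == 1

    def test_header_optional(self):
        with_header = list(parse_sam((SAM_HEADER + sam_line()).splitlines()))
        without = list(parse_sam([sam_line()]))
        assert with_header == without

    def test_reference_span_matches_pysam(self, tmp_path):
        """Our CIGAR arithmetic against pysam on randomized alignments."""
        rng = random.Random(5)
        lines = []
        for i in range(50):
            ops = []
            for _ in range(rng.randrange(1, 5)):
                ops.append(f"{rng.randrange(1, 30)}"
                           f"{rng.choice('MMMMIDN=X')}")
            cigar = "".join(ops)
            span, _ = cigar_reference_span(cigar)
            if span == 0:
                continue
            lines.append(sam_line(qname=f"q{i}", pos=rng.randrange(1, 500),
                                  cigar=cigar, seq="*"))
        sam_path = tmp_path / "x.sam"
        sam_path.write_text(SAM_HEADER + "\n".join(lines) + "\n")
        ours = {h.query_id: (h.ref_start, h.ref_end)
                for h in parse_sam(sam_path)}
        with pysam.AlignmentFile(str(sam_path), "r") as af:
            for rec in af:
                assert ours[rec.query_name] == \
                    (rec.reference_start, rec.reference_end)

    def test_blast8_and_sam_agree_on_same_placements(self):
        """The same read placements encoded both ways give identical intervals."""
        rng = random.Random(9)
        placements = [(f"q{i}", rng.randrange(0, 900), rng.randrange(20, 80))
                      for i in range(40)]
        blast_lines = [
            f"{q}\tr1\t100.00\t{ln}\t0\t0\t1\t{ln}\t{s + 1}\t{s + ln}"
            f"\t1e-10\t{2 * ln}" for q, s, ln in placements]
        sam_lines = [sam_line(qname=q, pos=s + 1, cigar=f"{ln}M", seq="*")
                     for q, s, ln in placements]
        b = [(h.query_id, h.ref_start, h.ref_end)
             for h in parse_blast8(blast_lines)]
        s = [(h.query_id, h.ref_start, h.ref_end)
             for h in parse_sam(sam_lines)]
        assert b == s


class TestResults:
    def test_empty_results_header_only(self, tmp_path):
        p = tmp_path / "res.tsv"
        write_results([], p)
        assert p.read_text() == formats.RESULTS_HEADER + "\n"

    def test_fixed_formatting(self, tmp_path):
        ann = Annotation("c1", 0, 100, "+", "g1")
        p = tmp_path / "res.tsv"
        write_results([RegionResult(ann, 3, 2.0, 2.0, 0.0)], p)
        row = p.read_text().splitlines()[1]
        assert row == "c1\t1\t100\t+\tg1\t3\t2.0000\t2.0000\t0.0000"

    def test_na_for_disabled_fields(self, tmp_path):
        ann = Annotation("c1", 0, 10, ".", "g")
        p = tmp_path / "res.tsv"
        write_results([RegionResult(ann, None, 1.0, 1.0, 0.0),
                       RegionResult(ann, 2, None, None, None)], p)
        rows = p.read_text().splitlines()[1:]
        assert rows[0].split("\t")[5] == "NA"
        assert rows[1].split("\t")[6:] == ["NA", "NA", "NA"]

    def test_round_trip_lossless_at_4_decimals(self, tmp_path):
        rng = random.Random(1)
        results = []
        for i in range(50):
            start = rng.randrange(0, 1000)
            ann = Annotation(f"c{rng.randrange(4)}", start,
                             start + rng.randrange(1, 500), "+", f"g{i}")
            vals = [round(rng.uniform(0, 50), 4) for _ in range(3)]
            results.append(RegionResult(ann, rng.randrange(100), *vals))
        p = tmp_path / "res.tsv"
        write_results(results, p)
        assert read_results(p) == results
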