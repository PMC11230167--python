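import pytest

from mave_anchor import (
    AlignmentBlock,
    AlignmentError,
    AlignmentHit,
    FixtureSpec,
    GeneContext,
    NoCompatibleHitError,
    coverage_identity,
    fixture_align,
    parse_psl,
    select_hit,
    select_hsp,
)
from mave_anchor.alignment import revcomp

PSL_HEADER = (
    "psLayout version 3\n\n"
    "match\tmis- \trep. \tN's\tQ gap\tQ gap\tT gap\tT gap\tstrand\tQ\tQ   \tQ    \tQ  \tT\tT   \tT    \tT  \tblock\tblockSizes \tqStarts\t tStarts\n"
    "     \tmatch\tmatch\t   \tcount\tbases\tcount\tbases\t      \tname\tsize\tstart\tend\tname\tsize\tstart\tend\tcount\n"
    "---------------------------------------------------------------------------------------------------------------------------------------------------------------\n"
)


def psl_row(
    matches=30, mismatches=0, strand="+", q_name="target", q_size=30,
    q_start=0, q_end=30, t_name="chr3", t_size=100000, t_start=1000, t_end=1030,
    sizes="30,", q_starts="0,", t_starts="1000,",
):
    n_blocks = len([s for s in sizes.split(",") if s])
    return "\t".join(map(str, [
        matches, mismatches, 0, 0, 0, 0, 0, 0, strand, q_name, q_size,
        q_start, q_end, t_name, t_size, t_start, t_end, n_blocks,
        sizes, q_starts, t_starts,
    ]))


class TestParsePsl:
    def test_single_block_row(self):
        (hit,) = parse_psl(psl_row())
        assert hit.chromosome == "chr3" and hit.strand == "+"
        (b,) = hit.blocks
        assert (b.query_start, b.query_end, b.ref_start, b.ref_end) == (0, 30, 1000, 1030)

    def test_header_only_stream_is_empty(self):
        assert parse_psl(PSL_HEADER) == []

    def test_two_rows_preserve_order(self):
        text = psl_row(t_name="chr3") + "\n" + psl_row(t_name="chr7")
        hits = parse_psl(PSL_HEADER + text)
        assert [h.chromosome for h in hits] == ["chr3", "chr7"]

    def test_wrong_column_count_names_line(self):
        with pytest.raises(AlignmentError, match="line 1"):
            parse_psl("1\t2\t3")

    def test_minus_strand_flips_query_offsets(self):
        # 10 nt query, one 6 nt block at reversed-query offset 1
        row = psl_row(
            matches=6, strand="-", q_size=10, q_start=1, q_end=7,
            sizes="6,", q_starts="1,", t_starts="500,", t_end=506,
        )
        (hit,) = parse_psl(row)
        (b,) = hit.blocks
        assert (b.query_start, b.query_end) == (3, 9)
        assert (b.ref_start, b.ref_end) == (500, 506)

    def test_protein_query_scales_to_nucleotide_space(self):
        row = psl_row(
            matches=10, strand="++", q_size=10, q_end=10,
            sizes="10,", q_starts="0,", t_starts="900,", t_end=930,
        )
        (hit,) = parse_psl(row)
        (b,) = hit.blocks
        assert (b.query_start, b.query_end, b.ref_start, b.ref_end) == (0, 30, 900, 930)

    def test_block_length_conservation(self):
        row = psl_row(sizes="10,20,", q_starts="0,10,", t_starts="1000,1500,",
                      matches=30, t_end=1520)
        (hit,) = parse_psl(row)
        for b in hit.blocks:
            assert b.query_end - b.query_start == b.ref_end - b.ref_start


def _hit(chrom, score, ref_start=100):
    size = max(score, 1)
    return AlignmentHit(
        chromosome=chrom, strand="+", score=score, matches=size, mismatches=0,
        blocks=[AlignmentBlock(0, size, ref_start, ref_start + size)],
    )


class TestHitSelection:
    def test_gene_context_filters_chromosome(self):
        hits = [_hit("chr3", 50), _hit("chr7", 80)]
        gene = GeneContext("SRC", "chr3", 90, 5000)
        assert select_hit(hits, gene).chromosome == "chr3"

    def test_without_gene_context_top_score_wins(self):
        hits = [_hit("chr3", 50), _hit("chr7", 80)]
        assert select_hit(hits, None).chromosome == "chr7"

    def test_single_hit_is_identity(self):
        (h,) = [_hit("chr1", 10)]
        assert select_hit([h]) is h

    def test_no_hit_on_gene_chromosome_raises(self):
        with pytest.raises(NoCompatibleHitError):
            select_hit([_hit("chr7", 80)], GeneContext("SRC", "chr3", 90, 5000))

    def test_selection_invariant_under_permutation(self):
        hits = [_hit("chr3", 50), _hit("chr3", 80), _hit("chr7", 99)]
        gene = GeneContext("G", "chr3", 0, 10)
        assert select_hit(hits, gene) is select_hit(list(reversed(hits)), gene)

    def test_hsp_minimum_distance_to_gene_start(self):
        hsps = [_hit("chr3", 10, ref_start=100), _hit("chr3", 10, ref_start=5000)]
        assert select_hsp(hsps, gene_start=90) is hsps[0]

    def test_hsp_single_is_identity(self):
        (h,) = [_hit("chr3", 10, ref_start=100)]
        assert select_hsp([h], 0) is h

    def test_hsp_equidistant_tie_keeps_input_order(self):
        hsps = [_hit("chr3", 10, ref_start=80), _hit("chr3", 10, ref_start=120)]
        assert select_hsp(hsps, gene_start=100) is hsps[0]


class TestCoverageIdentity:
    def test_perfect_full_length(self):
        assert coverage_identity(_hit("chr1", 60), 60) == (100.0, 100.0)

    def test_partial_coverage_and_identity(self):
        hit = AlignmentHit(
            chromosome="chr1", strand="+", score=24, matches=27, mismatches=3,
            blocks=[AlignmentBlock(0, 30, 1000, 1030)],
        )
        assert coverage_identity(hit, 60) == (50.0, 90.0)

    def test_zero_length_block_rejected_by_invariant(self):
        with pytest.raises(AlignmentError):
            AlignmentBlock(5, 5, 100, 100)


class TestFixtureAligner:
    def test_exact_slice_single_block(self, fixture_bundle):
        stores = fixture_bundle["stores"]
        chrom = stores.sequences.get_sequence("chrT")
        target = chrom[4500:4560]
        hits = fixture_align(target, stores)
        top = hits[0]
        assert top.strand == "+" and len(top.blocks) == 1
        b = top.blocks[0]
        assert (b.ref_start, b.ref_end, b.query_start, b.query_end) == (4500, 4560, 0, 60)

    def test_reverse_complement_slice_minus_hit(self, fixture_bundle):
        stores = fixture_bundle["stores"]
        chrom = stores.sequences.get_sequence("chrT")
        hits = fixture_align(revcomp(chrom[4500:4560]), stores)
        assert hits[0].strand == "-"
        assert hits[0].blocks[0].ref_start == 4500

    def test_spliced_target_block_bounds_match_exon_table(self, fixture_bundle):
        stores = fixture_bundle["stores"]
        rec = next(r for r in stores.transcripts.records if r.mane_status == "MANE Select")
        chrom = stores.sequences.get_sequence("chrT")
        spliced = "".join(chrom[s:e] for s, e in rec.exons[:2])
        hits = fixture_align(spliced, stores)
        top = hits[0]
        assert [(b.ref_start, b.ref_end) for b in top.blocks] == list(rec.exons[:2])

    def test_no_placement_returns_empty(self, fixture_bundle):
        assert fixture_align("TTAACCGGTTAACCGGTTAACCGGAATTGGCC" * 3,
                             fixture_bundle["stores"]) in ([],)

    def test_splice_extraction_reproduces_target(self, fixture_bundle):
        """Extracting the reference under each block and splicing gives back
        the aligned part of the target exactly (mismatch rate 0 here)."""
        stores = fixture_bundle["stores"]
        chrom = stores.sequences.get_sequence("chrT")
        rec = next(r for r in stores.transcripts.records if r.mane_status == "MANE Select")
        target = "".join(chrom[s:e] for s, e in rec.exons)
        top = fixture_align(target, stores)[0]
        rebuilt = "".join(chrom[b.ref_start:b.ref_end] for b in top.blocks)
        assert rebuilt == target
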