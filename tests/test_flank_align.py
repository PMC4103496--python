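import numpy as np
import pytest
from Bio import Align

from flanklift.flank_align import (
    HSP,
    AlignParams,
    TargetSeedIndex,
    UniqueStatus,
    filter_hsps,
    find_hsps,
    hsp_identity,
    revcomp,
    smith_waterman,
    unique_hsp,
)
from flanklift.genome_io import FlankQuery, GenomeSequence

from conftest import mutate_sequence, random_sequence


def _query(rng, n=201):
    return random_sequence(rng, n)


def _flank(seq, offset=100):
    return FlankQuery("src", offset + 1, seq, offset, False, False)


def _mk_hsp(q_span, matches, mismatches, gaps, t_start=0, strand="+"):
    qs, qe = q_span
    return HSP(
        query_start=qs,
        query_end=qe,
        target_contig="t",
        target_start=t_start,
        target_end=t_start + (qe - qs),
        strand=strand,
        blocks=((qs, t_start, qe - qs),),
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        score=matches - mismatches - gaps,
    )


class TestSmithWaterman:
    def test_exact_single_copy(self):
        rng = np.random.default_rng(1)
        q = _query(rng)
        t = random_sequence(rng, 300) + q + random_sequence(rng, 300)
        [h] = smith_waterman(q, t, AlignParams())
        assert (h.matches, h.mismatches, h.gap_columns) == (201, 0, 0)
        assert h.identity == 1.0
        assert h.strand == "+"
        assert (h.target_start, h.target_end) == (300, 501)

    def test_single_substitution(self):
        rng = np.random.default_rng(2)
        q = _query(rng)
        mutated = q[:80] + ("A" if q[80] != "A" else "C") + q[81:]
        t = random_sequence(rng, 100) + mutated + random_sequence(rng, 100)
        [h] = smith_waterman(q, t, AlignParams())
        assert (h.matches, h.mismatches, h.gap_columns) == (200, 1, 0)
        assert h.identity == pytest.approx(200 / 201)

    def test_single_deletion_gap_inclusive_identity(self):
        # one target base deleted: the gapped alignment keeps all 7 matches
        [h] = smith_waterman("ACGTACGT", "ACGACGT", AlignParams(min_score=1))[:1]
        assert (h.matches, h.gap_columns) == (7, 1)
        assert h.identity == pytest.approx(7 / 8)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT", AlignParams())

    def test_score_matches_biopython_local_aligner(self):
        """The DP engine's best local score equals Biopython's
        PairwiseAligner under the same affine-gap scoring."""
        params = AlignParams(min_score=5)
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = params.match_score
        aligner.mismatch_score = -params.mismatch_penalty
        aligner.open_gap_score = -(params.gap_open_penalty + params.gap_extend_penalty)
        aligner.extend_gap_score = -params.gap_extend_penalty
        rng = np.random.default_rng(9)
        for _ in range(30):
            q = random_sequence(rng, 80)
            t = (
                random_sequence(rng, 100)
                + mutate_sequence(rng, q, sub_rate=0.05, indel_rate=0.01)
                + random_sequence(rng, 100)
            )
            hsps = smith_waterman(q, t, params)
            assert hsps, "homologous copy must be found"
            assert hsps[0].score == aligner.score(t, q)


class TestHspIdentity:
    @pytest.mark.parametrize(
        "m,mm,g,expected",
        [(201, 0, 0, 1.0), (180, 20, 0, 0.90), (180, 20, 1, 180 / 201)],
    )
    def test_gap_inclusive_arithmetic(self, m, mm, g, expected):
        h = _mk_hsp((0, m + mm), m, mm, g)
        assert hsp_identity(h) == pytest.approx(expected)

    def test_boundary_is_inclusive_in_filter(self):
        q = _flank("A" * 201)
        passing = _mk_hsp((0, 200), 180, 20, 0)  # identity exactly 0.90
        failing = _mk_hsp((0, 200), 180, 19, 1)  # 180/200 on columns, but
        failing = _mk_hsp((0, 201), 180, 20, 1)  # 180/201 < 0.90
        assert filter_hsps([passing], q, AlignParams()) == [passing]
        assert filter_hsps([failing], q, AlignParams()) == []


class TestFilterHsps:
    def test_containment_and_coverage_boundaries(self):
        q = _flank("A" * 201)
        params = AlignParams()
        covering = _mk_hsp((0, 101), 101, 0, 0)  # 101/201 = 50.2% and contains 100
        assert filter_hsps([covering], q, params) == [covering]
        not_containing = _mk_hsp((0, 100), 100, 0, 0)  # variant at 100 excluded
        assert filter_hsps([not_containing], q, params) == []
        short = _mk_hsp((50, 150), 100, 0, 0)  # 100/201 = 49.75% < 50%
        assert filter_hsps([short], q, params) == []

    def test_truncated_flank_keeps_nominal_denominator(self):
        # A 101-base flank at a contig end: full-length alignment barely passes.
        q = FlankQuery("src", 1, "A" * 101, 0, True, False)
        params = AlignParams()
        full = _mk_hsp((0, 101), 101, 0, 0)
        assert filter_hsps([full], q, params) == [full]
        clipped = _mk_hsp((0, 100), 100, 0, 0)
        assert filter_hsps([clipped], q, params) == []


class TestUniqueHsp:
    def test_zero_one_many(self):
        h1 = _mk_hsp((0, 201), 201, 0, 0)
        h2 = _mk_hsp((0, 201), 201, 0, 0, t_start=500)
        assert unique_hsp([]) is UniqueStatus.NO_HSP
        assert unique_hsp([h1]) == h1
        assert unique_hsp([h1, h2]) is UniqueStatus.MULTIPLE_HSP


class TestFindHsps:
    def test_matches_oracle_on_verbatim_copy(self):
        rng = np.random.default_rng(4)
        q = _query(rng)
        t = random_sequence(rng, 400) + q + random_sequence(rng, 400)
        genome = GenomeSequence({"c": t})
        seeded = find_hsps(_flank(q), genome, AlignParams())
        oracle = smith_waterman(q, t, AlignParams(), contig="c")
        assert seeded == oracle
        assert len(seeded) == 1

    def test_reverse_complement_copy_found_on_minus_strand(self):
        rng = np.random.default_rng(5)
        q = _query(rng)
        t = random_sequence(rng, 250) + revcomp(q) + random_sequence(rng, 250)
        [h] = find_hsps(_flank(q), GenomeSequence({"c": t}), AlignParams())
        assert h.strand == "-"
        assert h.identity == 1.0
        assert (h.target_start, h.target_end) == (250, 451)

    def test_two_paralogous_copies_both_reported(self):
        rng = np.random.default_rng(6)
        q = _query(rng)
        t = (
            random_sequence(rng, 200)
            + q
            + random_sequence(rng, 300)
            + mutate_sequence(rng, q, sub_rate=0.03)
            + random_sequence(rng, 200)
        )
        hsps = find_hsps(_flank(q), GenomeSequence({"c": t}), AlignParams())
        assert len(hsps) == 2
        assert unique_hsp(filter_hsps(hsps, _flank(q), AlignParams())) is (
            UniqueStatus.MULTIPLE_HSP
        )

    def test_no_homology_returns_empty(self):
        rng = np.random.default_rng(7)
        q = _query(rng)
        t = random_sequence(rng, 2000)
        assert find_hsps(_flank(q), GenomeSequence({"c": t}), AlignParams()) == []

    def test_strand_symmetry_under_target_reversal(self):
        """HSPs against the reverse-complemented genome appear at mirrored
        coordinates with flipped strand."""
        rng = np.random.default_rng(8)
        q = _query(rng)
        t = (
            random_sequence(rng, 150)
            + mutate_sequence(rng, q, sub_rate=0.02)
            + random_sequence(rng, 150)
        )
        L = len(t)
        params = AlignParams()
        fwd = find_hsps(_flank(q), GenomeSequence({"c": t}), params)
        rev = find_hsps(_flank(q), GenomeSequence({"c": revcomp(t)}), params)
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (L - h.target_end, L - h.target_start, flip[h.strand], h.score)
            for h in rev
        }
        assert {
            (h.target_start, h.target_end, h.strand, h.score) for h in fwd
        } == mirrored

    def test_prebuilt_index_reused(self):
        rng = np.random.default_rng(10)
        q = _query(rng)
        t = random_sequence(rng, 100) + q + random_sequence(rng, 100)
        genome = GenomeSequence({"c": t})
        params = AlignParams()
        index = TargetSeedIndex(genome, params.seed_k)
        assert find_hsps(_flank(q), genome, params, index) == find_hsps(
            _flank(q), genome, params
        )
        with pytest.raises(ValueError, match="seed_k"):
            find_hsps(_flank(q), genome, AlignParams(seed_k=13), index)


class TestHspConsistency:
    def test_blocks_account_for_all_aligned_columns(self):
        """matches + mismatches equals the total block length, and blocks are
        strictly increasing on the query, for real alignments."""
        rng = np.random.default_rng(12)
        params = AlignParams(min_score=20)
        for _ in range(20):
            q = random_sequence(rng, 120)
            t = (
                random_sequence(rng, 60)
                + mutate_sequence(rng, q, sub_rate=0.05, indel_rate=0.02)
                + random_sequence(rng, 60)
            )
            for h in smith_waterman(q, t, params):
                assert h.matches + h.mismatches == sum(b[2] for b in h.blocks)
                q_offsets = [b[0] for b in h.blocks]
                assert q_offsets == sorted(q_offsets)
                assert h.blocks[0][0] == h.query_start
                assert h.blocks[-1][0] + h.blocks[-1][2] == h.query_end
                span = {h.target_contig: (h.target_start, h.target_end)}
                for _, bt, bl in h.blocks:
                    assert h.target_start <= bt and bt + bl <= h.target_end
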