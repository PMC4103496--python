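import warnings

import numpy as np
import pytest

from flanklift.flank_align import HSP, AlignParams
from flanklift.genome_io import GenomeSequence
from flanklift.liftover import (
    TranslationRecord,
    TranslationStatus,
    lift_variants,
    liftover_variant,
    project_position,
    read_translation_table,
    status_counts,
    translate_alleles,
    write_translation_table,
    write_translation_vcf,
)
from flanklift.flank_align import revcomp
from flanklift.variant_io import GenotypeCall, VariantRecord, read_vcf

from conftest import random_sequence


def _hsp(blocks, strand="+", contig="t"):
    qs = blocks[0][0]
    qe = blocks[-1][0] + blocks[-1][2]
    t_lo = min(b[1] for b in blocks)
    t_hi = max(b[1] + b[2] for b in blocks)
    n = sum(b[2] for b in blocks)
    return HSP(qs, qe, contig, t_lo, t_hi, strand, tuple(blocks), n, 0, 0, n)


class TestProjectPosition:
    def test_plus_strand_offset_arithmetic(self):
        h = _hsp([(50, 1000, 130)])
        assert project_position(h, 100) == 1050

    def test_minus_strand_mapping_decreases(self):
        # ungapped - strand HSP: query [0,10) <-> target [200,210)
        h = _hsp([(0, 200, 10)], strand="-")
        assert project_position(h, 3) == 206
        # enumerate all columns: strictly decreasing in target
        positions = [project_position(h, qp) for qp in range(10)]
        assert positions == list(range(209, 199, -1))

    def test_target_side_gap_routes_to_none(self):
        # blocks skip query positions 3-4 (consumed by a target-side gap)
        h = _hsp([(0, 100, 3), (5, 103, 5)])
        assert project_position(h, 3) is None
        assert project_position(h, 4) is None
        assert project_position(h, 5) == 103

    def test_outside_span_is_an_error(self):
        h = _hsp([(10, 0, 5)])
        with pytest.raises(ValueError, match="outside"):
            project_position(h, 9)

    def test_monotonic_within_hsp(self):
        h_plus = _hsp([(0, 100, 3), (5, 105, 5)])
        mapped = [project_position(h_plus, q) for q in range(h_plus.query_start, h_plus.query_end)]
        aligned = [m for m in mapped if m is not None]
        assert aligned == sorted(aligned) and len(set(aligned)) == len(aligned)


class TestTranslateAlleles:
    @pytest.mark.parametrize(
        "pair,strand,expected",
        [
            (("A", "G"), "+", ("A", "G")),
            (("A", "G"), "-", ("C", "T")),
            (("C", "T"), "-", ("A", "G")),
        ],
    )
    def test_strand_translation(self, pair, strand, expected):
        assert translate_alleles(pair, strand) == tuple(sorted(expected))

    def test_involution_on_minus(self):
        for a in "ACGT":
            for b in "ACGT":
                pair = tuple(sorted((a, b)))
                assert translate_alleles(translate_alleles(pair, "-"), "-") == pair

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            translate_alleles(("A", "N"), "-")


def _het(contig, pos, ref, alt):
    return VariantRecord(contig, pos, ref, (alt,), GenotypeCall.of(ref, alt))


class TestLiftoverVariant:
    def setup_method(self):
        rng = np.random.default_rng(31)
        self.seq = random_sequence(rng, 4000)
        self.genome = GenomeSequence({"c1": self.seq})
        self.params = AlignParams()

    def _some_het(self, pos):
        ref = self.seq[pos - 1]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        return _het("c1", pos, ref, alt)

    def test_self_liftover_identity(self):
        for pos in (150, 2000, 3900):
            r = liftover_variant(self._some_het(pos), self.genome, self.genome, self.params)
            assert r.status is TranslationStatus.TRANSLATED
            assert (r.target_contig, r.target_pos, r.strand) == ("c1", pos, "+")
            assert r.target_ref_base == self.seq[pos - 1]

    def test_reverse_complemented_target(self):
        target = GenomeSequence({"c1": revcomp(self.seq)})
        pos = 2000
        v = self._some_het(pos)
        r = liftover_variant(v, self.genome, target, self.params)
        assert r.status is TranslationStatus.TRANSLATED
        assert r.strand == "-"
        assert r.target_pos == len(self.seq) - pos + 1
        assert r.translated_alleles == translate_alleles(v.genotype.alleles, "-")

    def test_unrelated_target_is_no_hsp(self):
        rng = np.random.default_rng(32)
        target = GenomeSequence({"c1": random_sequence(rng, 4000)})
        r = liftover_variant(self._some_het(2000), self.genome, target, self.params)
        assert r.status is TranslationStatus.NO_HSP

    def test_excluded_target_contig(self):
        target = GenomeSequence({"chrX": self.seq})
        r = liftover_variant(self._some_het(2000), self.genome, target, self.params)
        assert r.status is TranslationStatus.TARGET_EXCLUDED_CONTIG

    def test_ref_mismatch_is_flank_unavailable(self):
        pos = 2000
        ref = self.seq[pos - 1]
        wrong = "ACGT"[("ACGT".index(ref) + 2) % 4]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        v = _het("c1", pos, wrong, alt)
        r = liftover_variant(v, self.genome, self.genome, self.params)
        assert r.status is TranslationStatus.FLANK_UNAVAILABLE

    def test_translated_record_requires_all_target_fields(self):
        v = self._some_het(100)
        with pytest.raises(ValueError, match="target fields"):
            TranslationRecord(v, TranslationStatus.TRANSLATED)
        with pytest.raises(ValueError, match="target fields"):
            TranslationRecord(
                v, TranslationStatus.NO_HSP, target_contig="c1", target_pos=1,
                strand="+", target_ref_base="A", translated_alleles=("A", "G"),
            )


class TestRoundTripOnSimulatedPair(object):
    def test_a_to_b_to_a_recovers_coordinates(self, small_pair):
        """Sites lifted A->B and then back B->A land on their original
        source coordinate whenever both directions translate."""
        ga, gb = small_pair["genome_a"], small_pair["genome_b"]
        hets = small_pair["hets_a"][:40]
        fwd = list(lift_variants(hets, ga, gb))
        translated = [r for r in fwd if r.status is TranslationStatus.TRANSLATED]
        assert translated, "nothing translated on the simulated pair"
        back_in = [
            VariantRecord(
                r.target_contig, r.target_pos, r.target_ref_base,
                tuple(sorted(set(r.translated_alleles) - {r.target_ref_base})),
                GenotypeCall.of(*r.translated_alleles),
            )
            for r in translated
            if r.target_ref_base in r.translated_alleles
        ]
        back = list(lift_variants(back_in, gb, ga))
        recovered = 0
        for orig, rec in zip(
            [r for r in translated if r.target_ref_base in r.translated_alleles], back
        ):
            if rec.status is TranslationStatus.TRANSLATED:
                assert (rec.target_contig, rec.target_pos) == (
                    orig.source.contig, orig.source.pos,
                )
                recovered += 1
        assert recovered > 0

    def test_status_counts_conserve_input(self, small_pair):
        results = list(
            lift_variants(
                small_pair["hets_a"][:30], small_pair["genome_a"], small_pair["genome_b"]
            )
        )
        counts = status_counts(results)
        assert sum(counts.values()) == len(results) == 30


class TestTranslationOutputs:
    def _records(self):
        v1 = _het("c1", 10, "A", "T")
        r1 = TranslationRecord(
            v1, TranslationStatus.TRANSLATED, target_contig="t1", target_pos=5,
            strand="+", target_ref_base="C", translated_alleles=("A", "T"),
        )
        v2 = _het("c1", 20, "C", "T")
        r2 = TranslationRecord(
            v2, TranslationStatus.TRANSLATED, target_contig="t1", target_pos=9,
            strand="+", target_ref_base="C", translated_alleles=("C", "T"),
        )
        v3 = _het("c1", 30, "G", "A")
        r3 = TranslationRecord(v3, TranslationStatus.NO_HSP)
        return [r1, r2, r3]

    def test_translation_vcf_ref_alt_semantics(self, tmp_path):
        path = tmp_path / "t.vcf"
        write_translation_vcf(self._records(), path, {"t1": 100})
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 2
        f1 = lines[0].split("\t")
        assert (f1[0], f1[1], f1[3], f1[4]) == ("t1", "5", "C", "A,T")
        f2 = lines[1].split("\t")
        assert (f2[3], f2[4]) == ("C", "T")
        back = list(read_vcf(path))
        assert back[1].genotype == GenotypeCall.of("C", "T")

    def test_collision_flagged(self, tmp_path):
        r1, r2, _ = self._records()
        r2 = TranslationRecord(
            r2.source, TranslationStatus.TRANSLATED, target_contig="t1",
            target_pos=5, strand="+", target_ref_base="C",
            translated_alleles=("C", "T"),
        )
        path = tmp_path / "t.vcf"
        with pytest.warns(UserWarning, match="multiple source variants"):
            write_translation_vcf([r1, r2], path, {"t1": 100})
        assert path.read_text().count("COLLIDE") >= 3  # header + 2 records

    def test_empty_translation_set(self, tmp_path):
        path = tmp_path / "t.vcf"
        write_translation_vcf([], path, {"t1": 100})
        assert all(l.startswith("#") for l in path.read_text().splitlines())

    def test_table_round_trip(self, tmp_path):
        path = tmp_path / "t.tsv"
        records = self._records()
        write_translation_table(records, path)
        back = read_translation_table(path)
        assert len(back) == len(records)
        for orig, rec in zip(records, back):
            assert rec.status is orig.status
            assert rec.source.contig == orig.source.contig
            assert rec.source.pos == orig.source.pos
            assert rec.target_pos == orig.target_pos
            assert rec.translated_alleles == orig.translated_alleles
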