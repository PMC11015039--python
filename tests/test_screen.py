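"""Saturation-mutagenesis SNV generation, PWM scoring and annotation checks."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repeatgain.errors import CoordinateError, EmptyInputError
from repeatgain.screen import (
    SNV,
    PwmSpliceScorer,
    SpliceJunction,
    check_exon_annotation,
    dataset_overlap,
    generate_saturation_snvs,
    revcomp,
    score_variants,
    write_snv_vcf,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture
def seq(rng):
    return random_seq(rng, 400)


class TestSaturationCounts:
    def test_one_junction_full_flanks_gives_300(self, seq):
        j = SpliceJunction("chr1", 200, "donor")
        assert len(generate_saturation_snvs(seq, [j])) == 300

    def test_two_disjoint_junctions_give_600(self, seq):
        js = [SpliceJunction("chr1", 120, "donor"), SpliceJunction("chr1", 300, "acceptor")]
        assert len(generate_saturation_snvs(seq, js)) == 600

    def test_edge_truncated_junction(self, seq):
        # 30 exonic nt before the boundary -> 3 * (30 + 50) SNVs
        j = SpliceJunction("chr1", 31, "donor")
        assert len(generate_saturation_snvs(seq, [j])) == 240

    def test_overlapping_windows_deduplicated(self, seq):
        js = [SpliceJunction("chr1", 200, "donor"), SpliceJunction("chr1", 210, "acceptor")]
        snvs = generate_saturation_snvs(seq, js)
        assert len(snvs) == len({(s.position, s.alt) for s in snvs})

    def test_junction_outside_sequence_rejected(self, seq):
        with pytest.raises(CoordinateError):
            generate_saturation_snvs(seq, [SpliceJunction("chr1", 1000, "donor")])

    @given(pos=st.integers(1, 400), flank=st.integers(1, 60),
           side=st.sampled_from(["donor", "acceptor"]))
    def test_count_matches_brute_force_enumeration(self, pos, flank, side):
        rng = np.random.default_rng(pos * 1000 + flank)
        s = random_seq(rng, 400)
        j = SpliceJunction("chr1", pos, side)
        got = generate_saturation_snvs(s, [j], flank=flank)
        b = j.boundary_index()
        covered = [p for p in range(1, 401) if b - flank <= p - 1 <= b + flank - 1]
        assert len(got) == 3 * len(covered)
        assert all(s[v.position - 1] == v.ref for v in got)


class TestPwmScorer:
    def test_consensus_donor_scores_near_one(self):
        # CAG|GTAAGT: best base at every donor position
        seq = "A" * 50 + "CAGGTAAGT" + "A" * 50
        j = SpliceJunction("chr1", 54, "donor")  # G of GT is position 54
        score = PwmSpliceScorer().score(seq, j)
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_breaking_the_gt_dinucleotide_drops_the_score(self):
        seq = "A" * 50 + "CAGGTAAGT" + "A" * 50
        j = SpliceJunction("chr1", 54, "donor")
        scorer = PwmSpliceScorer()
        broken = seq[:53] + "C" + seq[54:]
        assert scorer.score(broken, j) < scorer.score(seq, j) - 0.2

    def test_minus_strand_scores_reverse_complement(self):
        seq = "A" * 50 + "CAGGTAAGT" + "A" * 50
        j = SpliceJunction("chr1", 54, "donor")
        rc_seq = revcomp(seq)
        # same biological junction seen from the minus strand:
        # first intronic base at position len - 54 + 1
        j_rc = SpliceJunction("chr1", len(seq) - 53, "donor", strand="-")
        scorer = PwmSpliceScorer()
        assert scorer.score(rc_seq, j_rc) == pytest.approx(scorer.score(seq, j))

    def test_scores_bounded_in_unit_interval(self, rng):
        scorer = PwmSpliceScorer()
        for _ in range(50):
            s = random_seq(rng, 120)
            for side, pos in (("donor", 60), ("acceptor", 60)):
                assert 0.0 <= scorer.score(s, SpliceJunction("c", pos, side)) <= 1.0


class TestScoreVariants:
    def test_one_record_per_input_in_order(self, seq):
        j = SpliceJunction("chr1", 200, "donor")
        snvs = generate_saturation_snvs(seq, [j])
        deltas = score_variants(PwmSpliceScorer(), snvs, seq, [j])
        assert len(deltas) == len(snvs)
        assert [d.snv for d in deltas] == snvs

    def test_consensus_creating_mutation_is_sensitizing(self):
        # weak donor CAGGTAAGG -> consensus CAGGTAAGT
        seq = "C" * 50 + "CAGGTAAGG" + "C" * 50
        j = SpliceJunction("chr1", 54, "donor")
        snv = SNV("chr1", 59, ref="G", alt="T")
        (d,) = score_variants(PwmSpliceScorer(), [snv], seq, [j], threshold=0.01)
        assert d.delta > 0
        assert d.classification == "sensitizing"

    def test_reverse_mutation_negates_delta(self, seq):
        j = SpliceJunction("chr1", 200, "donor")
        snvs = generate_saturation_snvs(seq, [j])[:30]
        scorer = PwmSpliceScorer()
        fwd = score_variants(scorer, snvs, seq, [j])
        for d in fwd:
            mutated = (
                seq[: d.snv.position - 1] + d.snv.alt + seq[d.snv.position :]
            )
            back = SNV(d.snv.seq_id, d.snv.position, ref=d.snv.alt, alt=d.snv.ref)
            (rev,) = score_variants(scorer, [back], mutated, [j])
            assert rev.delta == pytest.approx(-d.delta, abs=1e-12)

    def test_ref_mismatch_recorded_not_raised(self, seq):
        j = SpliceJunction("chr1", 200, "donor")
        pos = 210
        wrong_ref = next(b for b in "ACGT" if b != seq[pos - 1])
        alt = next(b for b in "ACGT" if b not in (wrong_ref, seq[pos - 1]))
        bad = SNV("chr1", pos, ref=wrong_ref, alt=alt)
        good = generate_saturation_snvs(seq, [j])[0]
        deltas = score_variants(PwmSpliceScorer(), [bad, good], seq, [j])
        assert deltas[0].classification == "error"
        assert math.isnan(deltas[0].delta)
        assert deltas[1].classification != "error"

    def test_frequency_classes(self, seq):
        j = SpliceJunction("chr1", 200, "donor")
        base = generate_saturation_snvs(seq, [j])[0]
        common = SNV(base.seq_id, base.position, base.ref, base.alt, allele_frequency=0.19)
        rare = SNV(base.seq_id, base.position, base.ref, base.alt, allele_frequency=0.0006)
        out = score_variants(PwmSpliceScorer(), [common, rare, base], seq, [j])
        assert [d.frequency_class for d in out] == ["common", "rare", "unknown"]


GFF = """##gff-version 3
chr2\tsrc\tgene\t50\t500\t.\t+\t.\tID=g1
chr2\tsrc\texon\t101\t200\t.\t+\t.\tID=e1;Parent=g1
chr2\tsrc\texon\t300\t400\t.\t+\t.\tID=e2;Parent=g1
"""


class TestExonAnnotation:
    @pytest.fixture
    def gff3(self, tmp_path):
        p = tmp_path / "anno.gff3"
        p.write_text(GFF)
        return p

    def test_within_tolerance_is_annotated(self, gff3):
        assert check_exon_annotation(("chr2", 100, 200), gff3, tolerance=1) == "annotated"

    def test_beyond_tolerance_is_novel(self, gff3):
        assert check_exon_annotation(("chr2", 103, 200), gff3, tolerance=1) == "novel"

    def test_exact_match_with_zero_tolerance(self, gff3):
        assert check_exon_annotation(("chr2", 101, 200), gff3, tolerance=0) == "annotated"

    def test_wrong_sequence_is_novel(self, gff3):
        assert check_exon_annotation(("chr3", 101, 200), gff3) == "novel"

    def test_non_exon_features_ignored(self, gff3):
        assert check_exon_annotation(("chr2", 50, 500), gff3) == "novel"


class TestDatasetOverlap:
    def test_row_normalized_counting(self):
        mat = dataset_overlap({"A": ["g1", "g2", "g3", "g4"], "B": ["g1", "g2"]})
        assert mat.loc["A", "B"] == 0.5
        assert mat.loc["B", "A"] == 1.0

    def test_unit_diagonal_and_bounds(self):
        mat = dataset_overlap({"A": ["x", "y"], "B": ["y", "z"], "C": ["q"]})
        assert np.allclose(np.diag(mat), 1.0)
        assert ((mat.values >= 0) & (mat.values <= 1)).all()

    def test_disjoint_sets_zero_off_diagonal(self):
        mat = dataset_overlap({"A": ["a"], "B": ["b"]})
        assert mat.loc["A", "B"] == 0 and mat.loc["B", "A"] == 0

    def test_identical_sets_all_ones(self):
        mat = dataset_overlap({"A": ["a", "b"], "B": ["a", "b"]})
        assert (mat.values == 1).all()

    def test_empty_set_rejected(self):
        with pytest.raises(EmptyInputError):
            dataset_overlap({"A": [], "B": ["x"]})


def test_vcf_round_trip_fields(tmp_path, seq):
    j = SpliceJunction("chr1", 200, "donor")
    snvs = generate_saturation_snvs(seq, [j])[:10]
    deltas = score_variants(PwmSpliceScorer(), snvs, seq, [j])
    path = write_snv_vcf(deltas, tmp_path / "out.vcf")
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == 10
    chrom, pos, _, ref, alt, _, _, info = lines[0].split("\t")
    assert (chrom, int(pos), ref, alt) == (
        snvs[0].seq_id,
        snvs[0].position,
        snvs[0].ref,
        snvs[0].alt,
    )
    assert "DELTA=" in info and "CLS=" in info
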