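import numpy as np
import pytest

from circdiv import circ_detect
from circdiv.circ_detect import (
    annotate,
    call_junctions,
    cigar_reference_span,
    extract_split_candidates,
    merge_cohort,
    require_mate_in_circle,
)
from circdiv.io_formats import AlignmentRecord, RegionString

from conftest import make_junction_fragment


def _record(**kw):
    base = dict(
        read_name="r", chrom="chr1", pos=1000, strand="+", cigar="30M70S",
        is_first_in_pair=True, mate_chrom="chr1", mate_pos=600,
        sa_entries=(("chr1", 500, "+", "30S70M"),), mapq=60,
    )
    base.update(kw)
    return AlignmentRecord(**base)


def _mate(name="r", pos=600, chrom="chr1"):
    return AlignmentRecord(
        read_name=name, chrom=chrom, pos=pos, strand="-", cigar="100M",
        is_first_in_pair=False, mate_chrom=chrom, mate_pos=1000, sa_entries=(), mapq=60,
    )


class TestExtractSplitCandidates:
    def test_hand_computed_breakpoints_from_cigars(self):
        """Primary 30M70S at 1000 + SA 30S70M at 500 -> circle chr1:500-1029."""
        ev = extract_split_candidates([_record(), _mate()])
        assert len(ev) == 1
        assert ev[0].circle_start == 500
        assert ev[0].circle_end == 1029
        assert ev[0].upstream_segment == (1000, 1029)
        assert ev[0].downstream_segment == (500, 569)
        assert ev[0].mate_span == (600, 699)

    @pytest.mark.parametrize(
        "tweak",
        [
            {"sa_entries": (("chr1", 500, "+", "30S70M"), ("chr1", 900, "+", "50S50M"))},
            {"sa_entries": (("chr2", 500, "+", "30S70M"),)},
            {"sa_entries": (("chr1", 500, "-", "30S70M"),)},
            {"sa_entries": ()},
        ],
        ids=["two_sa_entries", "other_chromosome", "other_strand", "no_sa"],
    )
    def test_rejection_rules(self, tweak):
        assert extract_split_candidates([_record(**tweak), _mate()]) == []

    def test_forward_splice_orientation_rejected(self):
        """Read prefix mapping upstream of its suffix is a linear splice."""
        rec = _record(pos=500, cigar="30M70S", sa_entries=(("chr1", 1000, "+", "30S70M"),))
        diag = circ_detect.DetectDiagnostics()
        assert extract_split_candidates([rec, _mate()], diagnostics=diag) == []
        assert diag.not_backsplice == 1

    def test_unpaired_read_tallied(self):
        rec = _record(is_paired=False)
        diag = circ_detect.DetectDiagnostics()
        assert extract_split_candidates([rec], diagnostics=diag) == []
        assert diag.unpaired == 1

    def test_cigar_span_with_indels(self):
        # 10M2D5M3I10M consumes 10+2+5+10 = 27 reference bases
        assert cigar_reference_span(100, "10M2D5M3I10M") == (100, 126)


class TestMateContainment:
    def _ev(self, mate_span):
        return circ_detect.SplitReadEvidence(
            fragment_name="f", chrom="chr1", strand="+",
            upstream_segment=(1000, 1029), downstream_segment=(500, 569),
            mate_span=mate_span,
        )

    @pytest.mark.parametrize(
        "span,kept_full,kept_overlap",
        [
            ((600, 699), True, True),
            ((1100, 1199), False, False),
            ((995, 1094), False, True),  # straddles the circle end (1029)
            ((500, 599), True, True),  # flush with circle start
        ],
    )
    def test_containment_rules(self, span, kept_full, kept_overlap):
        ev = [self._ev(span)]
        assert bool(require_mate_in_circle(ev, "full")) is kept_full
        assert bool(require_mate_in_circle(ev, "overlap")) is kept_overlap


class TestCallJunctions:
    def _evidence(self, n_fragments, reps=1):
        out = []
        for i in range(n_fragments):
            for _ in range(reps):
                out.append(
                    circ_detect.SplitReadEvidence(
                        fragment_name=f"f{i}", chrom="chr1", strand="+",
                        upstream_segment=(1000, 1029), downstream_segment=(500, 569),
                        mate_span=(600, 699),
                    )
                )
        return out

    def test_threshold_boundary(self):
        assert len(call_junctions(self._evidence(5))) == 1
        assert call_junctions(self._evidence(5))[0].support == 5
        assert call_junctions(self._evidence(4)) == []

    def test_fragments_not_alignments_counted(self):
        # 5 fragments, 2 of them contributing two alignment lines each
        ev = self._evidence(5) + self._evidence(2)
        (junc,) = call_junctions(ev)
        assert junc.support == 5

    def test_invalid_min_reads(self):
        with pytest.raises(ValueError):
            call_junctions([], min_reads=0)

    def test_order_invariance_and_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        ev = self._evidence(8) + [
            circ_detect.SplitReadEvidence(
                fragment_name=f"g{i}", chrom="chr1", strand="+",
                upstream_segment=(3000, 3049), downstream_segment=(2500, 2549),
                mate_span=(2600, 2699),
            )
            for i in range(3)
        ]
        shuffled = list(ev)
        rng.shuffle(shuffled)
        a = call_junctions(ev, min_reads=1)
        b = call_junctions(shuffled, min_reads=1)
        assert [(str(j.region), j.support) for j in a] == [(str(j.region), j.support) for j in b]
        strict = {str(j.region) for j in call_junctions(ev, min_reads=5)}
        loose = {str(j.region) for j in call_junctions(ev, min_reads=1)}
        assert strict <= loose and len(loose) == 2 and len(strict) == 1


class TestAnnotate:
    def _junction(self, chrom, start, end, strand="+"):
        return circ_detect.BackspliceJunction(RegionString(chrom, start, end), strand, 7, frozenset())

    def test_hipk3_exact_match(self, fixture_genes):
        (circ,) = annotate([self._junction("chr11", 33286413, 33287512)], fixture_genes)
        assert circ.gene_name == "HIPK3" and circ.exon_span == "2"

    def test_smarca5_multi_exon_span(self, fixture_genes):
        (circ,) = annotate([self._junction("chr4", 143543509, 143543973)], fixture_genes)
        assert circ.gene_name == "SMARCA5" and circ.exon_span == "15-16"

    def test_off_by_one_is_novel(self, fixture_genes):
        (circ,) = annotate([self._junction("chr11", 33286414, 33287512)], fixture_genes)
        assert circ.gene_id == circ_detect.NOVEL

    def test_fgd6_region_is_novel(self, fixture_genes):
        """A genuine circle whose boundaries match no annotated exon is kept as NOVEL."""
        (circ,) = annotate([self._junction("chr12", 95208843, 95211268)], fixture_genes)
        assert circ.gene_id == circ_detect.NOVEL

    def test_wrong_strand_not_assigned(self, fixture_genes):
        (circ,) = annotate([self._junction("chr11", 33286413, 33287512, strand="-")], fixture_genes)
        assert circ.gene_id == circ_detect.NOVEL


class TestMergeCohort:
    def _circ(self, start, end, support=6):
        j = circ_detect.BackspliceJunction(RegionString("chr1", start, end), "+", support, frozenset())
        return circ_detect.CircRNA(junction=j)

    def test_presence_counting(self):
        per_sample = {
            "s1": [self._circ(500, 1029)],
            "s2": [self._circ(500, 1029)],
            "s3": [self._circ(500, 1029)],
            "s4": [],
            "s5": [],
        }
        catalog, matrix = merge_cohort(per_sample)
        assert matrix.shape == (1, 5)
        assert (matrix.loc["chr1:500-1029"] > 0).sum() == 3

    def test_exact_identity_of_regions(self):
        catalog, matrix = merge_cohort({"s1": [self._circ(500, 1029), self._circ(500, 1030)]})
        assert len(matrix) == 2

    def test_duplicate_sample_ids_impossible_via_mapping(self):
        with pytest.raises(ValueError):
            merge_cohort({})

    def test_cohort_recovers_planted_regions(self, small_cohort, detected):
        catalog, matrix = detected
        truth = small_cohort.truth
        expected = set(truth.presence.columns[truth.presence.any(axis=0)])
        assert set(matrix.index) == expected


class TestPerfectRecovery:
    def test_precision_recall_one_on_synthetic_fragments(self):
        """Planted junctions with >=5 fragments are recovered exactly."""
        records = []
        planted = {("chr1", 500, 1029): 6, ("chr1", 2500, 3049): 5, ("chr1", 5000, 5500): 4}
        i = 0
        for (chrom, start, end), k in planted.items():
            for _ in range(k):
                records += make_junction_fragment(f"f{i}", chrom, start, end)
                i += 1
        ev = require_mate_in_circle(extract_split_candidates(records))
        called = {(j.region.chrom, j.region.start, j.region.end) for j in call_junctions(ev)}
        assert called == {k for k, v in planted.items() if v >= 5}

    def test_support_invariant_to_duplicate_lines(self):
        records = make_junction_fragment("f0", "chr1", 500, 1029)
        ev = require_mate_in_circle(extract_split_candidates(records * 3))
        (junc,) = call_junctions(ev, min_reads=1)
        assert junc.support == 1
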