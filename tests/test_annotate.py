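"""Structural annotation: LTR pairs, copy classes, junctions, IN-CTD, CHD."""
import numpy as np
import pytest

from retrotarget.align import revcomp
from retrotarget.annotate import (
    ChdProfile, annotate_integrase, classify_copy, classify_family,
    classify_junction, detect_chd, detect_ltr_pair, finalize_nonltr_label,
)
from retrotarget.intervals import ConsensusElement, GenomicInterval
from retrotarget.scan import CopyCall
from retrotarget.simulate import build_ltr_consensus, reverse_translate


def _copy(coverage, start=10_000, end=None, strand="+"):
    length = sum(e - s for s, e in coverage)
    end = end if end is not None else start + length
    return CopyCall(id="x#1", family="x", mean_identity=99.0, score=500.0,
                    location=GenomicInterval("c", start, end, strand),
                    consensus_coverage=list(coverage))


@pytest.fixture(scope="module")
def ltr_element():
    rng = np.random.default_rng(13)
    ltr = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    prot = "".join("ACDEFGHIKLMNQRSTVW"[i] for i in rng.integers(0, 18, 999))
    return build_ltr_consensus("el", ltr, "AT" + "TGGCGACATCGTCTTTC",
                               reverse_translate(prot) + "TAA")


class TestDetectLtrPair:
    def test_identical_terminal_repeats_found_exactly(self, ltr_element):
        pair = detect_ltr_pair(ltr_element)
        L = ltr_element.length
        assert pair.left_span == (0, 300)
        assert pair.right_span == (L - 300, L)
        assert pair.identity == 1.0

    def test_substituted_right_ltr_identity(self, ltr_element):
        seq = list(ltr_element.sequence)
        L = len(seq)
        for off in (50, 150, 250):  # 3 substitutions in the right LTR
            pos = L - 300 + off
            seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        mutated = ConsensusElement(name="m", sequence="".join(seq),
                                   element_class="LTR")
        pair = detect_ltr_pair(mutated)
        assert pair.left_span == (0, 300)
        assert abs(pair.identity - 297 / 300) < 1e-9

    def test_non_ltr_element_gives_none(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        el = ConsensusElement(name="n", sequence=seq, element_class="nonLTR")
        assert detect_ltr_pair(el) is None

    def test_reverse_complement_mirrors_spans(self, ltr_element):
        pair = detect_ltr_pair(ltr_element)
        rc = ConsensusElement(name="rc", sequence=revcomp(ltr_element.sequence),
                              element_class="LTR")
        rpair = detect_ltr_pair(rc)
        L = ltr_element.length
        assert rpair.left_span == (L - pair.right_span[1], L - pair.right_span[0])
        assert rpair.right_span == (L - pair.left_span[1], L - pair.left_span[0])


class TestClassifyCopy:
    def test_solo_ltr(self, ltr_element):
        c = _copy([(0, 295)])
        assert classify_copy(c, ltr_element) == "solo_LTR"

    def test_full_length_without_genome_check(self, ltr_element):
        L = ltr_element.length
        c = _copy([(0, L)])
        assert classify_copy(c, ltr_element) == "full_length"

    def test_full_length_intact_from_genome(self, ltr_element):
        L = ltr_element.length
        genome = "T" * 5000 + ltr_element.sequence + "T" * 5000
        c = _copy([(0, L)], start=5000, end=5000 + L)
        assert classify_copy(c, ltr_element, genome) == "full_length_intact"

    def test_premature_stop_breaks_intactness(self, ltr_element):
        L = ltr_element.length
        s, e = ltr_element.orf_spans[0]
        seq = list(ltr_element.sequence)
        mid = s + ((e - s) // 2 // 3) * 3
        seq[mid: mid + 3] = "TAA"
        genome = "T" * 5000 + "".join(seq) + "T" * 5000
        c = _copy([(0, L)], start=5000, end=5000 + L)
        assert classify_copy(c, ltr_element, genome) == "full_length"

    def test_frame_breaking_indel_breaks_intactness(self, ltr_element):
        L = ltr_element.length
        s, e = ltr_element.orf_spans[0]
        seq = ltr_element.sequence
        mutated = seq[: s + 300] + seq[s + 301:]  # 1-bp deletion in the ORF
        genome = "T" * 5000 + mutated + "T" * 5000
        c = _copy([(0, L)], start=5000, end=5000 + len(mutated))
        assert classify_copy(c, ltr_element, genome) == "full_length"

    def test_in_frame_deletion_keeps_intactness(self, ltr_element):
        L = ltr_element.length
        s, e = ltr_element.orf_spans[0]
        seq = ltr_element.sequence
        mutated = seq[: s + 300] + seq[s + 303:]  # 3-bp deletion in the ORF
        genome = "T" * 5000 + mutated + "T" * 5000
        c = _copy([(0, L)], start=5000, end=5000 + len(mutated))
        assert classify_copy(c, ltr_element, genome) == "full_length_intact"

    def test_mid_element_coverage_is_partial(self, ltr_element):
        L = ltr_element.length
        c = _copy([(int(0.2 * L), int(0.8 * L))])
        assert classify_copy(c, ltr_element) == "partial"

    def test_ltr_class_without_pair_rejected(self):
        el = ConsensusElement(name="b", sequence="ACGT" * 500,
                              element_class="LTR", ltr_spans=None)
        with pytest.raises(ValueError, match="solo"):
            classify_copy(_copy([(0, 100)]), el)

    def test_exhaustive_and_exclusive(self, ltr_element):
        """Every coverage pattern maps to exactly one class."""
        L = ltr_element.length
        patterns = [[(0, 295)], [(0, L)], [(500, 2500)], [(0, 2000)],
                    [(L - 290, L)], [(5, L - 5)], [(100, 260)]]
        for cov in patterns:
            cls = classify_copy(_copy(cov), ltr_element)
            assert cls in {"full_length_intact", "full_length", "partial",
                           "solo_LTR"}


class TestClassifyJunction:
    def _elem(self, junction):
        rng = np.random.default_rng(2)
        ltr = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        prot = "".join("ACDEFGHIKLMNQRSTVW"[i] for i in rng.integers(0, 18, 300))
        return build_ltr_consensus("j", ltr, junction,
                                   reverse_translate(prot) + "TAA")

    def test_pbs_at_offset_two(self):
        el = self._elem("AT" + "TGGCGACATCGTCTTTC")
        j = classify_junction(el)
        assert j.kind == "PBS" and j.offset_bp == 2
        assert j.motif == "TGGCGACATCGTCT"

    def test_ppy(self):
        el = self._elem("TTTTCTTTTTCTTTT")
        j = classify_junction(el)
        assert j.kind == "PPy"

    def test_purine_junction_is_none(self):
        el = self._elem("AAAAAAAAAAAAAAAAAAAA")
        assert classify_junction(el).kind == "none"

    def test_invariant_to_sequence_beyond_window(self):
        a = self._elem("AT" + "TGGCGACATCGTCTTTC" + "AAAAAAAAAAAAAAAAAAAAAAAA")
        b = self._elem("AT" + "TGGCGACATCGTCTTTC" + "GGGGGGGGGGGGGGGGGGGGGGGG")
        ja, jb = classify_junction(a, search_window=19), classify_junction(b, search_window=19)
        assert (ja.kind, ja.offset_bp) == (jb.kind, jb.offset_bp)


class TestIntegrase:
    def test_ctd_lengths(self):
        rng = np.random.default_rng(4)
        tail32 = "".join("ACDEFGHIKLMNQRSTVW"[i] for i in rng.integers(0, 18, 32))
        tail183 = "".join("ACDEFGHIKLMNQRSTVW"[i] for i in rng.integers(0, 18, 183))
        core = "".join("ACDEFGHIKLMNQRSTVW"[i] for i in rng.integers(0, 18, 400))
        assert annotate_integrase(core + "GPY" + tail32).ctd_length == 32
        assert annotate_integrase(core + "GPF" + tail183).ctd_length == 183

    def test_no_motif_reports_undetermined(self):
        ann = annotate_integrase("MKLVHN" * 50)
        assert ann.gpyf_position is None and ann.ctd_length is None


class TestChd:
    def test_true_chd_in_ctd_is_group_one(self, chd_profile):
        rng = np.random.default_rng(6)
        pad = "".join("ACDEGHIKLMNQRSTV"[i] for i in rng.integers(0, 16, 60))
        true = chd_profile.true_chd
        call = detect_chd(pad + true + pad[:40], chd_profile)
        assert call is not None and call.group == "I"
        assert all(c in "FYW" for c in call.cage)

    def test_diverged_cage_is_group_two(self, chd_profile):
        rng = np.random.default_rng(6)
        pad = "".join("ACDEGHIKLMNQRSTV"[i] for i in rng.integers(0, 16, 60))
        chd = list(chd_profile.true_chd)
        c1, _, c3 = chd_profile.cage_columns
        chd[c1], chd[c3] = "S", "E"
        call = detect_chd(pad + "".join(chd) + pad[:40], chd_profile)
        assert call is not None and call.group == "II"

    def test_random_ctd_rejected(self, chd_profile):
        rng = np.random.default_rng(8)
        rand = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 200))
        assert detect_chd(rand, chd_profile) is None

    def test_false_positive_rate_on_shuffles(self, chd_profile):
        """<= 1% of 1000 shuffled true-CHD sequences score above threshold."""
        rng = np.random.default_rng(123)
        letters = list(chd_profile.true_chd)
        fp = 0
        for _ in range(1000):
            rng.shuffle(letters)
            if detect_chd("".join(letters), chd_profile) is not None:
                fp += 1
        assert fp <= 10

    def test_profile_needs_three_cage_columns(self):
        with pytest.raises(ValueError, match="cage"):
            ChdProfile(["KWKYF"] * 3, cage_columns=[1, 3])


class TestClassifyFamily:
    def test_ltr_with_chd_is_skipper(self, library, chd_profile):
        el = library["Skipper_like"]
        from Bio.Seq import Seq
        s, e = el.orf_spans[-1]
        prot = str(Seq(el.sequence[s:e]).translate()).rstrip("*")
        ann = annotate_integrase(prot, chd_profile=chd_profile)
        assert classify_family(el, ann).label == "Skipper"

    def test_ltr_without_chd_is_dglt(self, library, chd_profile):
        el = library["DGLTA_like"]
        from Bio.Seq import Seq
        s, e = el.orf_spans[-1]
        prot = str(Seq(el.sequence[s:e]).translate()).rstrip("*")
        ann = annotate_integrase(prot, chd_profile=chd_profile)
        assert classify_family(el, ann).label == "DGLT-A"

    def test_nonltr_provisional_then_finalized(self, library):
        el = library["TRE5_like"]
        fam = classify_family(el, None)
        assert fam.label == "NLTR"
        assert finalize_nonltr_label(fam, "yes", "upstream").label == "TRE5-like"
        assert finalize_nonltr_label(fam, "yes", "downstream").label == "TRE3-like"
        assert finalize_nonltr_label(fam, "no", None).label == "NLTR"
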