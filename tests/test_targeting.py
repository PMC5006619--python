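"""tRNA-gene association: distances, assignment, targeting calls."""
import numpy as np
import pytest

from retrotarget.intervals import GenomicInterval, TrnaGene
from retrotarget.scan import CopyCall
from retrotarget.targeting import (
    TargetingConfig, assign_elements, call_targeting, compute_gap,
    summarize_genome, trna_centric_scan,
)


def _trna(start, end, strand="+", tid="t1", contig="c"):
    return TrnaGene(id=tid, location=GenomicInterval(contig, start, end, strand))


def _copy(start, end, cid="x#1", family="x", contig="c", strand="+"):
    return CopyCall(id=cid, family=family, mean_identity=99.0, score=500.0,
                    location=GenomicInterval(contig, start, end, strand),
                    consensus_coverage=[(0, end - start)])


class TestComputeGap:
    def test_upstream_of_plus_strand_gene(self):
        assert compute_gap(GenomicInterval("c", 900, 985),
                           _trna(1000, 1073)) == ("upstream", 15)

    def test_downstream_of_plus_strand_gene(self):
        assert compute_gap(GenomicInterval("c", 1100, 1500),
                           _trna(1000, 1073)) == ("downstream", 27)

    def test_minus_strand_mirrors(self):
        assert compute_gap(GenomicInterval("c", 1100, 1500),
                           _trna(1000, 1073, "-")) == ("upstream", 27)
        assert compute_gap(GenomicInterval("c", 900, 985),
                           _trna(1000, 1073, "-")) == ("downstream", 15)

    def test_overlap_is_disruptive(self):
        side, gap = compute_gap(GenomicInterval("c", 1000, 1100),
                                _trna(1050, 1120))
        assert side == "disruptive" and gap is None

    def test_brute_force_oracle_all_placements(self):
        """Every placement of a 100-bp element around one tRNA gene agrees
        with direct base counting, both gene strands."""
        for strand in "+-":
            t = _trna(1450, 1523, strand)
            for a in range(0, 2900):
                loc = GenomicInterval("c", a, a + 100)
                side, gap = compute_gap(loc, t)
                if a + 100 <= 1450:
                    exp_gap = 1450 - (a + 100)
                    exp_side = "upstream" if strand == "+" else "downstream"
                elif a >= 1523:
                    exp_gap = a - 1523
                    exp_side = "downstream" if strand == "+" else "upstream"
                else:
                    exp_gap, exp_side = None, "disruptive"
                assert (side, gap) == (exp_side, exp_gap)


class TestAssignElements:
    def test_nearest_gene_wins(self):
        trnas = [_trna(10_000, 10_073, tid="t1"),
                 _trna(13_000, 13_073, tid="t2")]
        copies = [_copy(9_900, 9_985)]  # 15 bp upstream of t1, 2915 from t2
        (a,) = assign_elements(copies, trnas)
        assert a.trna_id == "t1" and a.gap_bp == 15 and a.side == "upstream"

    def test_beyond_flank_window_unassigned(self):
        trnas = [_trna(10_000, 10_073)]
        copies = [_copy(5_000, 6_400)]  # 3600 bp away
        assert assign_elements(copies, trnas) == []

    def test_nested_flagged_with_intervening_element(self):
        trnas = [_trna(20_000, 20_073, tid="t1")]
        inner = _copy(19_500, 19_950, cid="tre#1", family="tre")
        outer = _copy(15_000, 19_400, cid="dglt#1", family="dglt")
        assign = assign_elements([inner, outer], trnas)
        by_id = {a.copy_id: a for a in assign}
        assert by_id["tre#1"].nested is False
        assert by_id["dglt#1"].nested is True
        assert by_id["dglt#1"].intervening_elements == ["tre#1"]

    def test_element_and_trna_centric_views_consistent(self):
        rng = np.random.default_rng(5)
        trnas = [_trna(p, p + 73, tid=f"t{i}")
                 for i, p in enumerate(range(10_000, 100_000, 9_000))]
        copies = [_copy(int(p), int(p) + 400, cid=f"c#{i}")
                  for i, p in enumerate(rng.integers(0, 99_000, 30))]
        copies = [c for c in copies
                  if all(compute_gap(c.location, t)[1] is not None
                         for t in trnas)]
        cfg = TargetingConfig()
        assignments = assign_elements(copies, trnas, cfg)
        table = trna_centric_scan(trnas, copies, cfg)
        for a in assignments:
            listed = table[a.trna_id][a.side]
            assert (a.copy_id, a.gap_bp) in listed


def _mk_scene(gaps, side="upstream", genome_length=500_000, n_trna=40,
              elem_len=3000, family="fam"):
    """Place tRNA genes on a grid and copies at the given gaps."""
    slot = genome_length // n_trna
    trnas = [_trna(i * slot + slot // 2, i * slot + slot // 2 + 73,
                   tid=f"t{i}") for i in range(n_trna)]
    copies = []
    for i, g in enumerate(gaps):
        ts = trnas[i].location.start
        copies.append(_copy(ts - g - elem_len, ts - g,
                            cid=f"{family}#{i}", family=family))
    return trnas, copies


class TestCallTargeting:
    def test_table_row_shape_recovered(self):
        """18 upstream copies at gaps 13-33 give yes / "13-33 (18)"."""
        gaps = [13, 33] + [20, 25, 17, 30, 14, 22, 28, 19, 31, 15,
                           26, 24, 18, 21, 29, 16]
        trnas, copies = _mk_scene(gaps)
        assignments = assign_elements(copies, trnas)
        call = call_targeting("fam", copies, assignments, trnas, 500_000,
                              TargetingConfig(n_permutations=500, seed=1))
        assert call.verdict == "yes" and call.side == "upstream"
        assert call.table1_string == "13–33 (18)"
        assert call.p_perm <= 0.01

    def test_two_copies_fail_min_copies(self):
        trnas, copies = _mk_scene([15, 20])
        assignments = assign_elements(copies, trnas)
        call = call_targeting("fam", copies, assignments, trnas, 500_000,
                              TargetingConfig(n_permutations=200, seed=1))
        assert call.verdict == "no"

    def test_nested_copies_excluded_from_window(self):
        gaps = [13, 33, 20, 25, 17]
        trnas, copies = _mk_scene(gaps)
        # a fifth element sits between copy 0 and its gene: nested, and
        # copy 0's measured distance (13) must leave the window
        blocker = _copy(trnas[0].location.start - 10 - 2,
                        trnas[0].location.start - 10,
                        cid="blk#1", family="blk")
        copies[0] = _copy(copies[0].location.start - 600,
                          copies[0].location.end - 600,
                          cid="fam#0", family="fam")
        assignments = assign_elements(copies + [blocker], trnas)
        call = call_targeting("fam", copies, assignments, trnas, 500_000,
                              TargetingConfig(n_permutations=0))
        fam0 = next(a for a in assignments if a.copy_id == "fam#0")
        assert fam0.nested is True
        assert call.window == (17, 33)
        assert call.n_total == 5

    def test_heuristic_only_mode(self):
        gaps = [15, 20, 25, 18]
        trnas, copies = _mk_scene(gaps)
        assignments = assign_elements(copies, trnas)
        call = call_targeting("fam", copies, assignments, trnas, 500_000,
                              TargetingConfig(n_permutations=0))
        assert call.p_perm is None and call.verdict == "yes"

    def test_zero_copies_rejected(self):
        trnas, copies = _mk_scene([15])
        with pytest.raises(ValueError):
            call_targeting("other", copies, [], trnas, 500_000)

    def test_monotone_null_statistic(self):
        """A larger association cutoff never decreases the statistic."""
        from retrotarget.targeting import _nearest_gap_side, _trna_arrays
        rng = np.random.default_rng(17)
        trnas, _ = _mk_scene([])
        starts, ends, plus = _trna_arrays(trnas)
        for _ in range(50):
            a = int(rng.integers(0, 490_000))
            b = a + 3000
            side, gap = _nearest_gap_side(a, b, starts, ends, plus)
            if gap is None:
                continue
            for lo, hi in [(100, 500), (500, 1500)]:
                assert (gap <= lo) <= (gap <= hi)

    def test_strand_invariance(self):
        """Mirroring the genome leaves sides, gaps and verdicts unchanged."""
        G = 500_000
        gaps = [13, 33, 20, 25, 17, 30, 14, 22]
        trnas, copies = _mk_scene(gaps)
        flip = lambda iv: GenomicInterval(iv.contig, G - iv.end, G - iv.start,
                                          "-" if iv.strand == "+" else "+")
        trnas_m = [TrnaGene(id=t.id, location=flip(t.location)) for t in trnas]
        copies_m = [CopyCall(id=c.id, family=c.family, location=flip(c.location),
                             consensus_coverage=c.consensus_coverage,
                             mean_identity=c.mean_identity, score=c.score)
                    for c in copies]
        a1 = assign_elements(copies, trnas)
        a2 = assign_elements(copies_m, trnas_m)
        key = lambda xs: sorted((a.copy_id, a.trna_id, a.side, a.gap_bp) for a in xs)
        assert key(a1) == key(a2)
        c1 = call_targeting("fam", copies, a1, trnas, G,
                            TargetingConfig(n_permutations=200, seed=3))
        c2 = call_targeting("fam", copies_m, a2, trnas_m, G,
                            TargetingConfig(n_permutations=200, seed=3))
        assert (c1.verdict, c1.side, c1.window) == (c2.verdict, c2.side, c2.window)


class TestSummarize:
    def test_association_percent_and_union_content(self):
        trnas = [_trna(p, p + 73, tid=f"t{i}")
                 for i, p in enumerate(range(10_000, 110_000, 10_000))]
        copies = [_copy(trnas[i].location.start - 500 - 50,
                        trnas[i].location.start - 50, cid=f"f#{i}", family="f")
                  for i in range(6)]
        assignments = assign_elements(copies, trnas)
        calls = {"f": call_targeting("f", copies, assignments, trnas, 1_000_000,
                                     TargetingConfig(n_permutations=0))}
        rows, summary = summarize_genome(copies, {c.id: "full_length_intact"
                                                  for c in copies},
                                         calls, assignments, trnas, {}, 1_000_000)
        assert summary["trna_assoc_percent"] == 60.0
        assert summary["retroelement_bp"] == 6 * 500
        assert rows[0]["total"] == 6

    def test_overlapping_copies_counted_once(self):
        copies = [_copy(10_000, 15_000, cid="a#1", family="a"),
                  _copy(12_000, 17_000, cid="b#1", family="b")]
        _, summary = summarize_genome(copies, {}, {}, [], [_trna(50_000, 50_073)],
                                      {}, 100_000)
        assert summary["retroelement_bp"] == 7_000
        assert summary["retroelement_percent"] == 7.0
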