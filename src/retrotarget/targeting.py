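"""tRNA-gene association, integration windows, and "active targeting" calls.

Distances are measured between an element copy's tRNA-proximal terminus
and the nearest boundary of the tRNA gene's mature coding sequence, in
the tRNA gene's own transcriptional orientation (upstream = 5').  A
family is called actively targeting when enough copies sit close to tRNA
genes, predominantly on one side, and closer than expected by chance
under a uniform re-placement null (permutation test).  Copies separated
from their target by another element (nested insertions) count toward
association but never toward the reported integration window, since
their original target distance is indeterminable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, TrnaGene, merge_spans, union_length
from .scan import CopyCall

log = logging.getLogger(__name__)

EN_DASH = "–"


@dataclass
class TargetingConfig:
    flank_window: int = 3000
    assoc_max_gap: int = 500
    min_copies: int = 3
    side_consistency: float = 0.7
    n_permutations: int = 1000
    alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assoc_max_gap > self.flank_window:
            raise ValueError("assoc_max_gap must be <= flank_window")
        if not 0.5 < self.side_consistency <= 1.0:
            raise ValueError("side_consistency must be in (0.5, 1]")


@dataclass
class TdnaAssignment:
    copy_id: str
    trna_id: str
    side: str  # upstream | downstream
    gap_bp: int
    nested: bool = False
    intervening_elements: list = field(default_factory=list)


@dataclass
class TargetingCall:
    family: str
    verdict: str  # yes | no
    side: Optional[str]
    window: Optional[tuple]  # (min_gap, max_gap) over non-nested copies
    n_window: int
    n_total: int
    p_perm: Optional[float]
    table1_string: str


# ---------------------------------------------------------------------------
# distances

def compute_gap(copy_location: GenomicInterval, trna: TrnaGene
                ) -> Tuple[str, Optional[int]]:
    """(side, gap_bp) of an element relative to a tRNA gene.

    Gap counts the bases strictly between the element terminus and the
    first (upstream) or last (downstream) base of the mature coding
    sequence.  Overlapping placements are flagged "disruptive" with no
    gap.
    """
    loc, t = copy_location, trna.location
    if loc.contig != t.contig:
        raise ValueError("copy and tRNA gene on different contigs")
    if loc.start < t.end and t.start < loc.end:
        log.info("element %s overlaps tRNA gene %s: disruptive, no gap",
                 copy_location, trna.id)
        return "disruptive", None
    if loc.end <= t.start:  # element left of the gene
        gap = t.start - loc.end
        side = "upstream" if t.strand == "+" else "downstream"
    else:  # element right of the gene
        gap = loc.start - t.end
        side = "downstream" if t.strand == "+" else "upstream"
    return side, gap


def assign_elements(copies: Sequence[CopyCall], trnas: Sequence[TrnaGene],
                    config: Optional[TargetingConfig] = None) -> List[TdnaAssignment]:
    """Assign each copy to the tRNA gene with the smallest gap in range.

    Ties across tRNA genes break to the smaller gap, then upstream side,
    then lower genomic coordinate.  A copy is nested when another copy
    (any family) lies wholly between its proximal terminus and the
    target gene.
    """
    config = config or TargetingConfig()
    out: List[TdnaAssignment] = []
    for copy in copies:
        cands = []
        for t in trnas:
            if t.location.contig != copy.location.contig:
                continue
            side, gap = compute_gap(copy.location, t)
            if gap is None or gap > config.flank_window:
                continue
            cands.append((gap, 0 if side == "upstream" else 1,
                          t.location.start, side, t))
        if not cands:
            continue
        cands.sort(key=lambda c: (c[0], c[1], c[2]))
        gap, _, _, side, t = cands[0]
        # gap region between the copy's proximal terminus and the gene
        if copy.location.end <= t.location.start:
            lo, hi = copy.location.end, t.location.start
        else:
            lo, hi = t.location.end, copy.location.start
        intervening = [
            o.id for o in copies
            if o.id != copy.id and o.location.contig == copy.location.contig
            and lo <= o.location.start and o.location.end <= hi
        ]
        out.append(TdnaAssignment(copy.id, t.id, side, gap,
                                  nested=bool(intervening),
                                  intervening_elements=intervening))
    return out


def trna_centric_scan(trnas: Sequence[TrnaGene], copies: Sequence[CopyCall],
                      config: Optional[TargetingConfig] = None
                      ) -> Dict[str, Dict[str, list]]:
    """Per-tRNA listing of flanking copies within the flank window.

    Returns {trna_id: {"upstream": [(copy_id, gap), ...], "downstream":
    [...]}} with each side ordered by gap.  Every element-centric
    assignment appears in this listing (mutual consistency).
    """
    config = config or TargetingConfig()
    table: Dict[str, Dict[str, list]] = {
        t.id: {"upstream": [], "downstream": []} for t in trnas
    }
    for t in trnas:
        for c in copies:
            if c.location.contig != t.location.contig:
                continue
            side, gap = compute_gap(c.location, t)
            if gap is None or gap > config.flank_window:
                continue
            table[t.id][side].append((c.id, gap))
        for side in ("upstream", "downstream"):
            table[t.id][side].sort(key=lambda x: (x[1], x[0]))
    return table


# ---------------------------------------------------------------------------
# permutation null

def _trna_arrays(trnas: Sequence[TrnaGene]):
    order = np.argsort([t.location.start for t in trnas])
    starts = np.array([trnas[i].location.start for i in order])
    ends = np.array([trnas[i].location.end for i in order])
    plus = np.array([trnas[i].location.strand == "+" for i in order])
    return starts, ends, plus


def _nearest_gap_side(a: int, b: int, starts, ends, plus) -> Tuple[Optional[str], Optional[int]]:
    """Nearest-tRNA side/gap for a placed interval [a, b); None if overlapping."""
    i = int(np.searchsorted(starts, b))
    right_gap = int(starts[i] - b) if i < len(starts) else None
    j = int(np.searchsorted(ends, a, side="right")) - 1
    left_gap = int(a - ends[j]) if j >= 0 else None
    # overlap check with the immediate neighbours
    for k in (i - 1, i, j, j + 1):
        if 0 <= k < len(starts) and a < ends[k] and starts[k] < b:
            return None, None
    best = None
    if right_gap is not None:
        side = "upstream" if plus[i] else "downstream"
        best = (right_gap, side)
    if left_gap is not None and (best is None or left_gap < best[0]):
        side = "downstream" if plus[j] else "upstream"
        best = (left_gap, side)
    if best is None:
        return None, None
    return best[1], best[0]


def _null_statistic(lengths: Sequence[int], genome_length: int,
                    starts, ends, plus, exclusion: List[tuple],
                    assoc_max_gap: int, majority_side: str,
                    rng: np.random.Generator) -> int:
    """One replicate: re-place copies uniformly at non-overlapping
    positions and count those associated on the observed majority side."""
    placed: List[tuple] = list(exclusion)
    count = 0
    for L in lengths:
        for _ in range(200):
            a = int(rng.integers(0, max(1, genome_length - L)))
            b = a + L
            if any(a < e and s < b for s, e in placed):
                continue
            side, gap = _nearest_gap_side(a, b, starts, ends, plus)
            if side is None and gap is None:
                continue  # overlaps a tRNA gene; re-draw like the generator
            placed.append((a, b))
            if gap is not None and gap <= assoc_max_gap and side == majority_side:
                count += 1
            break
    return count


def call_targeting(family: str, copies: Sequence[CopyCall],
                   assignments: Sequence[TdnaAssignment],
                   trnas: Sequence[TrnaGene], genome_length: int,
                   config: Optional[TargetingConfig] = None,
                   exclusion_spans: Optional[List[tuple]] = None) -> TargetingCall:
    """Decide whether a family displays active targeting of tRNA genes.

    Verdict "yes" requires (a) at least ``min_copies`` copies associated
    within ``assoc_max_gap`` of a tRNA gene, (b) at least
    ``side_consistency`` of them on one side, and (c) permutation
    p <= alpha, where the null re-places the family's copies (same
    lengths) uniformly at non-overlapping positions and the statistic is
    the association count on the observed majority side.  The window string
    "min-max (n)" spans the non-nested associated copies on the majority
    side (en dash between the bounds, as conventionally printed).
    """
    config = config or TargetingConfig()
    fam_copies = [c for c in copies if c.family == family]
    if not fam_copies:
        raise ValueError(f"no copies of family {family}")
    fam_ids = {c.id for c in fam_copies}
    fam_assign = [a for a in assignments if a.copy_id in fam_ids]
    assoc = [a for a in fam_assign if a.gap_bp <= config.assoc_max_gap]
    n_up = sum(1 for a in assoc if a.side == "upstream")
    n_down = len(assoc) - n_up
    side = "upstream" if n_up >= n_down else "downstream"
    observed = max(n_up, n_down)
    frac = observed / len(assoc) if assoc else 0.0

    p = None
    if config.n_permutations > 0 and assoc:
        starts, ends, plus = _trna_arrays(trnas)
        lengths = [c.location.length for c in fam_copies]
        excl = exclusion_spans if exclusion_spans is not None else [
            (c.location.start, c.location.end) for c in fam_copies
        ]
        rng = np.random.default_rng(config.seed)
        hits = 0
        for _ in range(config.n_permutations):
            stat = _null_statistic(lengths, genome_length, starts, ends, plus,
                                   excl, config.assoc_max_gap, side, rng)
            if stat >= observed:
                hits += 1
        p = (1 + hits) / (1 + config.n_permutations)

    ok = (len(assoc) >= config.min_copies and frac >= config.side_consistency
          and (p is None or p <= config.alpha))
    verdict = "yes" if ok else "no"

    window_gaps = sorted(a.gap_bp for a in assoc
                         if a.side == side and not a.nested)
    if window_gaps and verdict == "yes":
        mn, mx = window_gaps[0], window_gaps[-1]
        window = (mn, mx)
        n_window = len(window_gaps)
        s = f"{mn}{EN_DASH}{mx}" if mn != mx else f"{mn}"
        table1 = f"{s} ({n_window})"
    else:
        window, n_window, table1 = None, 0, "–"
    return TargetingCall(family=family, verdict=verdict,
                         side=side if verdict == "yes" else None,
                         window=window, n_window=n_window,
                         n_total=len(fam_copies), p_perm=p,
                         table1_string=table1)


# ---------------------------------------------------------------------------
# genome summary

def summarize_genome(copies: Sequence[CopyCall], classes: Dict[str, str],
                     calls: Dict[str, TargetingCall],
                     assignments: Sequence[TdnaAssignment],
                     trnas: Sequence[TrnaGene], library: Dict,
                     genome_length: int) -> Tuple[list, dict]:
    """Per-family table rows and genome-level content summary.

    Rows carry: family, consensus length, LTR length, total copies,
    full-length-intact count, solo-LTR count, targeting verdict, and the
    5'/3' window strings.  Genome summary: retroelement fraction of the
    genome (union of copy spans), fraction of tRNA genes with at least
    one associated copy (overall and per family), and fraction flanked
    on both sides by targeting families.
    """
    fam_names = sorted({c.family for c in copies})
    copy_by_id = {c.id: c for c in copies}
    rows = []
    for fam in fam_names:
        fam_copies = [c for c in copies if c.family == fam]
        cons = library.get(fam)
        ltr_len = None
        if cons is not None and getattr(cons, "ltr_spans", None):
            s, e = cons.ltr_spans[0]
            ltr_len = e - s
        call = calls.get(fam)
        cls = [classes.get(c.id, "partial") for c in fam_copies]
        win5 = win3 = EN_DASH
        if call is not None and call.verdict == "yes":
            if call.side == "upstream":
                win5 = call.table1_string
            else:
                win3 = call.table1_string
        rows.append({
            "family": fam,
            "consensus_length": cons.length if cons is not None else None,
            "ltr_length": ltr_len,
            "total": len(fam_copies),
            "full_length_intact": cls.count("full_length_intact"),
            "solo_ltr": cls.count("solo_LTR"),
            "trna_specific": call.verdict if call is not None else "no",
            "window_5p": win5,
            "window_3p": win3,
        })

    spans = [(c.location.start, c.location.end) for c in copies]
    retro_bp = union_length(spans)

    assoc_by_trna: Dict[str, set] = {}
    side_by_trna: Dict[str, set] = {}
    for a in assignments:
        fam = copy_by_id[a.copy_id].family if a.copy_id in copy_by_id else None
        if fam is None:
            continue
        call = calls.get(fam)
        assoc_by_trna.setdefault(a.trna_id, set()).add(fam)
        if call is not None and call.verdict == "yes" and a.side == call.side:
            side_by_trna.setdefault(a.trna_id, set()).add(a.side)
    n_trna = len(trnas)
    per_family_assoc = {
        fam: 100.0 * sum(1 for t in assoc_by_trna.values() if fam in t) / n_trna
        for fam in fam_names
    }
    both = sum(1 for s in side_by_trna.values() if len(s) == 2)
    summary = {
        "genome_length": genome_length,
        "retroelement_bp": retro_bp,
        "retroelement_percent": 100.0 * retro_bp / genome_length,
        "trna_genes": n_trna,
        "trna_assoc_percent": 100.0 * len(assoc_by_trna) / n_trna,
        "trna_assoc_percent_by_family": per_family_assoc,
        "trna_both_sides_percent": 100.0 * both / n_trna,
    }
    return rows, summary
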