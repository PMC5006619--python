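"""Find copies of consensus elements in a genome and chain hits into calls.

The scanner is a DNA-level stand-in for a translated homology search:
exact k-mer seeds on both strands nominate candidate windows, and each
window is resolved by a full affine-gap local alignment (Gotoh) of the
consensus against the window, so hit scores equal the optimal
dynamic-programming local-alignment score under the same scoring scheme.
An e-value filter applies only to imported BLAST tables; the internal
scanner reports raw scores.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .align import AlignmentParams, encode, local_align, revcomp, identity_from_cigar
from .intervals import ConsensusElement, GenomicInterval, HomologyHit, merge_spans
from .io_formats import read_blast_tabular

log = logging.getLogger(__name__)


@dataclass
class ScanParams:
    """Scanner settings (BLASTN-like defaults, pinned in config)."""

    k: int = 12
    match: int = 1
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -1
    x_drop: int = 20  # window slack for extension bounds
    min_hit_score: int = 30
    chain_max_gap: int = 2000
    cluster_min_seeds: int = 5  # seeds required before a window is aligned

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")
        if self.chain_max_gap < 0:
            raise ValueError("chain_max_gap must be >= 0")

    @property
    def alignment(self) -> AlignmentParams:
        return AlignmentParams(self.match, self.mismatch, self.gap_open, self.gap_extend)


@dataclass
class CopyCall:
    """One genomic copy of a family, assembled from chained hits."""

    id: str
    family: str
    location: GenomicInterval
    consensus_coverage: list  # merged (start, end) consensus spans
    mean_identity: float
    score: float
    hits: list = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.location.strand


# ---------------------------------------------------------------------------
# seeding

def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers; -1 where the window has a non-ACGT base."""
    n = len(enc)
    if n < k:
        return np.empty(0, dtype=np.int64)
    x = enc.astype(np.int64)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for i in range(k):
        codes = codes * 4 + np.minimum(x[i : m + i], 3)
        ok &= x[i : m + i] < 4
    codes[~ok] = -1
    return codes


def _low_complexity(window: np.ndarray) -> bool:
    """Homopolymer-like or two-letter k-mers seed everywhere in A/T-rich
    DNA and are excluded from seeding (alignment still crosses them)."""
    counts = np.bincount(window, minlength=5)[:4]
    return counts.max() > 8 or (counts > 0).sum() < 3


def _seed_matches(g_enc: np.ndarray, q_enc: np.ndarray, k: int) -> List[Tuple[int, int]]:
    """(genome_pos, query_pos) exact k-mer matches (vectorized lookup)."""
    qcodes = _kmer_codes(q_enc, k)
    index: Dict[int, List[int]] = defaultdict(list)
    for pos, code in enumerate(qcodes):
        if code >= 0 and not _low_complexity(q_enc[pos: pos + k]):
            index[int(code)].append(pos)
    qcodes = np.array([c for c in index] or [-2], dtype=np.int64)
    gcodes = _kmer_codes(g_enc, k)
    hit_pos = np.nonzero(np.isin(gcodes, qcodes))[0]
    out = []
    for g in hit_pos:
        for q in index[int(gcodes[g])]:
            out.append((int(g), q))
    return out


def _two_hit_filter(seeds: List[Tuple[int, int]], max_diag_drift: int = 32,
                    max_pair_gap: int = 500) -> List[Tuple[int, int]]:
    """Keep seeds with a nearby partner on a similar alignment diagonal.

    Single chance k-mer matches (frequent in low-complexity, A/T-rich
    DNA) are discarded; genuine homologous stretches produce runs of
    near-diagonal seeds.
    """
    if len(seeds) < 2:
        return []
    by_diag = sorted(seeds, key=lambda s: (s[0] - s[1], s[0]))
    keep = [False] * len(by_diag)
    lo = 0
    for j in range(len(by_diag)):
        dj, gj = by_diag[j][0] - by_diag[j][1], by_diag[j][0]
        while dj - (by_diag[lo][0] - by_diag[lo][1]) > max_diag_drift:
            lo += 1
        # nearest predecessors first; a bounded look-back suffices
        for i in range(j - 1, max(lo, j - 16) - 1, -1):
            if abs(gj - by_diag[i][0]) <= max_pair_gap:
                keep[i] = keep[j] = True
                break
    return sorted(s for s, k_ in zip(by_diag, keep) if k_)


def _cluster_seeds(seeds: List[Tuple[int, int]], max_gap: int) -> List[List[Tuple[int, int]]]:
    """Group seeds into candidate loci by genome proximity."""
    if not seeds:
        return []
    seeds = sorted(seeds)
    clusters = [[seeds[0]]]
    for s in seeds[1:]:
        if s[0] - clusters[-1][-1][0] <= max_gap:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    return clusters


def _identity(gseq: str, qseq: str) -> float:
    """Percent identity of two sequence segments via edit-distance cigar."""
    if not gseq or not qseq:
        return 0.0
    res = edlib.align(qseq, gseq, mode="NW", task="path")
    return 100.0 * identity_from_cigar(qseq, gseq, res["cigar"])


def scan(genome: Sequence[Tuple[str, str]], consensus: ConsensusElement,
         params: Optional[ScanParams] = None) -> List[HomologyHit]:
    """Scan genome records for local-alignment hits of one consensus.

    Both strands are searched; each seeded candidate window yields at
    most one hit, whose span is the optimal local alignment's bounds.
    Hits scoring below ``min_hit_score`` are discarded.
    """
    params = params or ScanParams()
    if params.k > consensus.length:
        raise ValueError(f"k={params.k} exceeds consensus length {consensus.length}")
    hits: List[HomologyHit] = []
    L = consensus.length
    queries = {"+": consensus.sequence, "-": revcomp(consensus.sequence)}
    for contig, gseq in genome:
        if not gseq:
            raise ValueError(f"empty genome record {contig}")
        g_enc = encode(gseq)
        for strand, qseq in queries.items():
            q_enc = encode(qseq)
            seeds = _two_hit_filter(_seed_matches(g_enc, q_enc, params.k))
            for cluster in _cluster_seeds(seeds, params.chain_max_gap):
                if len(cluster) < params.cluster_min_seeds:
                    continue
                # seeds bound the achievable match count from above; skip
                # windows that cannot reach the reporting threshold
                coverage = sum(e - s for s, e in
                               merge_spans([(g, g + params.k) for g, _ in cluster]))
                if coverage < params.min_hit_score:
                    continue
                # window bounds from seed diagonals, with drift margin
                margin = 150 + L // 20 + params.x_drop
                w0 = max(0, min(g - q for g, q in cluster) - margin)
                w1 = min(len(gseq),
                         max(g + (L - q) for g, q in cluster) + margin)
                window = g_enc[w0:w1].copy()
                # iterate with masking so one window can hold several copies
                for _ in range(8):
                    score, (gs, ge), (qs, qe) = local_align(
                        window, q_enc, params.alignment)
                    if score < params.min_hit_score:
                        break
                    g_start, g_end = w0 + gs, w0 + ge
                    if strand == "+":
                        span = (qs, qe)
                    else:
                        span = (L - qe, L - qs)
                    pid = _identity(gseq[g_start:g_end], qseq[qs:qe])
                    hits.append(
                        HomologyHit(
                            query=consensus.name,
                            subject=GenomicInterval(contig, g_start, g_end, strand),
                            query_span=span,
                            percent_identity=pid,
                            score=float(score),
                        )
                    )
                    window[gs:ge] = 4  # mask and look for further copies
                    rest = [(g, g + params.k) for g, _ in cluster
                            if not (w0 + gs <= g < w0 + ge)]
                    if sum(e - s for s, e in merge_spans(rest)) < params.min_hit_score:
                        break
    # deduplicate the same locus reported from overlapping windows or both
    # strands' seeds: highest score keeps the locus
    hits.sort(key=lambda h: (-h.score, h.subject.contig, h.subject.start,
                             h.subject.strand, h.query_span))
    dedup: List[HomologyHit] = []
    for h in hits:
        dup = False
        for o in dedup:
            if h.subject.contig != o.subject.contig:
                continue
            ov = (min(h.subject.end, o.subject.end)
                  - max(h.subject.start, o.subject.start))
            if ov > 0.8 * min(h.subject.length, o.subject.length):
                dup = True
                break
        if not dup:
            dedup.append(h)
    dedup.sort(key=lambda h: (h.subject.contig, h.subject.start, h.query_span))
    return dedup


# ---------------------------------------------------------------------------
# chaining

def chain_hits(hits: Sequence[HomologyHit], params: Optional[ScanParams] = None,
               family: Optional[str] = None) -> List[CopyCall]:
    """Merge colinear hits into per-copy calls.

    Hits on the same contig and strand whose genome gap is at most
    ``chain_max_gap`` form a locus; within a locus the highest-scoring
    colinear subset (consensus and genome order agreeing, gaps bounded
    on both axes) defines the call.  Conflicting overlaps lose to score,
    ties to the leftmost genome coordinate.
    """
    params = params or ScanParams()
    out: List[CopyCall] = []
    by_group: Dict[tuple, List[HomologyHit]] = defaultdict(list)
    for h in hits:
        by_group[(h.query, h.subject.contig, h.subject.strand)].append(h)
    counter: Dict[str, int] = defaultdict(int)
    for (fam, contig, strand), group in sorted(by_group.items()):
        group.sort(key=lambda h: (h.subject.start, h.subject.end))
        # split into loci by genome gap
        loci: List[List[HomologyHit]] = [[group[0]]]
        for h in group[1:]:
            if h.subject.start - loci[-1][-1].subject.end <= params.chain_max_gap:
                loci[-1].append(h)
            else:
                loci.append([h])
        for locus in loci:
            remaining = list(locus)
            while remaining:
                chain = _best_chain(remaining, strand, params)
                if not chain:
                    break
                counter[fam] += 1
                gs = min(h.subject.start for h in chain)
                ge = max(h.subject.end for h in chain)
                spans = merge_spans([h.query_span for h in chain])
                wsum = sum(h.subject.length for h in chain)
                mid = sum(h.percent_identity * h.subject.length
                          for h in chain) / wsum
                out.append(
                    CopyCall(
                        id=f"{fam}#{counter[fam]}",
                        family=fam,
                        location=GenomicInterval(contig, gs, ge, strand),
                        consensus_coverage=spans,
                        mean_identity=mid,
                        score=sum(h.score for h in chain),
                        hits=list(chain),
                    )
                )
                # hits overlapping the winning chain's span conflict and
                # lose to score; non-overlapping leftovers may form
                # further copies of the same locus
                remaining = [h for h in remaining if h not in chain
                             and (h.subject.end <= gs or h.subject.start >= ge)]
    out = _resolve_cross_family(out)
    out.sort(key=lambda c: (c.location.contig, c.location.start))
    return out


def _resolve_cross_family(copies: List[CopyCall]) -> List[CopyCall]:
    """Best-score-wins where calls from related families overlap a locus.

    Shared sub-sequences (e.g. near-identical chromo-domain regions in
    related chromovirus families) produce genuine cross-family hits at
    the same genomic location; only the highest-scoring family keeps the
    locus.
    """
    kept: List[CopyCall] = []
    for c in sorted(copies, key=lambda c: (-c.score, c.location.start, c.family)):
        clash = next((o for o in kept if c.location.overlaps(o.location)
                      and o.family != c.family), None)
        if clash is not None:
            log.info("dropped %s (score %.0f): locus held by %s (score %.0f)",
                     c.id, c.score, clash.id, clash.score)
            continue
        kept.append(c)
    return kept


def _best_chain(locus: List[HomologyHit], strand: str,
                params: ScanParams) -> List[HomologyHit]:
    """Highest-scoring colinear subset (weighted chain DP over hits)."""
    n = len(locus)
    if n == 1:
        return list(locus)
    # genome order already sorted ascending; on '-' the consensus runs backward
    best = [h.score for h in locus]
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            hi, hj = locus[i], locus[j]
            if hj.subject.start < hi.subject.end:
                continue  # genome overlap -> conflict, not chainable
            ggap = hj.subject.start - hi.subject.end
            if ggap > params.chain_max_gap:
                continue
            if strand == "+":
                qgap = hj.query_span[0] - hi.query_span[1]
            else:
                qgap = hi.query_span[0] - hj.query_span[1]
            if qgap < 0 or qgap > params.chain_max_gap:
                continue
            cand = best[i] + hj.score
            if cand > best[j]:
                best[j] = cand
                prev[j] = i
    # pick best end; ties -> leftmost genome coordinate (smallest index)
    end = 0
    for j in range(1, n):
        if best[j] > best[end]:
            end = j
    chain = []
    while end != -1:
        chain.append(locus[end])
        end = prev[end]
    return list(reversed(chain))


def import_hits(blast_table, e_cutoff: float = 1e-15,
                params: Optional[ScanParams] = None) -> List[CopyCall]:
    """Import a BLAST outfmt-6 table and chain hits into copy calls.

    Hits are grouped per query family before chaining; behaviour
    downstream is identical to scanner-produced hits.
    """
    hits = read_blast_tabular(blast_table, e_cutoff=e_cutoff)
    return chain_hits(hits, params)


# ---------------------------------------------------------------------------
# consensus reconstruction

def consensus_from_copies(copy_alignments: Sequence[str]) -> str:
    """Majority-rule consensus of aligned copy sequences.

    Per-column majority base, ties broken A>C>G>T; columns whose
    majority character is a gap are dropped.  Requires >= 2 rows of
    equal aligned length.
    """
    rows = [s.upper() for s in copy_alignments]
    if len(rows) < 2:
        raise ValueError("need >= 2 aligned copies for a consensus")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("aligned copies must have equal length")
    order = "ACGT"
    out = []
    for col in zip(*rows):
        counts = {b: 0 for b in order}
        gaps = 0
        for c in col:
            if c == "-":
                gaps += 1
            elif c in counts:
                counts[c] += 1
        if 2 * gaps > len(rows):
            continue  # gap-majority column dropped
        best_base = max(order, key=lambda b: counts[b])  # ties: A>C>G>T
        out.append(best_base)
    return "".join(out)
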