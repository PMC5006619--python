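"""Structural classification of consensus elements and genomic copies.

Covers: terminal direct-repeat (LTR pair) detection, per-copy structural
class (full-length intact / full-length / partial / solo LTR), the
PBS-vs-polypyrimidine junction downstream of the left LTR, the GPY/F
motif anchoring the integrase carboxy-terminal extension (IN-CTD), and
chromo-domain (CHD) detection with group I / group II aromatic-cage
typing.  The family naming rule follows chromovirus convention: an
LTR element with a CHD in the IN-CTD is "Skipper"-like, one without is
"DGLT-A"-like.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
from Bio.Seq import Seq

from .align import AlignmentParams, encode, local_align, identity_from_cigar, revcomp
from .intervals import ConsensusElement, union_length
from .scan import CopyCall

log = logging.getLogger(__name__)

AROMATIC = set("FYW")
PYRIMIDINES = set("CT")


@dataclass
class LtrPair:
    left_span: tuple
    right_span: tuple
    identity: float
    length: int


@dataclass
class JunctionType:
    kind: str  # "PBS" | "PPy" | "none"
    offset_bp: Optional[int] = None
    motif: Optional[str] = None


@dataclass
class ChdCall:
    span: tuple  # protein sub-interval of the CTD
    cage: str  # the three cage residues
    group: str  # "I" | "II" | "I-atypical"
    score: float


@dataclass
class IntegraseAnnotation:
    gpyf_position: Optional[int]  # protein index of the G, or None
    ctd_length: Optional[int]  # residues after the tripeptide, or None ("n.d.")
    chd: Optional[ChdCall] = None


@dataclass
class FamilyClass:
    label: str  # Skipper | DGLT-A | TRE5-like | TRE3-like | NLTR | unclassified
    evidence: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# LTR pair detection

def detect_ltr_pair(consensus: ConsensusElement, min_len: int = 80,
                    min_identity: float = 0.90, end_window: int = 50
                    ) -> Optional[LtrPair]:
    """Highest-scoring near-identical terminal direct repeat, or None.

    The left copy must start within ``end_window`` of position 0 and the
    right copy end within ``end_window`` of the element end.
    """
    seq = consensus.sequence
    L = len(seq)
    if L <= 2 * min_len:
        return None
    half = min(L // 2, 1500)
    a, b = seq[:half], seq[-half:]
    params = AlignmentParams()
    score, (as_, ae), (bs, be) = local_align(encode(a), encode(b), params)
    if score <= 0:
        return None
    if as_ > end_window or (half - be) > end_window:
        return None
    if (ae - as_) < min_len or (be - bs) < min_len:
        return None
    if abs((ae - as_) - (be - bs)) > 5:
        return None
    res = edlib.align(a[as_:ae], b[bs:be], mode="NW", task="path")
    ident = identity_from_cigar(a[as_:ae], b[bs:be], res["cigar"])
    if ident < min_identity:
        return None
    return LtrPair(
        left_span=(as_, ae),
        right_span=(L - half + bs, L - half + be),
        identity=ident,
        length=ae - as_,
    )


# ---------------------------------------------------------------------------
# per-copy structural class

def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _copy_to_consensus_map(copy_seq: str, consensus_seq: str):
    """Align a copy to its consensus; yield (op_len, op, cons_pos, copy_pos).

    edlib conventions with align(query=copy, target=consensus):
    '='/'X' consume both; 'I' consumes the query (copy insertion);
    'D' consumes the target (copy deletion).  Mode HW locates the copy
    as an infix of the consensus.
    """
    res = edlib.align(copy_seq, consensus_seq, mode="HW", task="path")
    cons_pos = res["locations"][0][0]
    copy_pos = 0
    for L, op in _cigar_ops(res["cigar"]):
        yield L, op, cons_pos, copy_pos
        if op in "=XM":
            cons_pos += L
            copy_pos += L
        elif op == "I":
            copy_pos += L
        elif op == "D":
            cons_pos += L


def _orf_intact(copy_seq: str, consensus: ConsensusElement) -> bool:
    """Translate each ORF span from the copy; stops or frame breaks fail.

    Indels inside the ORF whose net length balance is divisible by 3
    keep the frame (a single in-frame indel does not break intactness);
    any other balance is a frame disruption.
    """
    events = list(_copy_to_consensus_map(copy_seq, consensus.sequence))
    for (s, e) in consensus.orf_spans:
        segment = []
        net = 0
        for L, op, cpos, qpos in events:
            if op in "=XM":
                lo = max(cpos, s)
                hi = min(cpos + L, e)
                if lo < hi:
                    segment.append(copy_seq[qpos + (lo - cpos): qpos + (hi - cpos)])
            elif op == "I":
                if s <= cpos < e:
                    net += L
                    segment.append(copy_seq[qpos: qpos + L])
            elif op == "D":
                ov = min(cpos + L, e) - max(cpos, s)
                if ov > 0:
                    net -= ov
        if net % 3 != 0:
            return False
        dna = "".join(segment)
        if len(dna) < e - s - 30:  # ORF largely missing from the copy
            return False
        dna = dna[: len(dna) - len(dna) % 3]
        prot = str(Seq(dna).translate())
        if "*" in prot[:-1]:
            return False
    return True


def classify_copy(copy: CopyCall, consensus: ConsensusElement,
                  genome_seq: Optional[str] = None,
                  full_length_coverage: float = 0.95, terminus_tol: int = 10,
                  solo_ltr_tol: int = 20, solo_ltr_min_cov: float = 0.80,
                  solo_ltr_overhang: int = 40) -> str:
    """Assign exactly one structural class to a copy call.

    solo_LTR: coverage lies within one LTR span (+- tolerance) and covers
    at least ``solo_ltr_min_cov`` of that LTR; up to
    ``solo_ltr_overhang`` bp of coverage beyond the tolerated window is
    ignored (optimal local alignments make short net-positive chance
    excursions into flanking DNA, far shorter than any genuine partial).
    full_length: coverage at least ``full_length_coverage`` of the
    consensus with both termini within ``terminus_tol`` bp of the
    consensus ends; additionally intact when every ORF translates
    without internal stops or frame-breaking indels.  Everything else:
    partial.
    """
    spans = copy.consensus_coverage
    if not spans:
        return "partial"
    cov = union_length(spans)
    L = consensus.length

    if consensus.element_class == "LTR":
        if consensus.ltr_spans is None:
            raise ValueError(
                f"{consensus.name}: LTR-class element without an LTR pair; "
                "cannot evaluate solo-LTR status"
            )
        for (ls, le) in consensus.ltr_spans:
            lo, hi = ls - solo_ltr_tol, le + solo_ltr_tol
            inside = sum(min(e, hi) - max(s, lo) for s, e in spans
                         if min(e, hi) > max(s, lo))
            outside = cov - inside
            if outside <= solo_ltr_overhang and \
                    inside >= solo_ltr_min_cov * (le - ls):
                return "solo_LTR"

    termini_ok = spans[0][0] <= terminus_tol and (L - spans[-1][1]) <= terminus_tol
    if cov >= full_length_coverage * L and termini_ok:
        if genome_seq is not None and consensus.orf_spans:
            cseq = genome_seq[copy.location.start: copy.location.end]
            if copy.location.strand == "-":
                cseq = revcomp(cseq)
            if _orf_intact(cseq, consensus):
                return "full_length_intact"
        return "full_length"
    return "partial"


# ---------------------------------------------------------------------------
# junction typing

def classify_junction(consensus: ConsensusElement, search_window: int = 40,
                      pbs_max_offset: int = 10, ppy_window: int = 15,
                      ppy_min_pyrimidines: int = 12) -> JunctionType:
    """Type the junction after the left LTR as PBS, PPy, or none.

    PBS: a TGG within ``pbs_max_offset`` bp of the LTR end (the motif is
    the TGG plus the following 11 bases, 14 in total, complementing a
    primer tRNA's CCA 3' end).  PPy: any 15-base window with >= 12
    pyrimidines including at least one C.
    """
    if consensus.ltr_spans is None:
        raise ValueError(f"{consensus.name}: junction typing requires an LTR pair")
    ltr_end = consensus.ltr_spans[0][1]
    window = consensus.sequence[ltr_end: ltr_end + search_window]
    tgg = window.find("TGG")
    if 0 <= tgg <= pbs_max_offset:
        return JunctionType("PBS", offset_bp=tgg, motif=window[tgg: tgg + 14])
    for i in range(0, max(0, len(window) - ppy_window) + 1):
        w = window[i: i + ppy_window]
        if len(w) < ppy_window:
            break
        npy = sum(1 for c in w if c in PYRIMIDINES)
        if npy >= ppy_min_pyrimidines and "C" in w:
            return JunctionType("PPy", offset_bp=i, motif=w)
    return JunctionType("none")


# ---------------------------------------------------------------------------
# integrase carboxy-terminal extension and chromo domain

GPYF = re.compile(r"GP[YF]")


def annotate_integrase(protein: str, in_core_end_hint: Optional[int] = None,
                       chd_profile: Optional["ChdProfile"] = None
                       ) -> IntegraseAnnotation:
    """Locate the GPY/F motif and measure the IN-CTD.

    The last G-P-[Y/F] tripeptide at or after ``in_core_end_hint``
    (default: last occurrence in the protein) marks the end of the IN
    core; the CTD runs from the residue after it to the carboxyl end.
    Without a motif the CTD is not determined ("n.d.").
    """
    start = in_core_end_hint or 0
    matches = [m for m in GPYF.finditer(protein) if m.start() >= start]
    if not matches:
        return IntegraseAnnotation(gpyf_position=None, ctd_length=None)
    m = matches[-1]
    ctd_start = m.start() + 3
    ctd = protein[ctd_start:]
    ann = IntegraseAnnotation(gpyf_position=m.start(), ctd_length=len(ctd))
    if chd_profile is not None and ctd:
        ann.chd = detect_chd(ctd, chd_profile)
    return ann


class ChdProfile:
    """Position-specific scoring model over a curated CHD alignment.

    Log-odds against a uniform amino-acid background with pseudocounts;
    exactly three columns are marked as the aromatic cage.  The
    detection threshold is the mean + 4 SD of scores of seeded random
    shuffles of the first (true) CHD sequence in the alignment.
    """

    AA = "ACDEFGHIKLMNPQRSTVWY"

    def __init__(self, rows: Sequence[str], cage_columns: Sequence[int],
                 pseudocount: float = 0.5, n_shuffles: int = 1000, seed: int = 2016):
        if len(cage_columns) != 3:
            raise ValueError("profile must mark exactly three cage columns")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("profile alignment rows must have equal length")
        self.length = lengths.pop()
        self.cage_columns = tuple(int(c) for c in cage_columns)
        idx = {a: i for i, a in enumerate(self.AA)}
        counts = np.full((self.length, 20), pseudocount)
        for row in rows:
            for j, aa in enumerate(row.upper()):
                if aa in idx:
                    counts[j, idx[aa]] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        self.matrix = np.log2(freqs / (1.0 / 20.0))
        self._idx = idx
        # unknown residues score a flat penalty via an extra matrix column
        self._mat21 = np.hstack([self.matrix, np.full((self.length, 1), -2.0)])
        true_chd = rows[0]
        rng = np.random.default_rng(seed)
        enc = self._encode(true_chd)
        scores = np.empty(n_shuffles)
        for i in range(n_shuffles):
            rng.shuffle(enc)
            scores[i] = self._mat21[np.arange(self.length), enc].sum()
        self.threshold = float(scores.mean() + 4.0 * scores.std())

    def _encode(self, protein: str) -> np.ndarray:
        return np.array([self._idx.get(aa, 20) for aa in protein], dtype=np.intp)

    def best_window(self, protein: str) -> Tuple[float, int]:
        n = len(protein)
        if n < self.length:
            return -np.inf, 0
        enc = self._encode(protein)
        m = n - self.length + 1
        scores = np.zeros(m)
        for j in range(self.length):
            scores += self._mat21[j, enc[j: j + m]]
        pos = int(np.argmax(scores))
        return float(scores[pos]), pos

    @classmethod
    def packaged(cls) -> "ChdProfile":
        """The packaged synthetic CHD profile fixture."""
        text = resources.files("retrotarget.data").joinpath(
            "chd_profile_synthetic.json").read_text()
        data = json.loads(text)
        return cls(data["rows"], data["cage_columns"])

    @property
    def true_chd(self) -> str:
        # reconstruct a representative CHD: per-column argmax residue
        return "".join(self.AA[int(j)] for j in self.matrix.argmax(axis=1))


def detect_chd(ctd_protein: str, profile: ChdProfile) -> Optional[ChdCall]:
    """Best profile window in the IN-CTD; None below threshold.

    Group I: all three cage residues aromatic (F/Y/W).  Group II: cage
    position 1 non-aromatic (position 3 typically also diverged).  An
    aromatic position 1 with a non-aromatic 2 or 3 is logged "I-atypical".
    """
    score, pos = profile.best_window(ctd_protein)
    if score < profile.threshold:
        return None
    cage = "".join(ctd_protein[pos + c] for c in profile.cage_columns)
    if all(c in AROMATIC for c in cage):
        group = "I"
    elif cage[0] not in AROMATIC:
        group = "II"
    else:
        group = "I-atypical"
        log.info("atypical cage %s: position 1 aromatic but 2/3 diverged", cage)
    return ChdCall(span=(pos, pos + profile.length), cage=cage,
                   group=group, score=float(score))


# ---------------------------------------------------------------------------
# family naming

def classify_family(consensus: ConsensusElement,
                    integrase: Optional[IntegraseAnnotation] = None) -> FamilyClass:
    """Name a family from its structure; non-LTR labels await targeting.

    LTR element with a CHD in the IN-CTD -> Skipper; LTR element without
    a CHD -> DGLT-A; non-LTR elements are provisionally NLTR until
    targeting evidence resolves TRE5-like/TRE3-like.
    """
    evidence: List[str] = []
    if consensus.element_class == "LTR":
        has_chd = integrase is not None and integrase.chd is not None
        if has_chd:
            evidence.append(f"CHD group {integrase.chd.group} in IN-CTD")
            return FamilyClass("Skipper", evidence)
        evidence.append("no CHD detected in IN-CTD")
        if integrase is not None and integrase.ctd_length is not None:
            evidence.append(f"IN-CTD length {integrase.ctd_length} aa")
        return FamilyClass("DGLT-A", evidence)
    evidence.append("non-LTR structure; targeting evidence pending")
    return FamilyClass("NLTR", evidence)


def finalize_nonltr_label(family_class: FamilyClass, verdict: str,
                          side: Optional[str]) -> FamilyClass:
    """Resolve NLTR into TRE5-like (upstream) / TRE3-like (downstream)."""
    if family_class.label != "NLTR" or verdict != "yes":
        return family_class
    label = "TRE5-like" if side == "upstream" else "TRE3-like"
    ev = family_class.evidence + [f"active targeting, side={side}"]
    return FamilyClass(label, ev)
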