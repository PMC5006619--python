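"""Seeded synthetic genomes with planted tRNA genes and retroelement copies.

The generator emulates a gene-dense, A/T-rich haploid genome of the kind
social amoebae carry: dispersed tRNA genes on both strands, and copies of
retroelement families planted at configurable sides and gap distances
relative to the tRNA genes' mature coding boundaries, with 5'-truncation,
solo-LTR formation and per-copy sequence divergence.  Every planted copy
is described exactly by a TruthRecord, so downstream stages can be scored
against known ground truth.

Determinism: one RNG stream per insertion profile, derived from
``(seed, crc32(family))`` through numpy's SeedSequence, so adding a
profile does not perturb the draws of the others; identical inputs give
byte-identical outputs.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq

from .align import revcomp
from .intervals import ConsensusElement, GenomicInterval, TrnaGene

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

STOP_CODONS = {"TAA", "TAG", "TGA"}

# one codon per amino acid, chosen A/T-rich where possible
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "*": "TAA",
}


def reverse_translate(protein: str) -> str:
    """DNA cassette for a protein (fixed A/T-rich codon table)."""
    return "".join(_CODON[aa] for aa in protein)


@dataclass
class GenomeSpec:
    """Shape of a synthetic genome."""

    length: int = 500_000
    gc_fraction: float = 0.28  # A/T-rich, dictyostelid-like
    n_trna: int = 40
    min_spacing: int = 100
    contig_name: str = "synth1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0,1]")
        if self.n_trna < 1 or self.length < 1000:
            raise ValueError("need n_trna >= 1 and length >= 1000")


@dataclass
class InsertionProfile:
    """How copies of one family are planted.

    ``side`` is defined in the tRNA gene's own transcriptional
    orientation (upstream = 5' of the mature coding sequence).  Gap
    distances are drawn uniformly on [gap_min, gap_max]; when
    ``n_copies >= 2`` the sample is pinned to attain both bounds so the
    planted window is exactly recoverable ground truth.  Non-full-length,
    non-solo copies are 5'-truncated by a uniform draw between
    ``trunc_min_bp`` and ``trunc_max_frac`` of the element length.
    """

    family: str
    n_copies: int
    side: str = "upstream"  # upstream | downstream | random
    gap_min: int = 13
    gap_max: int = 33
    orientation_rule: str = "random"  # fixed_plus | fixed_minus | random
    fraction_full_length: float = 1.0
    fraction_solo_ltr: float = 0.0
    trunc_min_bp: int = 60
    trunc_max_frac: float = 0.5
    substitution_rate: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.side not in ("upstream", "downstream", "random"):
            raise ValueError(f"bad side {self.side!r}")
        if self.fraction_full_length + self.fraction_solo_ltr > 1.0 + 1e-9:
            raise ValueError("fraction_full_length + fraction_solo_ltr must be <= 1")
        if self.gap_min > self.gap_max:
            raise ValueError("gap_min > gap_max")
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0,1)")


@dataclass
class TruthRecord:
    """Ground-truth twin of one planted copy."""

    id: str
    family: str
    location: GenomicInterval
    structural_class: str  # full_length_intact | full_length | partial | solo_LTR
    trna_id: Optional[str] = None
    side: Optional[str] = None
    gap_bp: Optional[int] = None
    nested: bool = False


# ---------------------------------------------------------------------------
# consensus construction

def _check_orf(dna: str, what: str) -> None:
    if len(dna) % 3 != 0:
        raise ValueError(f"{what}: ORF length {len(dna)} not a multiple of 3")
    for i in range(0, len(dna) - 3, 3):
        if dna[i : i + 3] in STOP_CODONS:
            raise ValueError(f"{what}: internal stop codon at nt {i}")


def build_ltr_consensus(name: str, ltr: str, junction_linker: str,
                        internal_orf: str, right_linker: str = "") -> ConsensusElement:
    """LTR-class consensus: LTR + junction linker + internal ORF + LTR.

    The two LTRs are identical; the junction linker sits immediately
    after the left LTR (where PBS/PPy typing looks).  The internal ORF
    cassette must be stop-free except terminally.
    """
    _check_orf(internal_orf, name)
    seq = ltr + junction_linker + internal_orf + right_linker + ltr
    orf_start = len(ltr) + len(junction_linker)
    return ConsensusElement(
        name=name,
        sequence=seq,
        element_class="LTR",
        ltr_spans=((0, len(ltr)), (len(seq) - len(ltr), len(seq))),
        orf_spans=[(orf_start, orf_start + len(internal_orf))],
    )


def build_nonltr_consensus(name: str, utr5: str, orf_dna: str,
                           polya_len: int = 15, utr3: str = "") -> ConsensusElement:
    """Non-LTR consensus: 5' UTR + ORF + 3' UTR + poly(A) tail."""
    _check_orf(orf_dna, name)
    seq = utr5 + orf_dna + utr3 + "A" * polya_len
    return ConsensusElement(
        name=name,
        sequence=seq,
        element_class="nonLTR",
        ltr_spans=None,
        orf_spans=[(len(utr5), len(utr5) + len(orf_dna))],
    )


# ---------------------------------------------------------------------------
# mutation

def mutate(seq: str, sub_rate: float, indel_rate: float,
           rng: np.random.Generator) -> Tuple[str, List[Tuple[int, int]]]:
    """Mutate a sequence; returns (mutated, indel events).

    Indel events are (position in the *original* sequence, length) with
    positive length = insertion, negative = deletion (1-3 bp).
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    if sub_rate > 0:
        hit = rng.random(n) < sub_rate
        idx = np.nonzero(hit)[0]
        for i in idx:
            choices = BASES[BASES != arr[i]]
            arr[i] = choices[rng.integers(len(choices))]
    indels: List[Tuple[int, int]] = []
    if indel_rate > 0:
        hit = np.nonzero(rng.random(n) < indel_rate)[0]
        for pos in hit:
            L = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                indels.append((int(pos), L))  # insertion before pos
            else:
                indels.append((int(pos), -min(L, n - int(pos))))
    if not indels:
        return arr.tobytes().decode(), []
    pieces = []
    cur = 0
    for pos, L in sorted(indels):
        pos = max(pos, cur)
        pieces.append(arr[cur:pos].tobytes().decode())
        if L > 0:
            ins = BASES[rng.integers(0, 4, size=L)]
            pieces.append(ins.tobytes().decode())
            cur = pos
        else:
            cur = pos + (-L)
    pieces.append(arr[cur:].tobytes().decode())
    return "".join(pieces), sorted(indels)


def _orf_intact_after_mutation(consensus: ConsensusElement, mutated: str,
                               indels: List[Tuple[int, int]]) -> bool:
    """Is every ORF still stop-free and in frame after per-copy mutation?"""
    for (s, e) in consensus.orf_spans:
        shift_at_s = sum(L for p, L in indels if p < s)
        net_in_orf = 0
        for p, L in indels:
            if s <= p < e:
                if abs(L) % 3 != 0:
                    return False
                net_in_orf += L
        ms = s + shift_at_s
        me = e + shift_at_s + net_in_orf
        if ms < 0 or me > len(mutated):
            return False
        prot = str(Seq(mutated[ms:me]).translate())
        if "*" in prot[:-1]:
            return False
    return True


# ---------------------------------------------------------------------------
# generation

def _profile_rng(seed: int, family: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(family.encode())])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _class_counts(profile: InsertionProfile) -> List[str]:
    n = profile.n_copies
    n_solo = min(_round_half_up(profile.fraction_solo_ltr * n), n)
    n_full = min(_round_half_up(profile.fraction_full_length * n), n - n_solo)
    n_part = n - n_solo - n_full
    return ["full_length"] * n_full + ["partial"] * n_part + ["solo_LTR"] * n_solo


def generate(spec: GenomeSpec, profiles: Sequence[InsertionProfile],
             library: Dict[str, ConsensusElement]
             ) -> Tuple[List[Tuple[str, str]], List[TrnaGene], List[TruthRecord]]:
    """Build (genome records, tRNA annotations, truth records).

    Geometry contract: for a targeted copy the tRNA-proximal terminus
    lies exactly ``gap_bp`` outside the mature coding boundary on the
    requested side, in the tRNA gene's own orientation.
    """
    rng = np.random.default_rng(spec.seed)
    contig = spec.contig_name
    L = spec.length

    # --- tRNA layout: one slot per gene, gene near the slot centre
    slot = L // spec.n_trna
    max_elem = max((library[p.family].length for p in profiles), default=0)
    max_gap = max((p.gap_max for p in profiles if p.side != "random"), default=0)
    need = max_elem + max_gap + spec.min_spacing
    if slot // 2 - slot // 10 - 90 < need:
        raise ValueError(
            f"infeasible packing: need {need} bp of flank per tRNA slot, "
            f"have {slot // 2 - slot // 10 - 90} (genome {L} bp / {spec.n_trna} tRNAs)"
        )
    trnas: List[TrnaGene] = []
    iso = list("ACDEFGHIKLMNPQRSTVWY")
    for i in range(spec.n_trna):
        tlen = int(rng.integers(70, 91))
        jitter = int(rng.integers(-(slot // 10), slot // 10 + 1))
        ts = i * slot + slot // 2 + jitter
        strand = "+" if rng.random() < 0.5 else "-"
        loc = GenomicInterval(contig, ts, ts + tlen, strand)
        trnas.append(
            TrnaGene(id=f"{contig}.trna{i + 1}", location=loc,
                     isotype=iso[int(rng.integers(len(iso)))],
                     anticodon="".join("ACGT"[int(b)] for b in rng.integers(0, 4, 3)))
        )

    occupied: List[Tuple[int, int]] = [(t.location.start, t.location.end) for t in trnas]

    def free(a: int, b: int, target: Optional[Tuple[int, int]] = None,
             pad: Optional[int] = None) -> bool:
        # the copy's own target tRNA is exempt from the spacing pad
        # (planted gaps are intentionally smaller than min_spacing)
        if a < 0 or b > L:
            return False
        pad = spec.min_spacing if pad is None else pad
        for s, e in occupied:
            if (s, e) == target:
                if a < e and s < b:
                    return False
                continue
            if a - pad < e and s < b + pad:
                return False
        return True

    truth: List[TruthRecord] = []
    placements: List[Tuple[int, str, str]] = []  # (genome pos, seq, truth id)

    avail = {"upstream": set(range(spec.n_trna)), "downstream": set(range(spec.n_trna))}

    for profile in profiles:
        cons = library[profile.family]
        prng = _profile_rng(spec.seed, profile.family)
        classes = _class_counts(profile)
        prng.shuffle(classes)

        # gap sample attains both bounds so the window is exact ground truth
        gaps = []
        if profile.side != "random":
            n = profile.n_copies
            if n >= 2:
                gaps = [profile.gap_min, profile.gap_max]
                gaps += [int(g) for g in prng.integers(profile.gap_min, profile.gap_max + 1, n - 2)]
            else:
                gaps = [int(prng.integers(profile.gap_min, profile.gap_max + 1))]
            order = prng.permutation(n)
            gaps = [gaps[i] for i in order]

        trna_order = [int(i) for i in prng.permutation(spec.n_trna)]

        for ci in range(profile.n_copies):
            cls = classes[ci]
            if cls == "solo_LTR":
                if cons.element_class != "LTR" or cons.ltr_spans is None:
                    raise ValueError(f"{profile.family}: solo_LTR fraction on a non-LTR element")
                s, e = cons.ltr_spans[0]
                base_seq = cons.sequence[s:e]
            elif cls == "partial":
                tmax = max(profile.trunc_min_bp + 1, int(profile.trunc_max_frac * cons.length))
                trunc = int(prng.integers(profile.trunc_min_bp, tmax))
                base_seq = cons.sequence[trunc:]
            else:
                base_seq = cons.sequence

            mutated, indels = mutate(base_seq, profile.substitution_rate,
                                     profile.indel_rate, prng)
            if cls == "full_length":
                intact = (profile.substitution_rate == 0 and profile.indel_rate == 0) or \
                    _orf_intact_after_mutation(cons, mutated, indels)
                cls_final = "full_length_intact" if intact else "full_length"
            else:
                cls_final = cls

            if profile.orientation_rule == "fixed_plus":
                strand = "+"
            elif profile.orientation_rule == "fixed_minus":
                strand = "-"
            else:
                strand = "+" if prng.random() < 0.5 else "-"
            planted_seq = mutated if strand == "+" else revcomp(mutated)
            elen = len(planted_seq)

            tid = f"{profile.family}#{ci + 1}"
            if profile.side == "random":
                # uniform over unoccupied space with no spacing pad, so
                # random placement matches the permutation-test null
                placed = False
                for _ in range(2000):
                    a = int(prng.integers(0, L - elen))
                    if free(a, a + elen, pad=0):
                        placed = True
                        break
                if not placed:
                    raise ValueError(f"infeasible packing: no free space for {tid}")
                loc = GenomicInterval(contig, a, a + elen, strand)
                truth.append(TruthRecord(tid, profile.family, loc, cls_final,
                                         side="random"))
            else:
                gap = gaps[ci]
                chosen = None
                for idx in trna_order:
                    if idx not in avail[profile.side]:
                        continue
                    t = trnas[idx]
                    ts, te = t.location.start, t.location.end
                    tstrand = t.location.strand
                    left_side = (profile.side == "upstream") == (tstrand == "+")
                    if left_side:
                        a, b = ts - gap - elen, ts - gap
                    else:
                        a, b = te + gap, te + gap + elen
                    if free(a, b, target=(ts, te)):
                        chosen = (idx, t, a, b)
                        break
                if chosen is None:
                    raise ValueError(
                        f"infeasible packing: no tRNA slot fits {tid} "
                        f"({elen} bp at gap {gap})"
                    )
                idx, t, a, b = chosen
                avail[profile.side].discard(idx)
                loc = GenomicInterval(contig, a, b, strand)
                truth.append(TruthRecord(tid, profile.family, loc, cls_final,
                                         trna_id=t.id, side=profile.side, gap_bp=gap))
            occupied.append((truth[-1].location.start, truth[-1].location.end))
            placements.append((truth[-1].location.start, planted_seq, tid))

    # --- assemble sequence: i.i.d. background, then overwrite feature slots
    gc = spec.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = BASES[rng.choice(4, size=L, p=probs)].copy()
    for t in trnas:
        s, e = t.location.start, t.location.end
        genome[s:e] = BASES[rng.integers(0, 4, size=e - s)]
    for pos, seq, _ in placements:
        genome[pos : pos + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)

    return [(contig, genome.tobytes().decode())], trnas, truth


def nested_insertion(genome: List[Tuple[str, str]], trnas: List[TrnaGene],
                     truth: List[TruthRecord], outer_family: str,
                     outer_seq: str, inner_id: Optional[str] = None
                     ) -> Tuple[List[Tuple[str, str]], List[TrnaGene], List[TruthRecord]]:
    """Insert an outer copy between an existing targeted copy and the far flank.

    The inner copy ends up between the outer copy and its tRNA gene, so
    the outer copy's original target distance is indeterminable; its
    truth record is marked ``nested``.  All downstream coordinates shift
    by the inserted length; the genome grows by exactly ``len(outer_seq)``.
    """
    eligible = [r for r in truth if r.trna_id is not None and not r.nested]
    if inner_id is not None:
        eligible = [r for r in eligible if r.id == inner_id]
    if not eligible:
        raise ValueError("nested_insertion: no eligible tRNA-assigned inner copy")
    inner = eligible[0]
    contig, seq = genome[0]
    if inner.location.contig != contig:
        raise ValueError("inner copy not on the provided contig")

    t = next(x for x in trnas if x.id == inner.trna_id)
    inner_left_of_trna = inner.location.end <= t.location.start
    pos = inner.location.start if inner_left_of_trna else inner.location.end
    ins_len = len(outer_seq)

    new_seq = seq[:pos] + outer_seq + seq[pos:]

    def shift_iv(iv: GenomicInterval) -> GenomicInterval:
        return iv.shifted(ins_len) if iv.start >= pos else iv

    new_trnas = [
        TrnaGene(id=x.id, location=shift_iv(x.location), isotype=x.isotype,
                 anticodon=x.anticodon, intron_spans=[shift_iv(i) for i in x.intron_spans])
        for x in trnas
    ]
    new_truth = [
        TruthRecord(r.id, r.family, shift_iv(r.location), r.structural_class,
                    r.trna_id, r.side, r.gap_bp, r.nested)
        for r in truth
    ]
    outer_loc = GenomicInterval(contig, pos, pos + ins_len, "+")
    # measured distance runs through the inner copy; the original target
    # distance is indeterminable, hence nested=True
    t_new = next(x for x in new_trnas if x.id == inner.trna_id)
    if inner_left_of_trna:
        gap_meas = t_new.location.start - outer_loc.end
    else:
        gap_meas = outer_loc.start - t_new.location.end
    new_truth.append(
        TruthRecord(f"{outer_family}#nested", outer_family, outer_loc,
                    "full_length_intact", trna_id=inner.trna_id, side=inner.side,
                    gap_bp=abs(gap_meas), nested=True)
    )
    return [(contig, new_seq)], new_trnas, new_truth
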