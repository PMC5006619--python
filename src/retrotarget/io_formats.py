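"""Readers and writers for the standard formats the pipeline touches.

One coordinate convention holds internally (0-based half-open); each
reader converts at the boundary:

* FASTA — via Biopython; sequences upper-cased, U normalised to T.
* tRNAscan-SE 2.x tabular — 1-based inclusive, begin>end means minus strand.
* BLAST outfmt-6 (12 columns) — 1-based inclusive, sstart>send means minus.
* GFF3 — 1-based inclusive.  BED — 0-based half-open.
* Aligned FASTA / Clustal — via Biopython AlignIO.
* Newick — via dendropy.
"""
from __future__ import annotations

import logging
from typing import List, Optional, Tuple

from Bio import AlignIO, SeqIO

from .intervals import GenomicInterval, HomologyHit, TrnaGene

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> List[Tuple[str, str]]:
    """Read FASTA records as (id, sequence), upper-cased, U->T normalised.

    Raises ``ValueError`` on duplicate ids or empty sequences.
    """
    records = []
    seen = set()
    n_u = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        if "U" in seq:
            n_u += seq.count("U")
            seq = seq.replace("U", "T")
        records.append((rec.id, seq))
    if n_u:
        log.info("normalised %d U bases to T while reading %s", n_u, path)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records, width: int = 70) -> None:
    """Write (id, sequence) records as FASTA (inverse of :func:`read_fasta`)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# tRNAscan-SE tabular

def read_trnascan_tabular(path) -> List[TrnaGene]:
    """Parse tRNAscan-SE 2.x tabular output (3 header lines).

    Columns: sequence name, tRNA number, begin, end, type, anticodon,
    intron begin, intron end, score.  Coordinates are 1-based inclusive;
    begin > end encodes the minus strand; intron 0/0 means no intron.
    """
    genes = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise ValueError(f"{path}:{lineno}: expected >= 9 tab-separated columns, got {len(fields)}")
        try:
            name = fields[0].strip()
            num = int(fields[1])
            begin, end = int(fields[2]), int(fields[3])
            isotype = fields[4].strip()
            anticodon = fields[5].strip()
            ib, ie = int(fields[6]), int(fields[7])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
        if begin <= end:
            strand = "+"
            start, stop = begin - 1, end
        else:
            strand = "-"
            start, stop = end - 1, begin
        loc = GenomicInterval(name, start, stop, strand)
        introns = []
        if ib != 0 or ie != 0:
            lo, hi = min(ib, ie), max(ib, ie)
            introns.append(GenomicInterval(name, lo - 1, hi, strand))
        genes.append(
            TrnaGene(id=f"{name}.trna{num}", location=loc, isotype=isotype,
                     anticodon=anticodon, intron_spans=introns)
        )
    return genes


def write_trnascan_tabular(path, genes: List[TrnaGene]) -> None:
    """Write tRNA genes in tRNAscan-SE-style tabular layout (3 header lines)."""
    with open(path, "w") as fh:
        fh.write("Sequence\t\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\tCove\n")
        fh.write("Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n")
        fh.write("--------\t------\t-----\t---\t----\t-----\t-----\t----\t-----\n")
        for g in genes:
            loc = g.location
            if loc.strand == "+":
                begin, end = loc.start + 1, loc.end
            else:
                begin, end = loc.end, loc.start + 1
            num = g.id.rsplit("trna", 1)[-1] if "trna" in g.id else "1"
            ib = ie = 0
            if g.intron_spans:
                iv = g.intron_spans[0]
                if loc.strand == "+":
                    ib, ie = iv.start + 1, iv.end
                else:
                    ib, ie = iv.end, iv.start + 1
            fh.write(
                f"{loc.contig}\t{num}\t{begin}\t{end}\t{g.isotype}\t{g.anticodon}\t{ib}\t{ie}\t50.0\n"
            )


# ---------------------------------------------------------------------------
# BLAST outfmt 6

def read_blast_tabular(path, e_cutoff: float = 1e-15) -> List[HomologyHit]:
    """Read a 12-column BLAST tabular file, dropping hits with e >= e_cutoff.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Subject coordinates with sstart > send
    are reported on the minus strand.
    """
    hits = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(f)}")
            try:
                evalue = float(f[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric e-value {f[10]!r}") from exc
            if evalue >= e_cutoff:
                n_dropped += 1
                continue
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            if sstart <= send:
                subj = GenomicInterval(f[1], sstart - 1, send, "+")
            else:
                subj = GenomicInterval(f[1], send - 1, sstart, "-")
            hits.append(
                HomologyHit(
                    query=f[0],
                    subject=subj,
                    query_span=(min(qstart, qend) - 1, max(qstart, qend)),
                    percent_identity=float(f[2]),
                    score=float(f[11]),
                    e_value=evalue,
                )
            )
    if n_dropped:
        log.info("discarded %d hits with e-value >= %g from %s", n_dropped, e_cutoff, path)
    return hits


# ---------------------------------------------------------------------------
# GFF3 / BED

def write_gff3(path, features, source: str = "retrotarget") -> None:
    """Write (interval, type, attrs) triples as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, ftype, attrs in features:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                f"{iv.contig}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attr_str}\n"
            )


def read_gff3(path) -> List[Tuple[GenomicInterval, str, dict]]:
    """Read GFF3 rows as (interval, type, attrs); converts to 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(f)}")
            start1, end1 = int(f[3]), int(f[4])
            if start1 > end1:
                raise ValueError(f"{path}:{lineno}: GFF3 start {start1} > end {end1}")
            strand = f[6] if f[6] in ("+", "-") else "+"
            attrs = {}
            if f[8] and f[8] != ".":
                for part in f[8].split(";"):
                    if "=" in part:
                        k, v = part.split("=", 1)
                        attrs[k] = v
            out.append((GenomicInterval(f[0], start1 - 1, end1, strand), f[2], attrs))
    return out


def write_bed(path, features) -> None:
    """Write (interval, name) pairs as 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv, name in features:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path) -> List[Tuple[GenomicInterval, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            name = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "+"
            out.append((GenomicInterval(f[0], int(f[1]), int(f[2]), strand), name))
    return out


# ---------------------------------------------------------------------------
# Alignments and trees

def read_alignment(path) -> List[Tuple[str, str]]:
    """Read an aligned FASTA or Clustal file as (id, row) pairs.

    The format is detected from the first line ("CLUSTAL" header vs ">").
    Rows of unequal length raise ``ValueError``.
    """
    with open(path) as fh:
        first = fh.readline()
    fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    rows = [(rec.id, str(rec.seq).upper()) for rec in aln]
    lengths = {len(s) for _, s in rows}
    if len(lengths) > 1:
        raise ValueError(f"alignment rows of unequal length in {path}: {sorted(lengths)}")
    return rows


def write_newick(path, tree) -> None:
    """Write a dendropy tree as newick, supports as internal node labels."""
    s = tree.as_string(schema="newick", suppress_rooting=True)
    with open(path, "w") as fh:
        fh.write(s if s.endswith("\n") else s + "\n")
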