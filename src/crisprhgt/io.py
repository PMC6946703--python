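"""Format handling: FASTA, FASTQ, GFF3 and the pipeline's TSV tables.

FASTA goes through Biopython.  FASTQ is parsed by a strict 4-line reader so
that truncated records can be reported with a line number (amplicon FASTQ
from the simulator always uses constant Phred+33 qualities).  GFF3 is read
into a flat feature list with the 1-based closed convention converted to
0-based half-open at this boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ReferenceSeq, ROLE_DONOR


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str, role: str = ROLE_DONOR) -> list[ReferenceSeq]:
    """Read a FASTA file into ReferenceSeq records (ids whitespace-truncated)."""
    refs = []
    for rec in SeqIO.parse(path, "fasta"):
        refs.append(ReferenceSeq(id=rec.id, seq=str(rec.seq).upper(), role=role))
    return refs


def write_fasta(path: str, refs: Iterable[ReferenceSeq], width: int = 70) -> None:
    records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in refs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# FASTQ

@dataclass(frozen=True)
class FastqRead:
    id: str
    seq: str
    qual: str


def read_fastq(path: str) -> list[FastqRead]:
    return list(iter_fastq(path))


def iter_fastq(path: str) -> Iterator[FastqRead]:
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header:
                continue
            if not header.startswith("@"):
                raise ParseError(f"{path}:{lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual or not plus.startswith("+"):
                raise ParseError(f"{path}:{lineno}: truncated FASTQ record starting at line {lineno}")
            lineno += 3
            if len(seq) != len(qual):
                raise ParseError(f"{path}:{lineno}: sequence/quality length mismatch for record at line {lineno - 3}")
            yield FastqRead(id=header[1:].split()[0], seq=seq.upper(), qual=qual)


def write_fastq(path: str, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_reads(path: str) -> list[FastqRead]:
    """Read amplicon reads from FASTQ or FASTA (by extension)."""
    if path.endswith((".fasta", ".fa", ".fna")):
        return [FastqRead(id=r.id, seq=r.seq, qual="I" * len(r.seq)) for r in read_fasta(path)]
    return read_fastq(path)


# ---------------------------------------------------------------------------
# GFF3

@dataclass(frozen=True)
class GffFeature:
    ref_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    ftype: str
    category: str


def read_gff3(path: str, category_keys: tuple[str, ...] = ("category", "product")) -> tuple[list[GffFeature], int]:
    """Parse a GFF3 file into features; returns (features, n_malformed_skipped).

    The category of a feature is taken from the first attribute key in
    ``category_keys`` that is present, else "unannotated".
    """
    feats: list[GffFeature] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                n_bad += 1
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            try:
                start0 = int(start) - 1
                end0 = int(end)
            except ValueError:
                n_bad += 1
                continue
            if start0 < 0 or end0 <= start0:
                n_bad += 1
                continue
            attr_map = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            category = "unannotated"
            for key in category_keys:
                if key in attr_map:
                    category = attr_map[key]
                    break
            feats.append(GffFeature(seqid, start0, end0, strand, ftype, category))
    return feats, n_bad


# ---------------------------------------------------------------------------
# TSV helpers

def write_tsv(path: str, header: list[str], rows: Iterable[Iterable]) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path: str) -> tuple[list[str], list[list[str]]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.rstrip("\n")]
    if not lines:
        raise ParseError(f"{path}: empty TSV")
    header = lines[0].split("\t")
    return header, [ln.split("\t") for ln in lines[1:]]
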