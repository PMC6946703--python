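"""Gapless seed-and-extend matcher for short queries against reference sets.

The matching primitive used throughout: exact k-mer seeds anchor candidate
diagonals on either strand; on each seeded diagonal the best-scoring gapless
segment (match +1, mismatch -1; ties broken by longer segment, then leftmost)
is taken as that diagonal's alignment.  Identity is matches over aligned
query columns, coverage is aligned query length over query length, both as
percentages.  Indel-tolerant extension is intentionally absent by default:
at spacer lengths (~33 nt) the gapless approximation is oracle-checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .model import MatchHit, ReferenceSeq, revcomp


@dataclass(frozen=True)
class Alignment:
    ref_id: str
    start: int      # reference, 0-based half-open, forward strand
    end: int
    strand: str
    qstart: int     # original query orientation, 0-based half-open
    qend: int
    matches: int
    length: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length

    def coverage(self, qlen: int) -> float:
        return 100.0 * self.length / qlen

    @property
    def score(self) -> int:
        return 2 * self.matches - self.length


def best_segment(values: list[int]) -> Optional[tuple[int, int, int]]:
    """Best-scoring contiguous segment of +1/-1 values.

    Maximizes (sum, length), preferring the leftmost on full ties; returns
    (start, end, score) with end exclusive, or None for empty input.
    Linear scan over prefix sums tracking the earliest minimum prefix.
    """
    if not values:
        return None
    best: Optional[tuple[int, int, int]] = None  # (score, length, start)
    prefix = 0
    min_prefix, min_idx = 0, 0
    for i, v in enumerate(values, start=1):
        prefix += v
        score = prefix - min_prefix
        length = i - min_idx
        cand = (score, length, min_idx)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
        if prefix < min_prefix:
            min_prefix, min_idx = prefix, i
    score, length, start = best
    return start, start + length, score


class ReferenceIndex:
    """Exact k-mer position index over a set of references."""

    def __init__(self, refs: Iterable[ReferenceSeq], k: int):
        self.k = k
        self.refs = list(refs)
        self.by_id = {r.id: r for r in self.refs}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for r in self.refs:
            seq = r.seq
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((r.id, i))

    def seed_diagonals(self, query: str) -> dict[str, set[int]]:
        """Per-reference set of diagonal offsets (ref_pos - query_pos)."""
        k = self.k
        diags: dict[str, set[int]] = {}
        for qpos in range(len(query) - k + 1):
            for ref_id, rpos in self.index.get(query[qpos:qpos + k], ()):
                diags.setdefault(ref_id, set()).add(rpos - qpos)
        return diags


def _batch_diagonal_alignments(oriented: str, ref: ReferenceSeq, offsets: list[int],
                               strand: str, qlen: int) -> list[Alignment]:
    """Best gapless segment on every given diagonal, vectorized.

    Implements exactly the ``best_segment`` convention (max score, then max
    length, then leftmost) via prefix sums over all (start, end) pairs.
    """
    qa = np.frombuffer(oriented.encode(), dtype=np.uint8)
    ra = np.frombuffer(ref.seq.encode(), dtype=np.uint8)
    L = qa.size
    n = ra.size
    offs = np.asarray(offsets, dtype=np.int64)
    pos = offs[:, None] + np.arange(L)[None, :]
    valid = (pos >= 0) & (pos < n)
    vals = np.full(pos.shape, -4 * L, dtype=np.int64)
    match = np.where(qa[None, :] == ra[np.clip(pos, 0, n - 1)], 1, -1)
    vals[valid] = match[valid]
    prefix = np.zeros((offs.size, L + 1), dtype=np.int64)
    np.cumsum(vals, axis=1, out=prefix[:, 1:])
    # running minimum of the prefix with its EARLIEST index, encoded so a
    # single maximum.accumulate carries both (smaller prefix wins, then
    # smaller index); decodes back to (min value, argmin).
    shift = 4 * L * L + L + 1
    comp = (shift - prefix) * (L + 2) + (L + 1 - np.arange(L + 1))[None, :]
    comp = np.maximum.accumulate(comp, axis=1)
    min_prefix = shift - comp // (L + 2)
    argmin = L + 1 - comp % (L + 2)
    # candidate segment ending at i: [argmin[:, i-1], i)
    ends = np.arange(1, L + 1)
    sc_all = prefix[:, 1:] - min_prefix[:, :-1]
    starts = argmin[:, :-1]
    lens = ends[None, :] - starts
    key = sc_all * 10000 + lens * 100 + (L - ends)[None, :]
    best_i = key.argmax(axis=1)
    d = np.arange(offs.size)
    sc = sc_all[d, best_i]
    a = starts[d, best_i]
    b = best_i + 1
    out: list[Alignment] = []
    for i in np.flatnonzero(sc > 0):
        a_qs, a_qe = int(a[i]), int(b[i])
        length = a_qe - a_qs
        matches = (int(sc[i]) + length) // 2
        if strand == "+":
            oqs, oqe = a_qs, a_qe
        else:  # query was reverse-complemented before seeding
            oqs, oqe = qlen - a_qe, qlen - a_qs
        out.append(Alignment(ref_id=ref.id, start=a_qs + int(offs[i]),
                             end=a_qe + int(offs[i]), strand=strand,
                             qstart=oqs, qend=oqe, matches=matches, length=length))
    return out


def candidate_alignments(query: str, index: ReferenceIndex) -> list[Alignment]:
    """All per-seeded-diagonal best alignments of a query, both strands."""
    out: list[Alignment] = []
    qlen = len(query)
    for strand, oriented in (("+", query), ("-", revcomp(query))):
        for ref_id, offsets in index.seed_diagonals(oriented).items():
            ref = index.by_id[ref_id]
            out.extend(_batch_diagonal_alignments(oriented, ref, sorted(offsets),
                                                  strand, qlen))
    return out


def best_local_match(query: str, db: Iterable[ReferenceSeq], seed_k: int,
                     index: Optional[ReferenceIndex] = None) -> Optional[MatchHit]:
    """Best hit of a query against a database, or None.

    The winner maximizes alignment score (matches - mismatches), ties going
    to the longer alignment, then lowest reference id, lowest reference
    start, '+' strand — i.e. the gapless Smith-Waterman optimum over seeded
    diagonals.  (Score and length together determine identity and coverage,
    so tie winners report identical percentages.)  Pass a prebuilt
    ``ReferenceIndex`` to amortize indexing over many queries.
    """
    refs = list(db)
    if not refs or len(query) < seed_k:
        return None
    if index is None or index.k != seed_k:
        index = ReferenceIndex(refs, seed_k)
    qlen = len(query)
    best: Optional[Alignment] = None
    for aln in candidate_alignments(query, index):
        if best is None:
            best = aln
            continue
        key = (aln.score, aln.length)
        bkey = (best.score, best.length)
        if key > bkey or (key == bkey and
                          (aln.ref_id, aln.start, aln.strand) <
                          (best.ref_id, best.start, best.strand)):
            best = aln
    if best is None:
        return None
    return _to_hit("query", best, qlen, index)


def _to_hit(spacer_id: str, aln: Alignment, qlen: int, index: ReferenceIndex) -> MatchHit:
    return MatchHit(
        spacer_id=spacer_id, ref_id=aln.ref_id, start=aln.start, end=aln.end,
        strand=aln.strand, identity=aln.identity, coverage=aln.coverage(qlen),
        qstart=aln.qstart, qend=aln.qend, qlen=qlen,
        slen=len(index.by_id[aln.ref_id].seq),
        n_mismatch=aln.length - aln.matches,
    )


def all_matches(spacer_id: str, query: str, index: ReferenceIndex,
                min_identity: float, min_coverage: float) -> list[MatchHit]:
    """Every threshold-passing alignment of one query (all refs, both strands)."""
    qlen = len(query)
    hits: dict[tuple, MatchHit] = {}
    for aln in candidate_alignments(query, index):
        if aln.identity >= min_identity and aln.coverage(qlen) >= min_coverage:
            key = (aln.ref_id, aln.start, aln.end, aln.strand)
            if key not in hits:
                hits[key] = _to_hit(spacer_id, aln, qlen, index)
    return sorted(hits.values(), key=lambda h: (h.ref_id, h.start, h.end, h.strand))
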