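"""Independent brute-force oracles used to verify the package's fast paths.

Everything here is deliberately naive: exhaustive scans and enumeration,
kept separate from the implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def hamming_scan(read: str, repeat: str, max_mismatch: int) -> list[tuple[int, int]]:
    """Greedy left-to-right non-overlapping Hamming occurrences, naive scan."""
    m = len(repeat)
    out = []
    last_end = 0
    for s in range(len(read) - m + 1):
        if s < last_end:
            continue
        d = sum(a != b for a, b in zip(read[s:s + m], repeat))
        if d <= max_mismatch:
            out.append((s, s + m))
            last_end = s + m
    return out


def best_segment_bruteforce(values: list[int]) -> tuple[int, int, int] | None:
    """Max-sum segment, ties to longer then leftmost, by O(L^2) enumeration."""
    best = None
    for i in range(len(values)):
        total = 0
        for j in range(i + 1, len(values) + 1):
            total += values[j - 1]
            cand = (total, j - i, -i)
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    total, length, neg_i = best
    return -neg_i, -neg_i + length, total


def sw_gapless_best(query: str, refs: dict[str, str]) -> tuple[float, float] | None:
    """Exhaustive gapless Smith-Waterman (match +1, mismatch -1) best hit.

    Considers every diagonal of every reference on both strands, takes each
    diagonal's maximum-scoring segment (ties: longer, then leftmost), and
    returns the (identity, coverage) of the globally maximum-scoring
    candidate (ties to the longer; score and length jointly determine both
    percentages, so any remaining tie is value-identical).  Fully
    enumerative, vectorized over all (diagonal, segment start, segment end)
    triples with numpy; independent of the package's seed-and-extend path.
    """
    qlen = len(query)
    best_key = None
    best = None
    pad = -4 * qlen  # any segment touching padding goes negative
    idx = np.arange(qlen + 1)
    seg_len = idx[None, :] - idx[:, None]  # seg_len[a, b] = b - a
    left_bonus = (qlen - idx)[None, :, None]
    for strand, q in (("+", query), ("-", rc(query))):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        for ref_id in sorted(refs):
            ra = np.frombuffer(refs[ref_id].encode(), dtype=np.uint8)
            n = ra.size
            offs = np.arange(-qlen + 1, n)
            pos = offs[:, None] + np.arange(qlen)[None, :]
            valid = (pos >= 0) & (pos < n)
            vals = np.full(pos.shape, pad, dtype=np.int64)
            match = np.where(qa[None, :] == ra[np.clip(pos, 0, n - 1)], 1, -1)
            vals[valid] = match[valid]
            prefix = np.zeros((offs.size, qlen + 1), dtype=np.int64)
            np.cumsum(vals, axis=1, out=prefix[:, 1:])
            score = prefix[:, None, :] - prefix[:, :, None]  # [d, a, b] = sum[a:b)
            key = np.where(seg_len[None] > 0,
                           score * 10000 + seg_len[None] * 100 + left_bonus,
                           np.iinfo(np.int64).min)
            flat = key.reshape(offs.size, -1).argmax(axis=1)
            a = flat // (qlen + 1)
            b = flat % (qlen + 1)
            d = np.arange(offs.size)
            sc = score[d, a, b]
            length = b - a
            ok = (sc > 0) & (length > 0)
            if not ok.any():
                continue
            matches = (sc[ok] + length[ok]) // 2
            identity = 100.0 * matches / length[ok]
            coverage = 100.0 * length[ok] / qlen
            rank = sc[ok] * 100.0 + length[ok]
            j = int(rank.argmax())
            if best_key is None or rank[j] > best_key:
                best_key = rank[j]
                best = (float(identity[j]), float(coverage[j]))
    return best


def substring_hits(query: str, refs: dict[str, str]) -> set[tuple[str, int, int, str]]:
    """All exact-substring occurrences of query (both strands), naive scan."""
    out = set()
    for ref_id, seq in refs.items():
        for strand, q in (("+", query), ("-", rc(query))):
            start = seq.find(q)
            while start != -1:
                out.add((ref_id, start, start + len(q), strand))
                start = seq.find(q, start + 1)
    return out


def min_cover_size(sets_by_ref: dict[str, set[str]]) -> int:
    """Cardinality of the optimum set cover by subset enumeration."""
    universe = set().union(*sets_by_ref.values())
    refs = sorted(sets_by_ref)
    for size in range(1, len(refs) + 1):
        for combo in combinations(refs, size):
            if set().union(*(sets_by_ref[r] for r in combo)) == universe:
                return size
    return len(refs)


def shared_kmers(a: str, b: str, k: int) -> set[str]:
    """k-mer set intersection of two sequences (forward orientation only)."""
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    return ka & kb
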