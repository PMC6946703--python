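"""Parse amplicon reads into spacer arrays and call expansions.

Repeats are located by Hamming distance (fixed-length direct repeats), the
substrings strictly between consecutive repeat occurrences become spacers,
and an array is expanded when spacers precede the first parental spacer.
"""

from __future__ import annotations

import numpy as np

from .model import ExpansionSummary, ParsedArray, revcomp

DEFAULT_MAX_MISMATCH = 2
DEFAULT_SPACER_BOUNDS = (25, 45)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def find_repeats(read_seq: str, repeat_seq: str, max_mismatch: int = DEFAULT_MAX_MISMATCH
                 ) -> list[tuple[int, int]]:
    """All greedy left-to-right non-overlapping repeat occurrences.

    An occurrence is a window at Hamming distance <= ``max_mismatch`` from
    ``repeat_seq``; an accepted occurrence excludes any window overlapping
    it.  Returns 0-based half-open intervals sorted by start.
    """
    if not repeat_seq:
        raise ValueError("repeat_seq must be non-empty")
    if max_mismatch >= len(repeat_seq) / 2:
        raise ValueError("max_mismatch must be < len(repeat_seq)/2")
    m = len(repeat_seq)
    n = len(read_seq)
    if n < m:
        return []
    read = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    rep = np.frombuffer(repeat_seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(read, m)
    mismatches = (windows != rep).sum(axis=1)
    candidates = np.flatnonzero(mismatches <= max_mismatch)
    out: list[tuple[int, int]] = []
    last_end = 0
    for s in candidates:
        if s >= last_end:
            out.append((int(s), int(s) + m))
            last_end = int(s) + m
    return out


def extract_spacers(read_seq: str, repeat_seq: str,
                    max_mismatch: int = DEFAULT_MAX_MISMATCH,
                    spacer_len_bounds: tuple[int, int] = DEFAULT_SPACER_BOUNDS,
                    read_id: str = "", reverse_complement: bool = False) -> ParsedArray:
    """Decompose one read into ordered spacers between repeat occurrences.

    Between-repeat gaps outside ``spacer_len_bounds`` are dropped and the
    array is marked malformed; fewer than two repeats yields status
    no_repeat / single_repeat with no spacers.
    """
    if reverse_complement:
        read_seq = revcomp(read_seq)
    repeats = find_repeats(read_seq, repeat_seq, max_mismatch)
    parsed = ParsedArray(read_id=read_id, n_repeats=len(repeats))
    if len(repeats) == 0:
        parsed.status = "no_repeat"
        return parsed
    if len(repeats) == 1:
        parsed.status = "single_repeat"
        return parsed
    lo, hi = spacer_len_bounds
    malformed = False
    for (s1, e1), (s2, e2) in zip(repeats, repeats[1:]):
        gap = read_seq[e1:s2]
        if lo <= len(gap) <= hi:
            parsed.spacers.append(gap)
        else:
            malformed = True
    parsed.status = "malformed" if (malformed or not parsed.spacers) else "ok"
    return parsed


def call_expansion(parsed: ParsedArray, parental_spacers: list[str],
                   parental_match_max_mismatch: int = 2) -> ParsedArray:
    """Fill is_expanded / new_spacers by anchoring on the first parental spacer.

    Spacers before the first occurrence of parental_spacers[0] (Hamming
    <= parental_match_max_mismatch, equal length) are new.  Arrays with no
    recognizable parental anchor are excluded (status becomes malformed).
    """
    if parsed.status != "ok":
        return parsed
    anchor = parental_spacers[0]
    anchor_idx = None
    for i, sp in enumerate(parsed.spacers):
        if len(sp) == len(anchor) and hamming(sp, anchor) <= parental_match_max_mismatch:
            anchor_idx = i
            break
    if anchor_idx is None:
        parsed.status = "malformed"
        parsed.is_expanded = False
        parsed.new_spacers = []
        return parsed
    parsed.new_spacers = list(parsed.spacers[:anchor_idx])
    parsed.is_expanded = anchor_idx >= 1
    return parsed


def summarize_expansion(parsed_arrays: list[ParsedArray], sample_id: str = "sample"
                        ) -> ExpansionSummary:
    """Expansion statistics over status=ok arrays of one sample."""
    ok = [p for p in parsed_arrays if p.status == "ok"]
    if not ok:
        raise ValueError(f"sample '{sample_id}': no well-formed arrays; sample unusable")
    n_exp = sum(1 for p in ok if p.is_expanded)
    n_new = sum(len(p.new_spacers) for p in ok)
    return ExpansionSummary(
        sample_id=sample_id,
        n_arrays_total=len(ok),
        n_arrays_expanded=n_exp,
        percent_expanded=100.0 * n_exp / len(ok),
        n_new_spacers=n_new,
    )


def parse_sample(reads, repeat_seq: str, parental_spacers: list[str],
                 max_mismatch: int = DEFAULT_MAX_MISMATCH,
                 spacer_len_bounds: tuple[int, int] = DEFAULT_SPACER_BOUNDS,
                 parental_match_max_mismatch: int = 2,
                 reverse_complement: bool = False) -> list[ParsedArray]:
    """Extract and expansion-call every read of a sample."""
    out = []
    for r in reads:
        parsed = extract_spacers(r.seq, repeat_seq, max_mismatch, spacer_len_bounds,
                                 read_id=r.id, reverse_complement=reverse_complement)
        out.append(call_expansion(parsed, parental_spacers, parental_match_max_mismatch))
    return out
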