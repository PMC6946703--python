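"""Quantitative read-outs over filtered spacer hits.

Normalized spacer mapping (spacers per kb of reference per 1000 exogenous
spacers), 200-bp window coverage, sample-level HGT calls, minimal covering
reference sets, PAM context summaries, annotation-category tables and
metagenome/plasmid provenance categories.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io import GffFeature
from .model import (
    CoverSet,
    MappingProfile,
    MatchHit,
    PamSummary,
    ReferenceSeq,
    SampleCall,
    revcomp,
)

DEFAULT_CONTROL_PERCENT = 0.03
DEFAULT_MIN_SPACERS = 10
DEFAULT_FOLD = 3.0
DEFAULT_WINDOW = 200


def normalized_spacer_mapping(hits: Sequence[MatchHit],
                              ref_len_by_id: Mapping[str, int],
                              total_exogenous: int) -> list[MappingProfile]:
    """Per-reference normalized spacer mapping.

    value = (n_spacers / (ref_len/1000)) / (total_exogenous/1000), where a
    spacer counts once per (spacer, reference) pair.  Every reference in
    ``ref_len_by_id`` is reported, zero-spacer references flagged explicitly.
    """
    if total_exogenous < 1:
        raise ValueError("total_exogenous must be >= 1")
    pairs = {(h.spacer_id, h.ref_id) for h in hits}
    n_by_ref = Counter(ref_id for _, ref_id in pairs)
    profiles = []
    for ref_id, ref_len in ref_len_by_id.items():
        if ref_len <= 0:
            raise ValueError(f"reference '{ref_id}' has non-positive length")
        n = n_by_ref.get(ref_id, 0)
        value = (n / (ref_len / 1000.0)) / (total_exogenous / 1000.0)
        profiles.append(MappingProfile(ref_id=ref_id, ref_len=ref_len, n_spacers=n,
                                       normalized_spacer_mapping=value, is_zero=(n == 0)))
    return profiles


def window_coverage(hits: Sequence[MatchHit], ref_len: int,
                    window: int = DEFAULT_WINDOW
                    ) -> list[tuple[tuple[int, int], float]]:
    """Mean per-base hit depth in fixed windows tiling [0, ref_len).

    Depth at a base is the number of hit intervals covering it; the final
    partial window is averaged over its own length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    depth = np.zeros(ref_len + 1)
    for h in hits:
        depth[max(h.start, 0)] += 1
        depth[min(h.end, ref_len)] -= 1
    depth = np.cumsum(depth[:-1])
    out = []
    for ws in range(0, ref_len, window):
        we = min(ws + window, ref_len)
        out.append(((ws, we), float(depth[ws:we].mean())))
    return out


def call_sample(sample_id: str, n_arrays: int, percent_exogenous: float,
                n_unique_exogenous: int,
                control_percent: float = DEFAULT_CONTROL_PERCENT,
                min_spacers: int = DEFAULT_MIN_SPACERS,
                fold: float = DEFAULT_FOLD) -> SampleCall:
    """Binary sample-level HGT decision.

    Positive iff at least ``min_spacers`` unique exogenous spacers were
    identified AND the exogenous percentage is at least ``fold`` times the
    no-donor control percentage.
    """
    if control_percent < 0:
        raise ValueError("control_percent must be >= 0")
    effective = fold * control_percent
    positive = (n_unique_exogenous >= min_spacers) and (percent_exogenous >= effective)
    return SampleCall(sample_id=sample_id, n_arrays=n_arrays,
                      percent_exogenous=percent_exogenous,
                      n_unique_exogenous=n_unique_exogenous,
                      control_percent=control_percent, min_spacers=min_spacers,
                      fold=fold, is_hgt_positive=positive,
                      effective_threshold=effective)


def _spacers_by_ref(hits: Sequence[MatchHit]) -> dict[str, set[str]]:
    by_ref: dict[str, set[str]] = {}
    for h in hits:
        by_ref.setdefault(h.ref_id, set()).add(h.spacer_id)
    return by_ref


def minimal_covering_set(hits: Sequence[MatchHit],
                         ref_len_by_id: Optional[Mapping[str, int]] = None,
                         method: str = "greedy") -> CoverSet:
    """Smallest reference set whose hits encompass all hit spacers.

    Greedy set cover by default: repeatedly take the reference covering the
    most uncovered spacers (ties to the longer reference when lengths are
    supplied, then lexicographic id).  Each spacer is assigned to the
    reference that first covered it; rows are re-sorted by assigned-spacer
    count descending for presentation.  ``method='exact'`` brute-forces the
    optimum (intended for <= 20 candidate references).
    """
    by_ref = _spacers_by_ref(hits)
    if not by_ref:
        return CoverSet(rows=[], uncovered_spacers=0)
    lengths = ref_len_by_id or {}

    if method == "exact":
        chosen = _exact_cover(by_ref)
    elif method == "greedy":
        chosen = _greedy_cover(by_ref, lengths)
    else:
        raise ValueError(f"unknown cover method '{method}'")

    covered: set[str] = set()
    assigned: list[tuple[str, int]] = []
    for ref_id in chosen:
        new = by_ref[ref_id] - covered
        assigned.append((ref_id, len(new)))
        covered |= new
    assigned.sort(key=lambda t: (-t[1], t[0]))
    rows, cum = [], 0
    for ref_id, n in assigned:
        cum += n
        rows.append((ref_id, n, cum))
    return CoverSet(rows=rows, uncovered_spacers=0)


def _greedy_cover(by_ref: dict[str, set[str]], lengths: Mapping[str, int]) -> list[str]:
    uncovered = set().union(*by_ref.values())
    chosen: list[str] = []
    while uncovered:
        best = min(by_ref, key=lambda r: (-len(by_ref[r] & uncovered),
                                          -lengths.get(r, 0), r))
        gain = by_ref[best] & uncovered
        if not gain:  # pragma: no cover - uncovered is union of sets
            break
        chosen.append(best)
        uncovered -= gain
    return chosen


def _exact_cover(by_ref: dict[str, set[str]]) -> list[str]:
    universe = set().union(*by_ref.values())
    refs = sorted(by_ref)
    for size in range(1, len(refs) + 1):
        for combo in combinations(refs, size):
            if set().union(*(by_ref[r] for r in combo)) == universe:
                return list(combo)
    return refs  # pragma: no cover


def pam_summary(hits: Sequence[MatchHit], refs: Iterable[ReferenceSeq]) -> PamSummary:
    """Upstream trinucleotide (PAM context) counts over hits.

    The context is the 3 nt immediately 5' of the protospacer on the
    protospacer strand: ref[start-3:start] for '+' hits, the reverse
    complement of ref[end:end+3] for '-' hits.  Hits within 3 nt of the
    reference end are skipped and counted as inextractable.
    """
    by_id = {r.id: r.seq for r in refs}
    counts: Counter[str] = Counter()
    skipped = 0
    for h in hits:
        seq = by_id[h.ref_id]
        if h.strand == "+":
            if h.start < 3:
                skipped += 1
                continue
            pam = seq[h.start - 3:h.start]
        else:
            if h.end + 3 > len(seq):
                skipped += 1
                continue
            pam = revcomp(seq[h.end:h.end + 3])
        counts[pam] += 1
    n = sum(counts.values())
    aag = counts.get("AAG", 0) / n if n else 0.0
    return PamSummary(counts=dict(counts), aag_fraction=aag,
                      n_extractable=n, n_skipped=skipped)


def annotate_hits(hits: Sequence[MatchHit], features: Sequence[GffFeature]
                  ) -> list[tuple[str, int]]:
    """Counts per annotation category over hits.

    A hit overlapping (>= 1 bp) an ORF inherits that ORF's category; a hit
    overlapping several ORFs counts once per ORF; a hit overlapping none
    counts as 'intergenic'.  Returned sorted by count descending.
    """
    by_ref: dict[str, list[GffFeature]] = {}
    for f in features:
        by_ref.setdefault(f.ref_id, []).append(f)
    counts: Counter[str] = Counter()
    for h in hits:
        overlapped = [f for f in by_ref.get(h.ref_id, ())
                      if f.start < h.end and h.start < f.end]
        if not overlapped:
            counts["intergenic"] += 1
        else:
            for f in overlapped:
                counts[f.category] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


PROVENANCE_CATEGORIES = ("metagenome_only", "both", "plasmid_only", "unmatched")


def categorize_provenance(metagenome_hits: Sequence[MatchHit],
                          plasmid_hits: Sequence[MatchHit],
                          spacer_ids: Iterable[str]
                          ) -> tuple[dict[str, str], dict[str, float]]:
    """Per-spacer provenance category and the per-sample percentage table.

    Categories partition the given unique exogenous spacers; percentages
    are over all of them and sum to 100 (when any spacers are given).
    """
    in_meta = {h.spacer_id for h in metagenome_hits}
    in_plasmid = {h.spacer_id for h in plasmid_hits}
    cats: dict[str, str] = {}
    for sid in spacer_ids:
        if sid in in_meta and sid in in_plasmid:
            cats[sid] = "both"
        elif sid in in_meta:
            cats[sid] = "metagenome_only"
        elif sid in in_plasmid:
            cats[sid] = "plasmid_only"
        else:
            cats[sid] = "unmatched"
    n = len(cats)
    table = {c: (100.0 * sum(1 for v in cats.values() if v == c) / n if n else 0.0)
             for c in PROVENANCE_CATEGORIES}
    return cats, table
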