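"""Endogenous/exogenous classification of new spacers and dereplication.

A spacer is endogenous when it has a hit with >= 80% identity AND >= 80%
query coverage against the recorder references (genome + recording
plasmid).  Matching runs in two passes: a seed length of 8, then a rescue
pass at seed length 5 for spacers with no pass-1 candidate.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional, Sequence

from .align import ReferenceIndex, all_matches, best_local_match
from .model import ConfigurationError, MatchHit, ReferenceSeq, SpacerRecord

DEFAULT_ID_THRESHOLD = 80.0
DEFAULT_COV_THRESHOLD = 80.0
PASS1_SEED = 8
PASS2_SEED = 5


def two_step_endogenous_filter(spacers: Sequence[SpacerRecord],
                               recorder_db: Iterable[ReferenceSeq],
                               id_threshold: float = DEFAULT_ID_THRESHOLD,
                               cov_threshold: float = DEFAULT_COV_THRESHOLD,
                               seed_pass1: int = PASS1_SEED,
                               seed_pass2: int = PASS2_SEED) -> list[SpacerRecord]:
    """Classify each spacer endogenous/exogenous against the recorder.

    Pass 1 seeds at length ``seed_pass1``; spacers with no qualifying pass-1
    hit are re-queried at ``seed_pass2`` (rescue pass).  Endogenous requires
    a hit with identity AND coverage at or above the thresholds — ANY such
    hit suffices, not only the best-scoring one; everything else is
    exogenous.
    """
    for name, t in (("id_threshold", id_threshold), ("cov_threshold", cov_threshold)):
        if not (0.0 < t <= 100.0):
            raise ConfigurationError(f"{name}={t} outside (0, 100]")
    refs = list(recorder_db)
    if not refs:
        raise ConfigurationError("recorder database is empty")
    idx1 = ReferenceIndex(refs, seed_pass1)
    idx2 = ReferenceIndex(refs, seed_pass2)
    out: list[SpacerRecord] = []
    for rec in spacers:
        qualifying = all_matches(rec.spacer_id, rec.sequence, idx1,
                                 id_threshold, cov_threshold)
        if not qualifying:
            qualifying = all_matches(rec.spacer_id, rec.sequence, idx2,
                                     id_threshold, cov_threshold)
        classification = "endogenous" if qualifying else "exogenous"
        if qualifying:
            hit: Optional[MatchHit] = max(
                qualifying, key=lambda h: h.aligned_len - 2 * h.n_mismatch)
        else:
            # diagnostic best recorder hit for sub-threshold spacers; the
            # cheap pass-1 seeding is enough for reporting purposes
            hit = best_local_match(rec.sequence, refs, seed_pass1, index=idx1)
        out.append(SpacerRecord(
            spacer_id=rec.spacer_id, sequence=rec.sequence, abundance=rec.abundance,
            sample_id=rec.sample_id, classification=classification,
            best_identity=hit.identity if hit else None,
            best_coverage=hit.coverage if hit else None,
        ))
    return out


def dereplicate(spacers: Iterable[SpacerRecord], sample_id: str = "") -> list[SpacerRecord]:
    """Exact-sequence dereplication (case-insensitive, strands not collapsed).

    Output is ordered by descending abundance then sequence; spacer ids are
    u<rank> over that order.  Classification is carried through when all
    members of a group agree.
    """
    counts: Counter[str] = Counter()
    classes: dict[str, set[str]] = {}
    for rec in spacers:
        seq = rec.sequence.upper()
        counts[seq] += rec.abundance
        classes.setdefault(seq, set()).add(rec.classification)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    for i, (seq, n) in enumerate(ordered):
        cls = classes[seq]
        out.append(SpacerRecord(
            spacer_id=f"u{i:06d}", sequence=seq, abundance=n, sample_id=sample_id,
            classification=cls.pop() if len(cls) == 1 else "unclassified",
        ))
    return out


def records_from_sequences(seqs: Iterable[str], sample_id: str = "") -> list[SpacerRecord]:
    """Wrap raw spacer sequences (one per supporting read) as records."""
    return [SpacerRecord(spacer_id=f"s{i:06d}", sequence=s.upper(), abundance=1,
                         sample_id=sample_id)
            for i, s in enumerate(seqs)]
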