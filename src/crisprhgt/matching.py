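"""Database matching at calibrated stringency, scrambled-sequence null,
threshold calibration and the community unique-mapping filter."""

from __future__ import annotations

import warnings
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .align import ReferenceIndex, all_matches
from .model import CalibrationCurve, ConfigurationError, MatchHit, ReferenceSeq, SpacerRecord

DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_MIN_COVERAGE = 95.0
DEFAULT_SEED_K = 10
DEFAULT_GRID = (80.0, 85.0, 90.0, 95.0, 100.0)


def match_to_database(spacers: Sequence[SpacerRecord], db: Iterable[ReferenceSeq],
                      min_identity: float = DEFAULT_MIN_IDENTITY,
                      min_coverage: float = DEFAULT_MIN_COVERAGE,
                      seed_k: int = DEFAULT_SEED_K,
                      index: Optional[ReferenceIndex] = None) -> list[MatchHit]:
    """ALL hits of each spacer meeting both thresholds, both strands.

    Every qualifying alignment is reported (the downstream unique-mapping
    filter and set-cover attribution need full hit multiplicity).  Output is
    ordered by (spacer_id, ref_id, start).
    """
    refs = list(db)
    if not refs:
        raise ConfigurationError("target database is empty")
    if index is None or index.k != seed_k:
        index = ReferenceIndex(refs, seed_k)
    hits: list[MatchHit] = []
    for rec in spacers:
        hits.extend(all_matches(rec.spacer_id, rec.sequence, index,
                                min_identity, min_coverage))
    hits.sort(key=lambda h: (h.spacer_id, h.ref_id, h.start))
    return hits


def scramble_spacers(spacers: Sequence[SpacerRecord], seed: int,
                     mode: str = "permute") -> list[SpacerRecord]:
    """Per-spacer null sequences: seeded Fisher-Yates character permutation.

    Each output preserves its input's length and, in the default mode, its
    exact nucleotide multiset.  ``mode='resample'`` draws i.i.d. from the
    spacer's own mononucleotide composition instead (sensitivity analysis).
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in spacers:
        chars = np.array(list(rec.sequence))
        if mode == "permute":
            rng.shuffle(chars)
        elif mode == "resample":
            chars = rng.choice(chars, size=chars.size, replace=True)
        else:
            raise ConfigurationError(f"unknown scramble mode '{mode}'")
        out.append(SpacerRecord(
            spacer_id=f"scrambled_{rec.spacer_id}", sequence="".join(chars),
            abundance=rec.abundance, sample_id=rec.sample_id))
    return out


def _hit_rate(spacers: Sequence[SpacerRecord], hits: list[MatchHit],
              threshold: float) -> float:
    if not spacers:
        return 0.0
    with_hit = {h.spacer_id for h in hits
                if h.identity >= threshold and h.coverage >= threshold}
    return len(with_hit) / len(spacers)


def calibrate_threshold(real_spacers: Sequence[SpacerRecord],
                        db: Iterable[ReferenceSeq], seed: int,
                        grid: Sequence[float] = DEFAULT_GRID,
                        seed_k: int = DEFAULT_SEED_K,
                        scramble_mode: str = "permute") -> CalibrationCurve:
    """Scrambled-null calibration of the identity/coverage hit threshold.

    Real and scrambled spacers are matched once at the most permissive grid
    value; per-threshold rates are then computed by filtering, which makes
    the scrambled rate monotone non-increasing by construction.  The chosen
    threshold is the smallest grid value where the scrambled hit rate is 0
    while the real hit rate is positive; if none qualifies the maximum grid
    value is returned with a warning flag.
    """
    if not real_spacers:
        raise ConfigurationError("calibration requires a non-empty spacer set")
    if len(real_spacers) < 100:
        warnings.warn(f"calibrating on only {len(real_spacers)} spacers; "
                      ">=100 recommended", stacklevel=2)
    grid = sorted(float(g) for g in grid)
    refs = list(db)
    index = ReferenceIndex(refs, seed_k)
    floor = min(grid)
    scrambled = scramble_spacers(real_spacers, seed, mode=scramble_mode)
    real_hits = match_to_database(real_spacers, refs, floor, floor, seed_k, index)
    scr_hits = match_to_database(scrambled, refs, floor, floor, seed_k, index)
    real_rates = [_hit_rate(real_spacers, real_hits, t) for t in grid]
    scr_rates = [_hit_rate(scrambled, scr_hits, t) for t in grid]
    chosen, warning = None, False
    for t, sr, rr in zip(grid, scr_rates, real_rates):
        if sr == 0.0 and rr > 0.0:
            chosen = t
            break
    if chosen is None:
        chosen, warning = max(grid), True
    return CalibrationCurve(thresholds=list(grid), scrambled_hit_rate=scr_rates,
                            real_hit_rate=real_rates, chosen_threshold=chosen,
                            warning=warning)


def filter_multi_mapping(hits: Sequence[MatchHit],
                         grouping: Optional[Callable[[str], str]] = None
                         ) -> tuple[list[MatchHit], int, float]:
    """Remove spacers whose hits span more than one reference (or group).

    ``grouping`` maps a reference id to a group key (e.g. a donor's contig
    set); default is the reference id itself.  Returns (kept hits,
    n spacers removed, removed fraction over unique spacers with >= 1 hit).
    """
    group = grouping or (lambda ref_id: ref_id)
    targets: dict[str, set[str]] = {}
    for h in hits:
        targets.setdefault(h.spacer_id, set()).add(group(h.ref_id))
    multi = {sid for sid, gs in targets.items() if len(gs) > 1}
    kept = [h for h in hits if h.spacer_id not in multi]
    fraction = len(multi) / len(targets) if targets else 0.0
    return kept, len(multi), fraction
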