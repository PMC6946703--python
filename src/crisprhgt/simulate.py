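"""Synthetic recording-experiment generator.

Produces references (recorder genome + recorder plasmid + donor elements),
ground-truth acquisition events, and CRISPR-array amplicon reads with the
statistical structure the downstream analysis assumes: an enforced array
expansion rate, a Bernoulli endogenous/exogenous split, an AAG
protospacer-adjacent-motif bias, optional acquisition hotspots and i.i.d.
per-base substitution errors.  Every output is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import FastqRead
from .model import (
    ConfigurationError,
    ReferenceSeq,
    ROLE_DONOR,
    ROLE_RECORDER_GENOME,
    ROLE_RECORDER_PLASMID,
    revcomp,
)

BASES = "ACGT"

# Canonical E. coli Type I-E direct repeat (29 bp); configurable.
DEFAULT_REPEAT = "GTGTTCCCCGCGCCAGCGGGGATAAACCG"

# Leader stub prepended to every amplicon read (primer-side context).
DEFAULT_LEADER = "ATTTCTTAGCTGCCTATACG"

# Parental array content is not modelled on a real strain; two fixed
# spacers are the arbitrary, configurable default.
DEFAULT_PARENTAL = (
    "ACCGTTGGCCTTAAGGCCAATTGGCACTAGCTA",
    "TTGACCGGTTCAAGGTTCCAAGGAACCTGATCC",
)

RECORDER_GENOME_ID = "recorder_genome"
RECORDER_PLASMID_ID = "recorder_plasmid"


@dataclass(frozen=True)
class Hotspot:
    ref_id: str
    start: int
    end: int
    weight: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_reads: int = 1000
    expansion_rate: float = 0.01
    exogenous_fraction: float = 0.35
    pam_bias: float = 0.5
    multi_acquisition_prob: float = 0.1
    hotspot: Optional[Hotspot] = None
    error_rate: float = 0.0
    spacer_len_mean: float = 33.0
    spacer_len_sd: float = 1.0
    spacer_len_bounds: tuple[int, int] = (25, 45)
    repeat_seq: str = DEFAULT_REPEAT
    leader_seq: str = DEFAULT_LEADER
    parental_spacers: tuple[str, ...] = DEFAULT_PARENTAL
    recorder_genome_len: int = 20000
    recorder_plasmid_len: int = 5000
    donor_lengths: dict[str, int] = field(default_factory=lambda: {"donor_1": 5000})
    plasmid_genome_weight: float = 10.0
    min_shared_kmer: int = 16

    @property
    def donor_ids(self) -> list[str]:
        return list(self.donor_lengths)

    def validate(self) -> None:
        for name in ("expansion_rate", "exogenous_fraction", "pam_bias",
                     "multi_acquisition_prob", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} must be in [0,1]")
        if self.n_reads <= 0:
            raise ConfigurationError("n_reads must be > 0")
        if len(self.repeat_seq) < 8 or set(self.repeat_seq) - set(BASES):
            raise ConfigurationError("repeat_seq must be ACGT-only and >= 8 nt")
        if self.recorder_genome_len < 10000:
            raise ConfigurationError("recorder genome surrogate must be >= 10 kb")
        if self.recorder_plasmid_len < 1000:
            raise ConfigurationError("recorder plasmid must be >= 1 kb")
        if not self.donor_lengths:
            raise ConfigurationError("at least one donor reference is required")
        for did, length in self.donor_lengths.items():
            if length < 1000:
                raise ConfigurationError(f"donor '{did}' length {length} < 1 kb")
        lo, hi = self.spacer_len_bounds
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid spacer_len_bounds")
        if not self.parental_spacers:
            raise ConfigurationError("at least one parental spacer is required")


@dataclass(frozen=True)
class AcquisitionEvent:
    read_id: str
    source_ref_id: str
    start: int
    end: int
    strand: str
    pam_trinucleotide: str
    is_exogenous: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def simulate_references(config: SimulationConfig) -> list[ReferenceSeq]:
    """Generate recorder genome, recorder plasmid, and donor references.

    Donors are resampled until they share no k-mer (default k=16) with the
    recorder set, so endogenous/exogenous attribution is unambiguous by
    construction.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    refs = [
        ReferenceSeq(RECORDER_GENOME_ID, _random_seq(rng, config.recorder_genome_len),
                     ROLE_RECORDER_GENOME),
        ReferenceSeq(RECORDER_PLASMID_ID, _random_seq(rng, config.recorder_plasmid_len),
                     ROLE_RECORDER_PLASMID),
    ]
    k = config.min_shared_kmer
    recorder_kmers: set[str] = set()
    for r in refs:
        recorder_kmers |= _kmers(r.seq, k)
        recorder_kmers |= _kmers(revcomp(r.seq), k)
    for did, length in config.donor_lengths.items():
        for _attempt in range(100):
            seq = _random_seq(rng, length)
            if not (_kmers(seq, k) & recorder_kmers) and not (_kmers(revcomp(seq), k) & recorder_kmers):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigurationError(f"could not generate donor '{did}' disjoint from recorder")
        refs.append(ReferenceSeq(did, seq, ROLE_DONOR))
    return refs


def _spacer_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    lo, hi = config.spacer_len_bounds
    length = int(round(rng.normal(config.spacer_len_mean, config.spacer_len_sd)))
    return min(max(length, lo), hi)


def _draw_protospacer(rng: np.random.Generator, ref: ReferenceSeq, length: int,
                      want_aag: bool, hotspot: Optional[Hotspot],
                      max_tries: int = 100000) -> tuple[int, int, str, str]:
    """Rejection-sample (start, end, strand, pam) from one reference.

    PAM is the trinucleotide immediately 5' of the protospacer on the
    protospacer strand; starts within 3 nt of either reference end are not
    drawn so the PAM is always extractable.  The hotspot multiplies the
    per-base draw rate inside its interval.
    """
    n = len(ref.seq)
    if n < length + 6:
        raise ConfigurationError(f"reference '{ref.id}' too short for a {length} nt protospacer")
    max_w = hotspot.weight if (hotspot and hotspot.ref_id == ref.id) else 1.0
    for _ in range(max_tries):
        start = int(rng.integers(3, n - length - 3 + 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        if hotspot and hotspot.ref_id == ref.id:
            w = hotspot.weight if hotspot.start <= start < hotspot.end else 1.0
            if rng.random() >= w / max_w:
                continue
        if strand == "+":
            pam = ref.seq[start - 3:start]
        else:
            pam = revcomp(ref.seq[end:end + 3])
        if want_aag != (pam == "AAG"):
            continue
        return start, end, strand, pam
    raise ConfigurationError(
        f"could not sample a {'PAM' if want_aag else 'non-PAM'} protospacer from '{ref.id}'")


def simulate_acquisitions(config: SimulationConfig,
                          refs: list[ReferenceSeq]) -> list[AcquisitionEvent]:
    """Draw ground-truth acquisition events.

    Exactly ``round(n_reads * expansion_rate)`` reads receive >= 1 event.
    Each event is exogenous with probability ``exogenous_fraction`` and has
    an AAG PAM with probability ``pam_bias`` (the complement is forced
    non-AAG so the realized fraction estimates the parameter directly).
    """
    config.validate()
    by_id = {r.id: r for r in refs}
    donors = [by_id[d] for d in config.donor_ids if d in by_id]
    if set(config.donor_ids) - set(by_id):
        raise ConfigurationError("donor_ids not all present among references")
    if config.hotspot is not None:
        hs = config.hotspot
        if hs.ref_id not in by_id:
            raise ConfigurationError(f"hotspot reference '{hs.ref_id}' unknown")
        if not (0 <= hs.start < hs.end <= len(by_id[hs.ref_id].seq)):
            raise ConfigurationError("hotspot interval outside reference")
        if hs.weight <= 0:
            raise ConfigurationError("hotspot weight must be > 0")

    rng = np.random.default_rng([config.seed, 202])
    n_expanded = int(round(config.n_reads * config.expansion_rate))
    expanded_idx = sorted(rng.choice(config.n_reads, size=n_expanded, replace=False).tolist())

    genome = by_id[RECORDER_GENOME_ID]
    plasmid = by_id[RECORDER_PLASMID_ID]
    w = config.plasmid_genome_weight
    events: list[AcquisitionEvent] = []
    for idx in expanded_idx:
        read_id = f"read_{idx:06d}"
        n_new = 2 if rng.random() < config.multi_acquisition_prob else 1
        for _ in range(n_new):
            is_exo = bool(rng.random() < config.exogenous_fraction)
            if is_exo:
                src = donors[int(rng.integers(len(donors)))]
            else:
                src = plasmid if rng.random() < w / (w + 1.0) else genome
            length = _spacer_length(rng, config)
            want_aag = bool(rng.random() < config.pam_bias)
            start, end, strand, pam = _draw_protospacer(
                rng, src, length, want_aag, config.hotspot)
            events.append(AcquisitionEvent(read_id, src.id, start, end, strand, pam, is_exo))
    return events


def event_spacer(event: AcquisitionEvent, refs_by_id: dict[str, ReferenceSeq]) -> str:
    """True (error-free) spacer sequence of an event, on the protospacer strand."""
    seq = refs_by_id[event.source_ref_id].seq[event.start:event.end]
    return seq if event.strand == "+" else revcomp(seq)


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    if hit.any():
        idx = np.flatnonzero(hit)
        base_map = np.frombuffer(b"ACGT", dtype=np.uint8)
        lut = {ord(b): [x for x in b"ACGT" if x != ord(b)] for b in BASES}
        for i in idx:
            choices = lut.get(int(arr[i]), list(base_map))
            arr[i] = choices[int(rng.integers(len(choices)))]
    return arr.tobytes().decode()


def simulate_reads(config: SimulationConfig, refs: list[ReferenceSeq],
                   events: list[AcquisitionEvent]
                   ) -> tuple[list[FastqRead], list[dict]]:
    """Build amplicon reads and the ground-truth manifest.

    Read layout: leader stub, then a repeat, then new spacers
    (leader-proximal first) and parental spacers, each followed by a repeat.
    Substitution errors are applied i.i.d. at ``error_rate``; the manifest
    records the error-free truth (one row per new spacer).
    """
    config.validate()
    by_id = {r.id: r for r in refs}
    events_by_read: dict[str, list[AcquisitionEvent]] = {}
    for ev in events:
        events_by_read.setdefault(ev.read_id, []).append(ev)

    rng = np.random.default_rng([config.seed, 303])
    repeat = config.repeat_seq
    parental_unit = "".join(s + repeat for s in config.parental_spacers)
    reads: list[FastqRead] = []
    manifest: list[dict] = []
    for idx in range(config.n_reads):
        read_id = f"read_{idx:06d}"
        new = events_by_read.get(read_id, [])
        new_part = "".join(event_spacer(ev, by_id) + repeat for ev in new)
        seq = config.leader_seq + repeat + new_part + parental_unit
        seq = _apply_errors(seq, rng, config.error_rate)
        reads.append(FastqRead(id=read_id, seq=seq, qual="I" * len(seq)))
        for ev in new:
            manifest.append({
                "read_id": read_id,
                "spacer_seq": event_spacer(ev, by_id),
                "source_ref": ev.source_ref_id,
                "start": ev.start,
                "end": ev.end,
                "strand": ev.strand,
                "pam": ev.pam_trinucleotide,
                "is_exogenous": int(ev.is_exogenous),
            })
    return reads, manifest


MANIFEST_COLUMNS = ["read_id", "spacer_seq", "source_ref", "start", "end",
                    "strand", "pam", "is_exogenous"]


def simulate_experiment(config: SimulationConfig):
    """Convenience: references, events, reads and manifest in one call."""
    refs = simulate_references(config)
    events = simulate_acquisitions(config, refs)
    reads, manifest = simulate_reads(config, refs, events)
    return refs, events, reads, manifest
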