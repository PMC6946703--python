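"""Shared domain types for the recording-analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Raised when a run/simulation configuration is invalid."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


# Reference roles
ROLE_RECORDER_GENOME = "recorder_genome"
ROLE_RECORDER_PLASMID = "recorder_plasmid"
ROLE_DONOR = "donor"
ROLE_PLASMID_DB = "plasmid_db"
ROLE_METAGENOME = "metagenome"


@dataclass(frozen=True)
class ReferenceSeq:
    """A named sequence with a role in the recording experiment."""

    id: str
    seq: str
    role: str = ROLE_DONOR

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ParsedArray:
    """One amplicon read decomposed into ordered spacers between repeats.

    ``spacers`` are ordered leader-proximal first.  ``new_spacers`` is always
    a prefix of ``spacers`` (new acquisitions integrate at the leader end).
    """

    read_id: str
    spacers: list[str] = field(default_factory=list)
    n_repeats: int = 0
    status: str = "ok"  # ok | no_repeat | single_repeat | malformed
    is_expanded: bool = False
    new_spacers: list[str] = field(default_factory=list)


@dataclass
class ExpansionSummary:
    sample_id: str
    n_arrays_total: int
    n_arrays_expanded: int
    percent_expanded: float
    n_new_spacers: int


@dataclass
class SpacerRecord:
    """A (dereplicated) spacer with abundance and its homology classification."""

    spacer_id: str
    sequence: str
    abundance: int = 1
    sample_id: str = ""
    classification: str = "unclassified"  # endogenous | exogenous | unclassified
    best_identity: Optional[float] = None
    best_coverage: Optional[float] = None


@dataclass(frozen=True)
class MatchHit:
    """One spacer-to-reference gapless local alignment.

    Coordinates are 0-based half-open on the reference forward strand;
    ``qstart``/``qend`` are on the original query orientation.
    """

    spacer_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    qstart: int = 0
    qend: int = 0
    qlen: int = 0
    slen: int = 0
    n_mismatch: int = 0

    @property
    def aligned_len(self) -> int:
        return self.end - self.start


@dataclass
class CalibrationCurve:
    thresholds: list[float]
    scrambled_hit_rate: list[float]
    real_hit_rate: list[float]
    chosen_threshold: float
    warning: bool = False


@dataclass
class MappingProfile:
    ref_id: str
    ref_len: int
    n_spacers: int
    normalized_spacer_mapping: float
    is_zero: bool = False
    window_coverage: Optional[list[tuple[tuple[int, int], float]]] = None


@dataclass
class SampleCall:
    sample_id: str
    n_arrays: int
    percent_exogenous: float
    n_unique_exogenous: int
    control_percent: float
    min_spacers: int
    fold: float
    is_hgt_positive: bool
    effective_threshold: float


@dataclass
class CoverSet:
    rows: list[tuple[str, int, int]]  # (ref_id, n_assigned, cumulative_covered)
    uncovered_spacers: int = 0

    @property
    def ref_ids(self) -> list[str]:
        return [r[0] for r in self.rows]


@dataclass
class PamSummary:
    counts: dict[str, int]
    aag_fraction: float
    n_extractable: int
    n_skipped: int
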