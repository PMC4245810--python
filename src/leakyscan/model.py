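"""Core domain types for TIS-level ribosome-profiling data.

The central objects are :class:`TisRecord` (one detected translation
initiation site on one transcript, with its start codon and initiating
footprint signal) and :class:`TranscriptTisSet` (the 5'->3' ordered series
of TISs on a single transcript, the unit over which initiation
probabilities are defined). Probabilities are only comparable within a
transcript, so every estimator consumes and returns per-transcript objects.

All coordinates are 0-based transcript coordinates; all sequences are in
the DNA alphabet (U mapped to T on ingest).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

from .errors import ValidationError

_VALID_BASES = frozenset("ACGT")

#: Codons at Hamming distance 1 from ATG (the near-cognate start codons).
NEAR_COGNATE_CODONS = frozenset(
    {"CTG", "GTG", "TTG", "ATA", "ATT", "ATC", "ACG", "AAG", "AGG"}
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class CodonClass(str, enum.Enum):
    """Start-codon category: canonical AUG, near-cognate (one substitution
    away from AUG), or anything else."""

    AUG = "AUG"
    NEAR_COGNATE = "near_cognate"
    OTHER = "other"


class Region(str, enum.Enum):
    """Location of a TIS relative to the annotated start of the CDS."""

    FIVE_PRIME_LEADER = "five_prime_leader"
    ANNOTATED_TIS = "annotated_tis"
    DOWNSTREAM = "downstream"


class Method(str, enum.Enum):
    """Probability estimator identity."""

    PAS = "PAS"
    LS = "LS"


def normalize_nucleotides(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def _check_codon(codon: str) -> str:
    codon = normalize_nucleotides(codon)
    if len(codon) != 3 or not set(codon) <= _VALID_BASES:
        raise ValidationError(
            f"invalid codon {codon!r}: must be 3 letters over A/C/G/T (or U)"
        )
    return codon


def classify_codon(codon: str) -> CodonClass:
    """Classify a start codon as AUG, near-cognate, or other.

    Near-cognate means exactly one substitution away from ATG (CUG, GUG,
    UUG, AUA, AUU, AUC, ACG, AAG, AGG); everything at distance >= 2 (e.g.
    AAA) is `other`.
    """
    codon = _check_codon(codon)
    if codon == "ATG":
        return CodonClass.AUG
    if codon in NEAR_COGNATE_CODONS:
        return CodonClass.NEAR_COGNATE
    return CodonClass.OTHER


@dataclass(frozen=True)
class TisRecord:
    """One detected TIS on one transcript.

    Parameters
    ----------
    gene_id, transcript_id:
        Identifiers from the source table.
    position:
        0-based transcript coordinate of the first nucleotide of the start
        codon.
    codon:
        The start codon, DNA alphabet (U accepted and mapped to T).
    signal:
        Non-negative initiating-footprint signal R_i: either a raw read
        count or a normalized R_LTM - R_CHX score. Negative normalized
        scores are representable only before thresholding and are rejected
        here; thresholding happens upstream of record construction.
    region:
        Optional location relative to the annotated TIS.
    frame:
        Optional reading frame (0/1/2) relative to the annotated CDS.
    """

    gene_id: str
    transcript_id: str
    position: int
    codon: str
    signal: float
    region: Optional[Region] = None
    frame: Optional[int] = None
    codon_class: CodonClass = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "codon", _check_codon(self.codon))
        object.__setattr__(self, "codon_class", classify_codon(self.codon))
        if self.position < 0:
            raise ValidationError(
                f"TIS position must be >= 0, got {self.position} "
                f"(transcript {self.transcript_id})"
            )
        if not self.signal >= 0:
            raise ValidationError(
                f"TIS signal must be >= 0, got {self.signal} "
                f"(transcript {self.transcript_id}, position {self.position})"
            )
        if self.frame is not None and self.frame not in (0, 1, 2):
            raise ValidationError(f"frame must be 0, 1 or 2, got {self.frame}")


@dataclass
class TranscriptTisSet:
    """The ordered 5'->3' series of TISs on one transcript.

    The scanning model reads strictly 5'->3', so `tis_list` must be sorted
    by strictly increasing position; ties are rejected because the scanning
    order of two TISs at the same coordinate is undefined.
    """

    transcript_id: str
    gene_id: str
    tis_list: list[TisRecord]
    sequence: Optional[str] = None
    is_single_isoform: bool = True

    def __post_init__(self) -> None:
        for tis in self.tis_list:
            if tis.transcript_id != self.transcript_id:
                raise ValidationError(
                    f"TIS transcript_id {tis.transcript_id!r} does not match "
                    f"set transcript_id {self.transcript_id!r}"
                )
        positions = [t.position for t in self.tis_list]
        for a, b in zip(positions, positions[1:]):
            if b <= a:
                raise ValidationError(
                    f"TIS positions must be strictly increasing on "
                    f"{self.transcript_id}: {a} followed by {b}"
                    + (" (tied positions are malformed)" if a == b else "")
                )
        if self.sequence is not None:
            self.sequence = normalize_nucleotides(self.sequence)
            for tis in self.tis_list:
                at = self.sequence[tis.position : tis.position + 3]
                if at != tis.codon:
                    raise ValidationError(
                        f"codon mismatch on {self.transcript_id} at position "
                        f"{tis.position}: record says {tis.codon}, sequence "
                        f"has {at!r}"
                    )

    def __len__(self) -> int:
        return len(self.tis_list)

    @property
    def signals(self) -> list[float]:
        return [t.signal for t in self.tis_list]

    @property
    def positions(self) -> list[int]:
        return [t.position for t in self.tis_list]

    def with_tis_list(self, tis_list: Sequence[TisRecord]) -> "TranscriptTisSet":
        """Copy of this set with a replacement (already ordered) TIS list."""
        return TranscriptTisSet(
            transcript_id=self.transcript_id,
            gene_id=self.gene_id,
            tis_list=list(tis_list),
            sequence=self.sequence,
            is_single_isoform=self.is_single_isoform,
        )


@dataclass(frozen=True)
class ProbabilityResult:
    """Per-TIS initiation probabilities for one transcript.

    `probabilities` aligns 1:1 with the transcript's `tis_list`. `ru` is
    the signal assigned to the artificial 3'-most pseudo-TIS aggregating
    all initiation below the detection limit; it is 0 for the PAS method
    and for LS without the pseudo-TIS.
    """

    transcript_id: str
    method: Method
    ru: float
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.ru < 0:
            raise ValidationError(f"ru must be >= 0, got {self.ru}")
        for p in self.probabilities:
            if not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"probability {p} outside [0, 1] on {self.transcript_id}"
                )


#: A per-TIS true-probability specification for the simulator: either a
#: fixed vector (recycled/truncated per transcript), a (low, high) uniform
#: range, or a callable (rng, k) -> k probabilities.
ProbabilitySpec = Union[
    Sequence[float], tuple[float, float], Callable[..., Sequence[float]]
]


@dataclass
class ScanSimConfig:
    """Generative parameters for synthetic scanning-ribosome datasets.

    Each of `ribosome_budget` scanning complexes enters the 5' end of each
    transcript and initiates at successive TISs with their true
    probabilities; TISs whose sampled count falls below
    `detection_threshold` are removed from the emitted (observed) table but
    kept in the truth table. `loss_hook` is a per-inter-TIS-interval
    attrition fraction applied to the scanning pool (default 0: no loss).
    """

    n_transcripts: int = 100
    tis_per_transcript: Union[int, tuple[int, int]] = 2
    true_probabilities: ProbabilitySpec = (0.05, 0.9)
    ribosome_budget: int = 100_000
    detection_threshold: float = 0.0
    codon_pool: dict[str, float] = field(
        default_factory=lambda: {"ATG": 0.6, "CTG": 0.4}
    )
    seed: int = 0
    loss_hook: float = 0.0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValidationError("n_transcripts must be positive")
        if self.ribosome_budget < 1:
            raise ValidationError("ribosome_budget must be positive")
        if not (0.0 <= self.loss_hook < 1.0):
            raise ValidationError(
                f"loss_hook must be in [0, 1), got {self.loss_hook}"
            )
        if self.detection_threshold < 0:
            raise ValidationError("detection_threshold must be >= 0")
        if isinstance(self.tis_per_transcript, int):
            if self.tis_per_transcript < 1:
                raise ValidationError("tis_per_transcript must be positive")
        else:
            lo, hi = self.tis_per_transcript
            if lo < 1 or hi < lo:
                raise ValidationError(
                    f"bad tis_per_transcript range ({lo}, {hi})"
                )
        for codon, weight in self.codon_pool.items():
            _check_codon(codon)
            if weight < 0:
                raise ValidationError(f"codon weight must be >= 0: {codon}")
        if isinstance(self.true_probabilities, Sequence) and not callable(
            self.true_probabilities
        ):
            for p in self.true_probabilities:
                if not (0.0 < p <= 1.0):
                    raise ValidationError(
                        f"true probabilities must be in (0, 1], got {p}"
                    )


__all__ = [
    "CodonClass",
    "Method",
    "NEAR_COGNATE_CODONS",
    "STOP_CODONS",
    "ProbabilityResult",
    "Region",
    "ScanSimConfig",
    "TisRecord",
    "TranscriptTisSet",
    "classify_codon",
    "normalize_nucleotides",
    "replace",
]
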