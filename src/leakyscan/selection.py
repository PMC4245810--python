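"""Candidate-selection filters for leaky-scanning analysis.

Downstream initiation on a transcript is evidence of leaky scanning only
when reinitiation can be excluded: if the ORF started at the first TIS
terminates (hits an in-frame stop) upstream of the second TIS, a ribosome
could have translated the first ORF, resumed scanning, and reinitiated —
so such "separated" TIS pairs are filtered out. Pairs whose ORFs overlap,
or that share one ORF, cannot arise by termination-reinitiation and are
kept.

The strict two-TIS candidate set additionally requires single-isoform
transcripts (so all footprints provably come from one mRNA) and restricts
start codons to an allow-list (ATG and CTG by default: other near-cognate
TIS calls carry a high false-positive fraction from arrested elongating
ribosomes).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .errors import ContractError, ValidationError
from .model import (
    STOP_CODONS,
    TranscriptTisSet,
    classify_codon,
    normalize_nucleotides,
)

# re-exported: codon classification is part of this module's surface
classify_codon = classify_codon

DEFAULT_ALLOWED_CODONS = frozenset({"ATG", "CTG"})


class OrfLabel(str, enum.Enum):
    """Geometric relationship between the ORFs of two TISs on one mRNA."""

    OVERLAPPING_ORFS = "overlapping_orfs"
    SAME_ORF = "same_orf"
    SEPARATED_ORFS = "separated_orfs"


@dataclass(frozen=True)
class OrfConfiguration:
    """Classification of a 5' TIS / 3' TIS pair.

    `frame_offset` is (b - a) mod 3; `has_inframe_stop_between` is True
    when the first TIS's ORF terminates at or before the second TIS.
    """

    label: OrfLabel
    has_inframe_stop_between: bool
    frame_offset: int

    def __post_init__(self) -> None:
        if self.label is OrfLabel.SAME_ORF and (
            self.frame_offset != 0 or self.has_inframe_stop_between
        ):
            raise ValidationError("same_orf requires frame 0 and no stop")
        if self.label is OrfLabel.SEPARATED_ORFS and not (
            self.has_inframe_stop_between
        ):
            raise ValidationError("separated_orfs requires an in-frame stop")


def _first_stop_end(sequence: str, start: int) -> Optional[int]:
    """End coordinate (exclusive) of the first in-frame stop codon of the
    ORF starting at `start`, or None if the ORF runs off the sequence."""
    for p in range(start, len(sequence) - 2, 3):
        if sequence[p : p + 3] in STOP_CODONS:
            return p + 3
    return None


def classify_orf_configuration(
    tis_a_pos: int, tis_b_pos: int, sequence: str
) -> OrfConfiguration:
    """Classify the ORF relationship of two TISs at positions a < b.

    The ORF of the 5' TIS is extended codon-by-codon in its own frame to
    its first stop (TAA/TAG/TGA, standard code). If that ORF terminates at
    or before b, the pair is `separated_orfs` (reinitiation possible). In
    frame 0 with no intervening stop the TISs share one ORF (`same_orf`);
    out of frame with the first ORF still open at b they are
    `overlapping_orfs`.
    """
    if tis_a_pos >= tis_b_pos:
        raise ValidationError(
            f"TIS positions must satisfy a < b, got {tis_a_pos}, {tis_b_pos}"
        )
    sequence = normalize_nucleotides(sequence)
    if tis_a_pos < 0 or tis_b_pos + 3 > len(sequence):
        raise ValidationError(
            f"TIS positions ({tis_a_pos}, {tis_b_pos}) out of bounds for "
            f"sequence of length {len(sequence)}"
        )
    frame_offset = (tis_b_pos - tis_a_pos) % 3
    orf_a_end = _first_stop_end(sequence, tis_a_pos)
    # stop "between" the starts: first ORF fully terminated by position b.
    # The codon starting exactly at b is never scanned (it is the
    # downstream start itself); in frame 0 a stop starting at a position
    # < b ends at <= b, so the two readings coincide.
    stop_before_b = orf_a_end is not None and orf_a_end <= tis_b_pos
    if stop_before_b:
        label = OrfLabel.SEPARATED_ORFS
    elif frame_offset == 0:
        label = OrfLabel.SAME_ORF
    else:
        label = OrfLabel.OVERLAPPING_ORFS
    return OrfConfiguration(
        label=label,
        has_inframe_stop_between=stop_before_b,
        frame_offset=frame_offset,
    )


def _codon_filter(
    tis_set: TranscriptTisSet, allowed_codons: frozenset[str]
) -> TranscriptTisSet:
    kept = [t for t in tis_set.tis_list if t.codon in allowed_codons]
    return tis_set.with_tis_list(kept)


def _normalize_allowed(allowed_codons: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_nucleotides(c) for c in allowed_codons)


def select_two_tis_candidates(
    tis_sets: Iterable[TranscriptTisSet],
    sequences: Mapping[str, str],
    allowed_codons: Iterable[str] = DEFAULT_ALLOWED_CODONS,
) -> list[TranscriptTisSet]:
    """The strict candidate set for testing the LS estimator.

    Retains transcripts that (1) are single-isoform, (2) have exactly two
    TISs after restricting to `allowed_codons`, and (3) whose TIS pair is
    `same_orf` or `overlapping_orfs` — pairs separated by a stop codon are
    excluded because reinitiation could explain the downstream signal.
    Transcript sequences are required for the stop-codon scan; a surviving
    candidate without a sequence is an error.

    Returned sets carry the filtered two-TIS list and the sequence.
    """
    allowed = _normalize_allowed(allowed_codons)
    out: list[TranscriptTisSet] = []
    for tis_set in tis_sets:
        if not tis_set.is_single_isoform:
            continue
        filtered = _codon_filter(tis_set, allowed)
        if len(filtered) != 2:
            continue
        seq = filtered.sequence
        if seq is None:
            seq = sequences.get(tis_set.transcript_id)
            if seq is None:
                raise ContractError(
                    f"no sequence available for candidate transcript "
                    f"{tis_set.transcript_id}; cannot run the in-frame "
                    "stop-codon filter"
                )
        a, b = filtered.positions
        config = classify_orf_configuration(a, b, seq)
        if config.label is OrfLabel.SEPARATED_ORFS:
            continue
        out.append(
            TranscriptTisSet(
                transcript_id=filtered.transcript_id,
                gene_id=filtered.gene_id,
                tis_list=filtered.tis_list,
                sequence=seq,
                is_single_isoform=filtered.is_single_isoform,
            )
        )
    return out


def select_all_tis_candidates(
    tis_sets: Iterable[TranscriptTisSet],
    allowed_codons: Iterable[str] = DEFAULT_ALLOWED_CODONS,
) -> list[TranscriptTisSet]:
    """The permissive candidate set: single-isoform transcripts with at
    least one TIS after codon filtering; no ORF-configuration filter, so
    configurations permitting reinitiation are retained."""
    allowed = _normalize_allowed(allowed_codons)
    out: list[TranscriptTisSet] = []
    for tis_set in tis_sets:
        if not tis_set.is_single_isoform:
            continue
        filtered = _codon_filter(tis_set, allowed)
        if len(filtered) >= 1:
            out.append(filtered)
    return out


__all__ = [
    "DEFAULT_ALLOWED_CODONS",
    "OrfConfiguration",
    "OrfLabel",
    "classify_codon",
    "classify_orf_configuration",
    "select_all_tis_candidates",
    "select_two_tis_candidates",
]
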