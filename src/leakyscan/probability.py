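"""PAS and LS initiation-probability estimators and signal normalization.

Two estimators convert per-TIS initiating-footprint signal into per-TIS
probabilities of translation initiation on a transcript with TISs indexed
1..k in 5'->3' order:

PAS (Proportion of Absolute Signal)::

    P_i = R_i / sum_{s=1..k} R_s

LS (Leaky Scanning)::

    P_i = R_i / (sum_{s=i..k} R_s + R_u)

The LS denominator is the footprint signal of the ribosomes still
*available* to initiate at TIS_i — everything at TIS_i and downstream —
so the estimate at each TIS is independent of how many ribosomes were
captured upstream. R_u is the signal assigned to an artificial 3'-most
pseudo-TIS (TIS_u) standing for all initiation events below the detection
limit; with R_u = 0 the most 3' detected TIS always receives probability
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ContractError, DegenerateInputError
from .model import Method, ProbabilityResult, TranscriptTisSet


@dataclass(frozen=True)
class NormalizationInputs:
    """Read counts needed for the R_LTM - R_CHX normalized TIS signal.

    `x_*` are reads at the TIS, `n_*` total reads on the TIS's mRNA, in
    the initiation-arrest (LTM) and elongation-arrest (CHX) libraries.
    """

    x_ltm: float
    n_ltm: float
    x_chx: float
    n_chx: float

    def __post_init__(self) -> None:
        if not (self.n_ltm > 0 and self.n_chx > 0):
            raise ContractError(
                f"per-mRNA totals must be positive: n_ltm={self.n_ltm}, "
                f"n_chx={self.n_chx}"
            )
        if self.x_ltm < 0 or self.x_chx < 0:
            raise ContractError("per-TIS read counts must be >= 0")
        if self.x_ltm > self.n_ltm or self.x_chx > self.n_chx:
            raise ContractError(
                "per-TIS reads cannot exceed the per-mRNA total"
            )


def normalize_signal(inputs: NormalizationInputs) -> float:
    """R_LTM - R_CHX with R_k = (X_k / N_k) x 10 for k in {LTM, CHX}.

    May be negative (more elongating than initiating signal at the codon);
    the caller decides thresholding via :func:`apply_detection_threshold`.
    """
    r_ltm = inputs.x_ltm / inputs.n_ltm * 10.0
    r_chx = inputs.x_chx / inputs.n_chx * 10.0
    return r_ltm - r_chx


def pas_probabilities(tis_set: TranscriptTisSet) -> ProbabilityResult:
    """Probability of initiation as each TIS's share of total signal.

    P_i = R_i / sum of all R_s on the transcript. The probabilities sum
    to 1 by construction.

    Raises
    ------
    ContractError
        If the transcript has no TISs.
    DegenerateInputError
        If total signal is zero (no probabilities are defined).
    """
    if len(tis_set) == 0:
        raise ContractError(
            f"transcript {tis_set.transcript_id} has no TISs"
        )
    total = sum(tis_set.signals)
    if total <= 0:
        raise DegenerateInputError(
            f"total signal on {tis_set.transcript_id} is {total}; "
            "PAS probabilities are undefined"
        )
    probs = tuple(s / total for s in tis_set.signals)
    return ProbabilityResult(
        transcript_id=tis_set.transcript_id,
        method=Method.PAS,
        ru=0.0,
        probabilities=probs,
    )


def ls_probabilities(
    tis_set: TranscriptTisSet, ru: float = 0.0
) -> ProbabilityResult:
    """Leaky-scanning probability of initiation at each TIS.

    P_i = R_i / (R_i + R_{i+1} + ... + R_k + R_u), the suffix sums taken
    over TISs in 5'->3' order. `ru` is the signal of the artificial
    pseudo-TIS appended 3' of all detected TISs; with ru = 0 the last TIS
    with positive signal receives probability exactly 1.

    Raises
    ------
    ContractError
        If the transcript has no TISs or ru < 0.
    DegenerateInputError
        If any suffix sum plus ru is zero (probability undefined at that
        TIS).
    """
    if len(tis_set) == 0:
        raise ContractError(
            f"transcript {tis_set.transcript_id} has no TISs"
        )
    if ru < 0:
        raise ContractError(f"ru must be >= 0, got {ru}")
    signals = tis_set.signals
    # one backward pass builds every suffix sum; per-transcript TIS counts
    # are small and well-scaled, so no compensated summation
    suffix = [0.0] * len(signals)
    acc = ru
    for i in range(len(signals) - 1, -1, -1):
        acc += signals[i]
        suffix[i] = acc
    probs = []
    for i, (s, denom) in enumerate(zip(signals, suffix)):
        if denom <= 0:
            tis = tis_set.tis_list[i]
            raise DegenerateInputError(
                f"zero denominator at TIS {i + 1} (position {tis.position}) "
                f"of {tis_set.transcript_id}: no signal at or downstream of "
                "this TIS and ru = 0"
            )
        probs.append(s / denom)
    return ProbabilityResult(
        transcript_id=tis_set.transcript_id,
        method=Method.LS,
        ru=ru,
        probabilities=tuple(probs),
    )


def apply_detection_threshold(
    tis_set: TranscriptTisSet, threshold: float
) -> TranscriptTisSet:
    """Copy of `tis_set` keeping only TISs with signal >= threshold.

    The comparison is inclusive: a TIS exactly at the minimum detection
    threshold is detected. Ordering is preserved; the result may be empty
    (downstream estimators reject empty sets).
    """
    if threshold < 0:
        raise ContractError(f"threshold must be >= 0, got {threshold}")
    kept = [t for t in tis_set.tis_list if t.signal >= threshold]
    return tis_set.with_tis_list(kept)


#: Published R_u defaults: the minimum detection threshold of each study.
_RU_DEFAULTS = {"lee": 0.05, "ingolia": 50.0}


def default_ru(
    dataset_style: str, custom_value: Optional[float] = None
) -> float:
    """The published R_u value for a dataset style.

    'lee' -> 0.05 (R_LTM - R_CHX units), 'ingolia' -> 50 (Harr footprint
    counts); both equal the minimum TIS detection threshold of the
    respective study. 'custom' requires `custom_value`.
    """
    style = dataset_style.lower()
    if style == "custom":
        if custom_value is None:
            raise ContractError(
                "dataset_style='custom' requires custom_value"
            )
        if custom_value < 0:
            raise ContractError(f"ru must be >= 0, got {custom_value}")
        return float(custom_value)
    if style in _RU_DEFAULTS:
        if custom_value is not None:
            raise ContractError(
                f"custom_value is only valid with dataset_style='custom', "
                f"not {dataset_style!r}"
            )
        return _RU_DEFAULTS[style]
    raise ContractError(
        f"unknown dataset_style {dataset_style!r}; "
        "expected 'lee', 'ingolia' or 'custom'"
    )


__all__ = [
    "NormalizationInputs",
    "apply_detection_threshold",
    "default_ru",
    "ls_probabilities",
    "normalize_signal",
    "pas_probabilities",
]
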