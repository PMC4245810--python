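"""Position-specific weighting of start-codon (Kozak) context.

The context of a TIS is the four nucleotides most predictive of
initiation efficiency in the Kozak model: positions -3, -2, -1 (just
upstream of the start codon, whose first base is +1) and +4 (just
downstream of it). A PWM built from observed contexts holds the raw
per-position nucleotide frequencies, and a context's score is the sum of
its four positional weights — an additive frequency score in [0, 4], not
a log-odds score, so the per-position argmax string (typically ACC..G)
attains the maximum by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ContractError, ValidationError
from .model import normalize_nucleotides

#: Context positions relative to the first TIS nucleotide at +1.
CONTEXT_POSITIONS = (-3, -2, -1, 4)
_NUCLEOTIDES = ("A", "C", "G", "T")
_NT_INDEX = {nt: i for i, nt in enumerate(_NUCLEOTIDES)}


def _check_context(context: str) -> str:
    context = normalize_nucleotides(context)
    if len(context) != 4 or any(nt not in _NT_INDEX for nt in context):
        raise ValidationError(
            f"invalid context {context!r}: must be 4 letters over A/C/G/T"
        )
    return context


@dataclass(frozen=True)
class KozakPwm:
    """Position-specific weight matrix over context positions -3,-2,-1,+4.

    `weights[i, j]` is the weight of nucleotide `j` (A,C,G,T order) at
    position `CONTEXT_POSITIONS[i]`; each row sums to 1 (frequency
    weighting). `n_contexts` is the number of training contexts.
    """

    weights: np.ndarray
    n_contexts: int
    positions: tuple[int, ...] = field(default=CONTEXT_POSITIONS)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4, 4):
            raise ValidationError(f"PWM must be 4x4, got shape {w.shape}")
        if (w < 0).any():
            raise ValidationError("PWM weights must be non-negative")
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("PWM rows must each sum to 1")
        if self.n_contexts < 1:
            raise ValidationError("n_contexts must be >= 1")
        object.__setattr__(self, "weights", w)

    def consensus(self) -> str:
        """The per-position argmax context (ties broken A<C<G<T)."""
        return "".join(_NUCLEOTIDES[i] for i in self.weights.argmax(axis=1))

    def to_tsv(self, path) -> None:
        """Write the matrix as TSV: rows -3,-2,-1,+4; columns A,C,G,T."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#position\t" + "\t".join(_NUCLEOTIDES) + "\n")
            for pos, row in zip(self.positions, self.weights):
                cells = "\t".join(f"{x:.10g}" for x in row)
                fh.write(f"{pos:+d}\t{cells}\n")

    @classmethod
    def from_tsv(cls, path, n_contexts: int = 1) -> "KozakPwm":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rows.append([float(x) for x in line.split("\t")[1:5]])
        return cls(weights=np.array(rows), n_contexts=n_contexts)


def build_pwm(
    contexts: Sequence[str], pseudocount: float = 0.0
) -> KozakPwm:
    """Build a frequency PWM from observed 4-letter contexts.

    Weights are raw per-position frequencies (no pseudocounts by default:
    in-scope datasets have thousands of contexts, so zero cells are
    legitimate). A `pseudocount` added to every cell before normalization
    is available for tiny training sets.
    """
    if len(contexts) == 0:
        raise ContractError("cannot build a PWM from an empty context list")
    if pseudocount < 0:
        raise ContractError("pseudocount must be >= 0")
    counts = np.full((4, 4), pseudocount, dtype=float)
    for ctx in contexts:
        ctx = _check_context(ctx)
        for i, nt in enumerate(ctx):
            counts[i, _NT_INDEX[nt]] += 1
    weights = counts / counts.sum(axis=1, keepdims=True)
    return KozakPwm(weights=weights, n_contexts=len(contexts))


def context_score(pwm: KozakPwm, context: str) -> float:
    """Additive Kozak score: the sum over the 4 positions of the weight of
    the context's nucleotide there. Range [0, 4]."""
    context = _check_context(context)
    return float(
        sum(pwm.weights[i, _NT_INDEX[nt]] for i, nt in enumerate(context))
    )


@dataclass(frozen=True)
class ContextExtraction:
    """Result of context extraction: either a 4-letter context, or None
    with a reason code ('insufficient_5prime_context' / 'plus4_absent')."""

    context: Optional[str]
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.context is not None


def extract_context(sequence: str, tis_position: int) -> ContextExtraction:
    """Extract the -3,-2,-1,+4 context of a TIS from its transcript.

    With the first TIS nucleotide at +1 (0-based index `tis_position`),
    the context is sequence[tis_position-3 : tis_position] plus
    sequence[tis_position+3]. TISs closer than 3 nt to the 5' end, or
    lacking the +4 base, are flagged undefined rather than errored —
    boundary TISs are real data, not caller mistakes.
    """
    sequence = normalize_nucleotides(sequence)
    if tis_position < 3:
        return ContextExtraction(None, "insufficient_5prime_context")
    if tis_position + 3 >= len(sequence):
        return ContextExtraction(None, "plus4_absent")
    ctx = sequence[tis_position - 3 : tis_position] + sequence[tis_position + 3]
    return ContextExtraction(_check_context(ctx))


@dataclass(frozen=True)
class CorrelationResult:
    """Rank (or linear) correlation between context scores and initiation
    probabilities, with the number of undefined-context pairs dropped."""

    coefficient: float
    pvalue: float
    n_used: int
    n_dropped: int
    method: str
    degenerate: bool = False


def correlate_score_with_probability(
    scores: Iterable[Optional[float]],
    probabilities: Iterable[float],
    method: str = "spearman",
) -> CorrelationResult:
    """Correlate Kozak context scores with initiation probabilities.

    Pairs whose score is None/NaN (undefined context) are dropped and
    counted. Constant inputs yield a NaN coefficient flagged `degenerate`.
    `method` is 'spearman' (default; the score is ordinal in spirit) or
    'pearson'.
    """
    scores = list(scores)
    probabilities = list(probabilities)
    if len(scores) != len(probabilities):
        raise ContractError(
            f"length mismatch: {len(scores)} scores vs "
            f"{len(probabilities)} probabilities"
        )
    pairs = [
        (s, p)
        for s, p in zip(scores, probabilities)
        if s is not None and not np.isnan(s)
    ]
    n_dropped = len(scores) - len(pairs)
    if len(pairs) < 3:
        raise ContractError(
            f"need >= 3 defined pairs for a correlation, have {len(pairs)}"
        )
    xs = np.array([s for s, _ in pairs])
    ys = np.array([p for _, p in pairs])
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return CorrelationResult(
            coefficient=float("nan"),
            pvalue=float("nan"),
            n_used=len(pairs),
            n_dropped=n_dropped,
            method=method,
            degenerate=True,
        )
    if method == "spearman":
        res = stats.spearmanr(xs, ys)
    elif method == "pearson":
        res = stats.pearsonr(xs, ys)
    else:
        raise ContractError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        coefficient=float(res.statistic),
        pvalue=float(res.pvalue),
        n_used=len(pairs),
        n_dropped=n_dropped,
        method=method,
    )


__all__ = [
    "CONTEXT_POSITIONS",
    "ContextExtraction",
    "CorrelationResult",
    "KozakPwm",
    "build_pwm",
    "context_score",
    "correlate_score_with_probability",
    "extract_context",
]
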