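"""Exception hierarchy for leakyscan.

All package errors derive from :class:`LeakyScanError` so callers can catch
one type at a pipeline boundary; the subclasses mirror the distinct failure
modes of the contracts (bad file, bad value, bad call, mathematically
undefined input).
"""


class LeakyScanError(Exception):
    """Base class for all leakyscan errors."""


class FormatError(LeakyScanError):
    """A file does not conform to its expected format (missing column,
    duplicate FASTA id, empty file)."""


class ValidationError(LeakyScanError):
    """A value violates a domain invariant (negative signal, bad codon
    alphabet, out-of-bounds position)."""


class ContractError(LeakyScanError):
    """A call violates an API precondition (mismatched lengths, missing
    required argument, empty input where non-empty is required)."""


class DegenerateInputError(LeakyScanError):
    """Input is structurally valid but the requested quantity is undefined
    on it (e.g. zero total signal: no probabilities exist)."""
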