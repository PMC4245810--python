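"""Dataset-level diagnostics of TIS tables.

Two signatures of the scanning model are worth checking on any dataset
before trusting per-TIS probabilities:

* a codon that is *inefficient* as a start should appear more often as
  the first (5'-most) TIS of a multi-TIS mRNA — where scanning-ribosome
  density is highest — than as the last; a putative start codon enriched
  as the *last* TIS is suspect (likely arrested elongating ribosomes,
  not initiation);
* raising the detection threshold should shed weak TISs first, so the
  detected count is non-increasing and the non-AUG fraction (non-AUG
  starts are mostly weak) should fall.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .errors import ContractError
from .model import CodonClass, TranscriptTisSet

logger = logging.getLogger(__name__)


def first_last_codon_frequencies(
    tis_sets: Iterable[TranscriptTisSet],
) -> pd.DataFrame:
    """Frequency of each codon as the first vs the last TIS of an mRNA.

    Only transcripts with >= 2 TISs contribute (on a single-TIS mRNA the
    same codon is trivially both). Returns a DataFrame indexed by codon
    with columns `first_freq` and `last_freq`, each summing to 1 across
    codons; empty (with a logged warning) when no multi-TIS transcripts
    exist.
    """
    first: dict[str, int] = {}
    last: dict[str, int] = {}
    n_multi = 0
    for tis_set in tis_sets:
        if len(tis_set) < 2:
            continue
        n_multi += 1
        f = tis_set.tis_list[0].codon
        l = tis_set.tis_list[-1].codon
        first[f] = first.get(f, 0) + 1
        last[l] = last.get(l, 0) + 1
    if n_multi == 0:
        logger.warning("no multi-TIS transcripts: codon frequency table empty")
        return pd.DataFrame(columns=["first_freq", "last_freq"])
    codons = sorted(set(first) | set(last))
    df = pd.DataFrame(
        {
            "first_freq": [first.get(c, 0) / n_multi for c in codons],
            "last_freq": [last.get(c, 0) / n_multi for c in codons],
        },
        index=pd.Index(codons, name="codon"),
    )
    return df


def threshold_sensitivity(
    tis_sets: Iterable[TranscriptTisSet],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Detected-TIS count and non-AUG fraction as the threshold varies.

    For each threshold, counts TISs with signal >= threshold and the
    fraction of those that are not AUG starts. `n_detected` is
    non-increasing in the threshold; `fraction_non_aug` is NaN when
    nothing is detected.
    """
    if len(thresholds) == 0:
        raise ContractError("threshold list must be non-empty")
    all_tis = [t for ts in tis_sets for t in ts.tis_list]
    rows = []
    for thr in thresholds:
        detected = [t for t in all_tis if t.signal >= thr]
        n = len(detected)
        non_aug = sum(
            1 for t in detected if t.codon_class is not CodonClass.AUG
        )
        rows.append(
            {
                "threshold": thr,
                "n_detected": n,
                "fraction_non_aug": (non_aug / n) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


__all__ = ["first_last_codon_frequencies", "threshold_sensitivity"]
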