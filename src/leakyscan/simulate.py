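"""Scanning-ribosome simulator: the generative reading of leaky scanning.

A pool of scanning preinitiation complexes enters the 5' end of each
transcript and visits its TISs strictly 5'->3'; at TIS_i each surviving
complex initiates with the TIS's true probability p_i, otherwise scans
on. In expectation the footprint count at TIS_i is therefore

    R_i = p_i x budget x prod_{s<i} (1 - p_s)

and the residual budget x prod (1 - p_s) is the pool that scans past the
last TIS — exactly the undetectable-initiation mass the LS estimator's
artificial pseudo-TIS (R_u) stands for. Feeding expected counts back into
the LS estimator with ru = residual recovers the true probabilities
exactly; the stochastic mode replaces expectations with sequential
binomial draws so estimator bias and noise can be measured against a
known truth.

Stochastic sampling is implemented as successive binomial draws per TIS
(statistically identical to per-ribosome Bernoulli traversal, O(k) per
transcript regardless of budget). An optional per-inter-TIS-interval loss
fraction thins the scanning pool between TISs (default 0); it is a
pluggable stand-in for processivity losses that the probability model
itself does not represent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .model import (
    Method,
    ScanSimConfig,
    TisRecord,
    TranscriptTisSet,
)
from .probability import ls_probabilities, pas_probabilities
from .selection import OrfLabel, classify_orf_configuration

_STOP_SAFE_CODON = "GGC"  # replacement codon that can't create a stop
_TIS_SPACING = 12  # nt between planted TIS starts; multiple of 3 + 0 by default


def expected_counts(
    true_probabilities: Sequence[float], budget: float
) -> tuple[list[float], float]:
    """Expected footprint counts under leaky scanning, plus the residual.

    counts[i] = p_i x remaining_i with remaining_1 = budget and
    remaining_{i+1} = remaining_i x (1 - p_i); the residual
    budget x prod(1 - p_i) is the scanning pool left after the last TIS.
    Conservation holds exactly: sum(counts) + residual == budget.
    """
    if budget <= 0:
        raise ContractError(f"budget must be positive, got {budget}")
    for p in true_probabilities:
        if not (0.0 < p <= 1.0):
            raise ValidationError(
                f"true probabilities must be in (0, 1], got {p}"
            )
    counts: list[float] = []
    remaining = float(budget)
    for p in true_probabilities:
        c = p * remaining
        counts.append(c)
        remaining -= c
    return counts, remaining


def _draw_true_probabilities(
    config: ScanSimConfig, rng: np.random.Generator, k: int
) -> np.ndarray:
    spec = config.true_probabilities
    if callable(spec):
        p = np.asarray(spec(rng, k), dtype=float)
    elif (
        isinstance(spec, tuple)
        and len(spec) == 2
        and all(isinstance(x, float) for x in spec)
    ):
        lo, hi = spec  # a 2-tuple of floats is a uniform sampling range
        p = rng.uniform(lo, hi, size=k)
    else:
        vals = list(spec)
        if len(vals) < k:
            raise ContractError(
                f"fixed probability vector of length {len(vals)} cannot "
                f"cover {k} TISs"
            )
        p = np.asarray(vals[:k], dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("drawn true probabilities must be in (0, 1]")
    return p


def _draw_k(config: ScanSimConfig, rng: np.random.Generator) -> int:
    if isinstance(config.tis_per_transcript, int):
        return config.tis_per_transcript
    lo, hi = config.tis_per_transcript
    return int(rng.integers(lo, hi + 1))


@dataclass
class SimResult:
    """Output of a simulation run.

    `observed` holds per-transcript TIS sets after the detection
    threshold; `truth` is a tidy table with one row per *planted* TIS
    (transcript_id, position, codon, rank, true_p, count, detected), so
    analyses never have to reverse-engineer the generating parameters.
    `uninitiated` maps transcript_id to the scanning pool that passed the
    last TIS without initiating (includes loss-hook attrition).
    """

    observed: list[TranscriptTisSet]
    truth: pd.DataFrame
    uninitiated: dict[str, int]
    config: ScanSimConfig


def sample_counts(config: ScanSimConfig) -> SimResult:
    """Draw stochastic footprint counts from the scanning model.

    Per transcript, the scanning pool of `ribosome_budget` complexes is
    propagated 5'->3': before each TIS a Binomial(pool, loss_hook) share
    is lost (if loss_hook > 0), then Binomial(pool, p_i) complexes
    initiate and leave the pool. Counts below `detection_threshold` are
    dropped from the observed table but kept in the truth table.
    Reproducible: identical config (incl. seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    observed: list[TranscriptTisSet] = []
    truth_rows: list[dict] = []
    uninitiated: dict[str, int] = {}
    codons = list(config.codon_pool)
    weights = np.array([config.codon_pool[c] for c in codons], dtype=float)
    if weights.sum() <= 0:
        raise ContractError("codon_pool weights must sum to > 0")
    weights = weights / weights.sum()

    for t in range(config.n_transcripts):
        tx_id = f"sim_tx{t:05d}"
        gene_id = f"sim_g{t:05d}"
        k = _draw_k(config, rng)
        p = _draw_true_probabilities(config, rng, k)
        positions = [_TIS_SPACING * (i + 1) for i in range(k)]
        tis_codons = [codons[i] for i in rng.choice(len(codons), size=k, p=weights)]
        pool = config.ribosome_budget
        records: list[TisRecord] = []
        for i in range(k):
            if config.loss_hook > 0 and pool > 0:
                pool -= int(rng.binomial(pool, config.loss_hook))
            count = int(rng.binomial(pool, p[i])) if pool > 0 else 0
            pool -= count
            detected = count >= config.detection_threshold
            truth_rows.append(
                {
                    "transcript_id": tx_id,
                    "position": positions[i],
                    "codon": tis_codons[i],
                    "rank": i + 1,
                    "true_p": float(p[i]),
                    "count": count,
                    "detected": detected,
                }
            )
            if detected:
                records.append(
                    TisRecord(
                        gene_id=gene_id,
                        transcript_id=tx_id,
                        position=positions[i],
                        codon=tis_codons[i],
                        signal=float(count),
                    )
                )
        uninitiated[tx_id] = pool
        observed.append(
            TranscriptTisSet(
                transcript_id=tx_id,
                gene_id=gene_id,
                tis_list=records,
                is_single_isoform=True,
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "transcript_id",
            "position",
            "codon",
            "rank",
            "true_p",
            "count",
            "detected",
        ],
    )
    return SimResult(
        observed=observed, truth=truth, uninitiated=uninitiated, config=config
    )


def _plant_codon(seq: list[str], pos: int, codon: str) -> None:
    seq[pos : pos + 3] = list(codon)


def assign_codons_and_sequences(
    tis_sets: Sequence[TranscriptTisSet],
    config: ScanSimConfig,
    orf_configuration: Optional[OrfLabel] = None,
) -> list[TranscriptTisSet]:
    """Give each TIS set a synthetic transcript sequence.

    Start codons from `config.codon_pool` are planted at the recorded TIS
    positions in a random background (seeded from `config.seed`); stop
    codons read in the frame of the first TIS are then planted or removed
    to realize `orf_configuration` for two-TIS transcripts, if requested.
    The codon/sequence consistency invariant of TranscriptTisSet holds on
    every returned set.

    Raises ContractError when the requested configuration is impossible
    for the given positions (e.g. `same_orf` with (b - a) mod 3 != 0, or
    no room between the TISs to plant a stop).
    """
    rng = np.random.default_rng(config.seed + 1)  # decoupled from count noise
    codons = list(config.codon_pool)
    weights = np.array([config.codon_pool[c] for c in codons], dtype=float)
    weights = weights / weights.sum()
    out: list[TranscriptTisSet] = []
    for tis_set in tis_sets:
        if not tis_set.tis_list:
            out.append(tis_set)
            continue
        length = max(t.position for t in tis_set.tis_list) + 9
        seq = list(rng.choice(["A", "C", "G", "T"], size=length))
        new_records: list[TisRecord] = []
        tis_positions = []
        for tis in tis_set.tis_list:
            codon = codons[int(rng.choice(len(codons), p=weights))]
            _plant_codon(seq, tis.position, codon)
            tis_positions.append(tis.position)
        if orf_configuration is not None:
            if len(tis_set.tis_list) != 2:
                raise ContractError(
                    "orf_configuration requests apply to two-TIS "
                    f"transcripts; {tis_set.transcript_id} has "
                    f"{len(tis_set.tis_list)}"
                )
            a, b = tis_positions
            _realize_configuration(seq, a, b, orf_configuration)
        # codons may have been touched while realizing the configuration
        for tis in tis_set.tis_list:
            codon = "".join(seq[tis.position : tis.position + 3])
            new_records.append(
                TisRecord(
                    gene_id=tis.gene_id,
                    transcript_id=tis.transcript_id,
                    position=tis.position,
                    codon=codon,
                    signal=tis.signal,
                    region=tis.region,
                    frame=tis.frame,
                )
            )
        out.append(
            TranscriptTisSet(
                transcript_id=tis_set.transcript_id,
                gene_id=tis_set.gene_id,
                tis_list=new_records,
                sequence="".join(seq),
                is_single_isoform=tis_set.is_single_isoform,
            )
        )
    return out


def _frame_positions(a: int, b: int) -> range:
    """Codon start positions in the frame of `a`, strictly between the two
    start codons (after a's codon, ending before b's codon begins)."""
    start = a + 3
    stops = []
    p = start
    while p + 3 <= b:
        stops.append(p)
        p += 3
    return range(start, start + 3 * len(stops), 3) if stops else range(0)


def _realize_configuration(
    seq: list[str], a: int, b: int, label: OrfLabel
) -> None:
    from .model import STOP_CODONS

    frame_offset = (b - a) % 3
    if label is OrfLabel.SAME_ORF and frame_offset != 0:
        raise ContractError(
            f"same_orf impossible: (b - a) mod 3 = {frame_offset} != 0"
        )
    if label is OrfLabel.OVERLAPPING_ORFS and frame_offset == 0:
        raise ContractError(
            "overlapping_orfs impossible: TISs are in the same frame"
        )
    slots = list(_frame_positions(a, b))
    if label is OrfLabel.SEPARATED_ORFS:
        if not slots:
            raise ContractError(
                f"no room to plant a stop codon between positions {a} and {b}"
            )
        # extra stops downstream of the first are harmless
        _plant_codon(seq, slots[0], "TAA")
        return
    # same_orf / overlapping_orfs: the first ORF must stay open past b,
    # so clear every in-frame stop whose codon ends at or before b
    for p in slots:
        if "".join(seq[p : p + 3]) in STOP_CODONS:
            _plant_codon(seq, p, _STOP_SAFE_CODON)
    if frame_offset != 0:
        # a stop codon in a's frame straddling b would also end the first
        # ORF at b at the earliest; it ends after b, so the ORF still
        # covers b and the pair classifies as overlapping. Nothing to do.
        pass


@dataclass
class RecoveryReport:
    """Truth-vs-estimate comparison from a simulation run.

    `per_tis` has one row per (transcript, TIS rank) with true_p and the
    estimate; `by_rank` aggregates bias (mean estimate - true) and RMSE
    per 5'->3' TIS rank.
    """

    method: Method
    ru: float
    per_tis: pd.DataFrame
    by_rank: pd.DataFrame

    @property
    def bias(self) -> pd.Series:
        return self.by_rank["bias"]

    @property
    def rmse(self) -> pd.Series:
        return self.by_rank["rmse"]


def recovery_experiment(
    config: ScanSimConfig,
    method: Method = Method.LS,
    ru_policy: Union[str, float] = "residual",
    mode: str = "sample",
) -> RecoveryReport:
    """Simulate, estimate, and score recovery of true probabilities.

    `mode='sample'` draws stochastic counts via :func:`sample_counts`;
    `mode='expected'` uses noise-free expected counts. `ru_policy`
    chooses the pseudo-TIS signal per transcript:

    * ``'residual'`` — budget minus the transcript's total observed
      signal, i.e. the scanning pool that passed the last detected TIS
      (exact pool accounting when the detection threshold is 0); with
      this policy LS inverts the generator exactly in expected mode and
      is unbiased at every TIS rank in sample mode;
    * ``'threshold'`` — the detection threshold, the heuristic used on
      real data where the residual pool is unobservable;
    * a float — that fixed value (0 disables the pseudo-TIS).
    """
    if mode not in ("sample", "expected"):
        raise ContractError(f"mode must be 'sample' or 'expected': {mode!r}")
    if isinstance(ru_policy, str) and ru_policy not in (
        "residual", "threshold"
    ):
        raise ContractError(
            f"ru_policy must be 'residual', 'threshold' or a number, "
            f"got {ru_policy!r}"
        )

    def resolve_ru(total_observed: float) -> float:
        if ru_policy == "residual":
            return max(config.ribosome_budget - total_observed, 0.0)
        if ru_policy == "threshold":
            return config.detection_threshold
        return float(ru_policy)

    def estimate(tis_set: TranscriptTisSet, ru: float):
        if method is Method.LS:
            return ls_probabilities(tis_set, ru=ru)
        return pas_probabilities(tis_set)

    rows: list[dict] = []
    if mode == "expected":
        rng = np.random.default_rng(config.seed)
        for t in range(config.n_transcripts):
            tx_id = f"sim_tx{t:05d}"
            k = _draw_k(config, rng)
            p = _draw_true_probabilities(config, rng, k)
            counts, _ = expected_counts(p, config.ribosome_budget)
            tis_list = [
                TisRecord(
                    gene_id=tx_id,
                    transcript_id=tx_id,
                    position=_TIS_SPACING * (i + 1),
                    codon="ATG",
                    signal=c,
                )
                for i, c in enumerate(counts)
            ]
            tis_set = TranscriptTisSet(
                transcript_id=tx_id, gene_id=tx_id, tis_list=tis_list
            )
            result = estimate(tis_set, resolve_ru(sum(counts)))
            for i, (tp, est) in enumerate(zip(p, result.probabilities)):
                rows.append(
                    {
                        "transcript_id": tx_id,
                        "rank": i + 1,
                        "true_p": float(tp),
                        "estimate": est,
                    }
                )
    else:
        sim = sample_counts(config)
        truth_by_tx = dict(tuple(sim.truth.groupby("transcript_id")))
        for tis_set in sim.observed:
            if len(tis_set) == 0:
                continue
            result = estimate(tis_set, resolve_ru(sum(tis_set.signals)))
            truth = truth_by_tx[tis_set.transcript_id].set_index("position")
            for tis, est in zip(tis_set.tis_list, result.probabilities):
                row = truth.loc[tis.position]
                rows.append(
                    {
                        "transcript_id": tis_set.transcript_id,
                        "rank": int(row["rank"]),
                        "true_p": float(row["true_p"]),
                        "estimate": est,
                    }
                )
    per_tis = pd.DataFrame(
        rows, columns=["transcript_id", "rank", "true_p", "estimate"]
    )
    per_tis["error"] = per_tis["estimate"] - per_tis["true_p"]
    by_rank = (
        per_tis.groupby("rank")
        .agg(
            n=("error", "size"),
            bias=("error", "mean"),
            rmse=("error", lambda e: float(np.sqrt(np.mean(e**2)))),
        )
        .reset_index()
    )
    ru_label = float("nan") if isinstance(ru_policy, str) else float(ru_policy)
    return RecoveryReport(
        method=method, ru=ru_label, per_tis=per_tis, by_rank=by_rank
    )


__all__ = [
    "RecoveryReport",
    "SimResult",
    "assign_codons_and_sequences",
    "expected_counts",
    "recovery_experiment",
    "sample_counts",
]
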