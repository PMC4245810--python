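# Methods

## Model

Cap-dependent initiation is modelled as strict 5′→3′ scanning with
leakage: each scanning 40S complex encounters the TISs of an mRNA in
coordinate order and commits at TIS_i with probability p_i, otherwise
continues. Under this model the initiating-footprint signal R_i at TIS_i
is proportional to p_i times the pool of complexes that reached it, so

    p_i = R_i / (R_i + R_{i+1} + … + R_k + R_u)

where the suffix sum is the observable part of that pool and R_u is the
signal of a single artificial pseudo-TIS appended 3′ of all detected
TISs, aggregating every initiation event below the detection limit. The
baseline PAS estimate, R_i over the total mRNA signal, coincides with LS
only for the 5′-most TIS; downstream it is attenuated by the factor
(pool reaching TIS_i)/(total initiations), which for two TISs gives the
closed form PAS₂ = p₂(1−p₁)/(p₁ + p₂(1−p₁)).

Assumptions: footprint signal within one mRNA is proportional to
initiation events (library-size and transcript-abundance factors cancel
inside a transcript and are never compared across transcripts);
reinitiation and internal entry are absent (the candidate filters
enforce the former); all footprints of a transcript come from a single
isoform.

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| detection threshold | signal units | 0.05 | minimum TIS-calling threshold of the normalized R_LTM−R_CHX signal; comparison is inclusive (a TIS exactly at the minimum is detected) |
| R_u | signal units | detection threshold (0.05 lee-style, 50 ingolia-style) | the pseudo-TIS stands for sub-threshold initiation, so its mass is at most one threshold unit; R_u = 0 degenerates to P_k = 1 |
| allowed start codons | — | ATG, CTG | other near-cognate calls are heavily contaminated by arrested elongating ribosomes (diagnosed by the first-vs-last codon frequency table) |
| Kozak PWM pseudocount | counts | 0 | in-scope training sets have thousands of contexts; zero cells are legitimate |

Signal normalization follows R_k = (X_k/N_k)×10 per library (k = LTM,
CHX), differenced; negative values are representable and removed by
thresholding, not clamped.

## Candidate selection

A TIS pair is evidence for leaky scanning only if termination-
reinitiation cannot explain the downstream signal. The classifier
extends the 5′ TIS's ORF codon-by-codon (standard stop codons TAA, TAG,
TGA) to its first in-frame stop: if the ORF terminates at or before the
downstream TIS the pair is `separated_orfs` and excluded; in-frame pairs
with no intervening stop share one ORF (`same_orf`); out-of-frame pairs
whose first ORF is still open at the downstream start are
`overlapping_orfs`. "Overlapping" is read as: the downstream TIS lies
strictly within the first ORF — the only geometry under which downstream
initiation cannot follow termination. The stop scan covers codon starts
from the first TIS up to (exclusive) the downstream TIS; the codon
beginning exactly at the downstream start is the start itself and is not
scanned. The scan is run once, on the first TIS's frame, for all pair
geometries. Single-isoform status is taken from the input annotation,
never recomputed.

## Kozak context scoring

The PWM covers positions −3, −2, −1, +4 (first TIS nucleotide = +1) and
holds raw per-position nucleotide frequencies; a context's score is the
sum of its four positional weights (range 0–4). Frequencies rather than
log-odds keep the score's maximum at the per-position argmax string by
construction (typically ACC…G); the weighting scheme is isolated so a
log-odds variant can be swapped in. Score–strength association defaults
to Spearman rank correlation (Pearson available): the additive score is
an ordinal summary, and rank correlation is insensitive to its arbitrary
scale. TISs with fewer than 3 nt of 5′ context or no +4 base return an
undefined context with a reason code and are dropped (and counted) from
correlations.

## Simulator

The generator draws, per transcript, a TIS count, per-TIS true
probabilities, and start codons, then propagates an integer scanning
budget through the TISs as successive binomial draws — statistically
identical to per-ribosome Bernoulli traversal but O(k) per transcript.
Counts below the detection threshold are omitted from the observed table
but retained in a parallel truth table, so recovery experiments never
reverse-engineer the truth. Expected-value mode replaces draws by their
means; on such data the LS estimator with R_u equal to the residual pool
inverts the generator exactly (machine precision), which is the
package's primary correctness anchor. An optional per-inter-TIS-interval
loss fraction thins the scanning pool between TISs (default 0),
providing a hook for processivity effects outside the probability model.

Counting noise is binomial by construction. The simulator does not
emulate LTM/CHX chemistry, footprint-length distributions, mapping
ambiguity, overdispersion between replicates, or transcript-abundance
variation — passing recovery tests therefore demonstrates estimator
correctness under the scanning model, not robustness to those real-data
artifacts.

Default study conditions for stochastic recovery: 200 transcripts with
two TISs each, 10^5 scanning complexes per transcript, true
probabilities drawn uniformly per rank; at these sizes the Monte-Carlo
standard error of a per-rank bias is well below 0.01, the bound the
recovery check asserts. The worked three-TIS example (efficiencies 0.2,
0.8, 0.8; budget 1000) is exact arithmetic, not simulation.

### ru policies in recovery experiments

`residual` sets R_u per transcript to budget minus total observed signal
— exact pool accounting, usable only when the budget is known (i.e. in
simulation); with it LS is unbiased at every TIS rank. `threshold` uses
the detection threshold, the only policy available on real data; it
leaves the most 3′ TIS estimate near 1 whenever the residual pool is
genuinely large, an acknowledged limitation of the published heuristic.

## Numerical choices

Suffix sums are computed in one backward pass per transcript; TIS counts
per transcript are small (≤ tens) and well-scaled, so compensated
summation is unnecessary. Zero total signal (PAS) or a zero suffix-sum
denominator (LS with R_u = 0) raise degenerate-input errors naming the
TIS rather than returning clamped values. Tied TIS coordinates are
rejected on ingest: the scanning order of two TISs at one position is
undefined. Transcript coordinates are 0-based throughout; bedGraph
export is 0-based half-open over the 3-nt start codon. All sequence
handling is in the DNA alphabet (U→T on ingest).

## Known limitations

- R_u is a fixed per-mRNA constant, not estimated from data; the two
  published presets are exposed and any value accepted.
- The in-frame stop scan checks only the first TIS's ORF extent, for all
  pair geometries.
- No isoform quantification: multi-isoform genes are simply excluded.
- The probability model ignores elongating-ribosome occlusion of
  closely spaced starts; the simulator's loss hook is a stand-in, not a
  mechanistic model.
- bedGraph export maps transcript to genome coordinates only through a
  user-supplied offset table; no liftover is attempted.
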