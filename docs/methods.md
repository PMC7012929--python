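# Methods

## Problem

Long non-coding RNAs such as Eleanor2 (a 656-nt conserved transcription
unit on chr6, minus strand, hg19) act on chromatin in ways that depend on
their folded structure. Before testing fragments of such an RNA in vitro,
one wants to know which parts of the molecule fold as *self-contained local
structures* — regions that pair densely within themselves and barely at all
with the rest of the transcript — because those are the fragments most
likely to retain their fold when excised. This package computes that
decomposition from a base-pairing probability matrix, and carries the
small amount of exact bookkeeping (transcript termini, dosing equivalence)
needed to design the corresponding in-vitro experiments.

## The pairing ensemble and its probabilities

For a sequence of length L, the Boltzmann ensemble is the set of all
pseudoknot-free secondary structures. Under the package's folding model a
structure's weight is the product over its base pairs of a per-pair-type
weight, optionally multiplied by a stacking bonus for each pair whose inner
neighbour is also paired. Defaults:

| parameter | default | meaning |
|---|---|---|
| allowed pairs | AU, GC, GU | canonical plus wobble |
| pair weight | GC 3.0, AU 2.0, GU 1.0 | relative pair stability (dimensionless Boltzmann factors, order GC > AU > GU) |
| `min_loop` | 3 nt | minimum hairpin loop (steric constraint) |
| `stacking_bonus` | 1.0 (off) | multiplicative reward for helical stacking |

The partition value Z = Σ_S w(S) and the pairing probabilities
p_ij = Σ_{S ∋ (i,j)} w(S) / Z are computed by inside and outside dynamic
programming over the unambiguous rightmost-pair decomposition

    Z(i, j) = Z(i, j−1) + Σ_k Z(i, k−1) · Zb(k, j)
    Zb(i, j) = w_ij · [ Z(i+1, j−1) + (s−1) · Zb(i+1, j−1) ]

(the second term attributes each stack to its outer pair exactly once),
followed by the mirror-image outside recursion; both are O(L³) time and
O(L²) space, the same algorithmic skeleton as the standard McCaskill
computation under the full nearest-neighbour model.

This model is *not* the Turner nearest-neighbour model: loop sizes and
sequence context carry no energy beyond the pair weights, so absolute
probabilities differ from those of thermodynamic folders. The downstream
domain statistics consume only the matrix {p_ij}, so matrices computed by
an external Turner-model tool can be imported (plain TSV, or the Vienna
dot-plot `ubox` dialect where each stored value is √p) and scanned
identically. The package makes no claim of numerical identity with any
particular external folder or parameter set.

**Numerics.** The DP runs in plain double precision with an adaptive
per-nucleotide rescaling: every nucleotide carries a factor 1/scale, and if
any table cell overflows (or the final value underflows) the scale is
adjusted by exp(±600/L) and the pass repeated. For a 656-nt GC-rich
sequence Z exceeds 10³⁰⁰, so rescaling is required; probabilities are
ratios and are unaffected by the choice of scale. Contract, enforced by
test: agreement with exhaustive enumeration to 1e-9 (relative for Z,
absolute for each p_ij) at oracle scale.

## γ-centroid structure prediction

Given {p_ij} and γ > 0, the estimator reports the nested structure
maximizing Σ_{(i,j)∈S} [(γ+1) p_ij − 1]. Only pairs with p_ij > 1/(γ+1)
can contribute positive gain; the default γ = 4 (threshold 0.2) is the
conventional working point for locating well-supported helices. The
maximization is an O(L³) interval DP. Two canonical-form choices:

- Pairs with exactly zero gain (p_ij = 1/(γ+1)) are excluded; the argmax
  value is unchanged and the output is the minimum-pair optimum.
- Ties between equal-gain decompositions are broken toward fewer pairs,
  then toward the lexicographically smallest pair set (traceback prefers
  "position unpaired", then the smallest partner index), so output is
  deterministic. Because of such ties, the pair count is not strictly
  monotone in γ in degenerate cases; the test suite asserts monotonicity
  statistically over random matrices and surfaces any counterexample.

The DP does not re-impose `min_loop`: matrices produced by the folder
already have zero probability inside the loop constraint, and imported
matrices are taken at face value.

## Domain detection

Positions 1..L are divided into consecutive 10-nt blocks; when L is not a
multiple of 10 the trailing remainder forms a short final block, so no
position is dropped (656 nt → 66 blocks, the last of 6 nt). Every run of
successive blocks is a candidate D — B(B+1)/2 candidates for B blocks
(2211 at L = 656) — scored by

    p_inside(D) = Σ_{i<j; i,j∈D} p_ij / |D|²
    p_io(D)     = Σ_{i<j; exactly one end in D} p_ij / ((L−|D|) |D|)

A candidate is extracted when p_inside > 0.003 **and** p_io < 0.0003, both
strict. Conventions, each a deliberate choice where the formulas leave
room:

- **Pair counting.** The matrix is defined for unordered i < j, so both
  sums count each pair once, with the denominators exactly as written
  above. The `symmetric_double_count` flag counts each cross pair in both
  directions instead (doubling p_io); thresholds are then
  convention-dependent and must be supplied by the caller.
- **Whole-sequence candidate.** D = 1..L has an empty cross set and a zero
  denominator; p_io is defined as 0 (the empty sum) and the candidate
  remains scoreable.
- **Reporting.** Several overlapping candidates can pass simultaneously
  (any extension of a strong hairpin by weakly-pairing blocks dilutes
  p_inside only quadratically). `all_passing` reports them all;
  `maximal_passing` (default) drops candidates strictly contained in
  another passing candidate; `best_nonoverlapping` greedily keeps
  candidates by descending p_inside. The scanner contains no randomness.

Scoring uses 2-D prefix sums (O(1) per candidate after O(L²) setup); the
test suite checks it against an independently written double loop to
1e-12.

## Synthetic fixtures

`matrix_only` mode writes an idealized hairpin signature straight into a
matrix: for a planted interval of span s, an anti-diagonal stem of
⌊s/3⌋ entries at the chosen stem probability occupies the outer two-thirds
of the interval (the inner third is the unpaired loop), plus sparse uniform
cross-noise elsewhere — about one entry per position, each below the
`background_noise` bound. The generator refuses specifications whose noise
bound reaches the p_io threshold, because the worst-case cross statistic of
any candidate is bounded by the noise level: below the threshold, noise can
never mask a planted domain. Row sums are validated against the
one-partner-per-base bound.

For recovery experiments the stem probability is calibrated per span
(`detectable_stem_probability`): the planted candidate's p_inside is placed
at the geometric midpoint of the open window
(t_inside, t_inside·((s+10)/s)²) in which the planted interval passes but
any one-block extension fails, making the planted domain *sharp* — exactly
recoverable under `maximal_passing`. Spans beyond ~100 nt would need stem
probabilities above 1 to stay sharp and are refused. Under these
conditions the scanner recovers 100 of 100 planted domains at L = 120
(spans 30–80 nt, default thresholds); any failure would have to come from
noise crossing a threshold, and the acceptance test prints the failing
seeds for inspection.

`sequence_with_hairpins` mode emits a sequence whose planted intervals are
random G/C inverted repeats (outer two-thirds of the span) closed by
A-only loops, embedded in an A-only background. Adenosine pairs with
nothing under the AU/GC/GU rules in a U-free sequence, so the pairing
ensemble concentrates on the planted stems; folding such a sequence and
scanning it recovers a domain covering each plant end-to-end.

**What the fixtures do not emulate:** real transcripts have heterogeneous
composition, competing near-isoenergetic folds, non-zero pairing between
domains, and Turner-model loop energetics. Passing the recovery sweep shows
the scanner implements its definition correctly and is robust to
sub-threshold noise — not that the thresholds are optimal for any
particular biological transcript.

## Transcript construction and dosing

Run-off T7 transcription from a pGEM-style template adds GGG (promoter) at
the 5′ end; linearization with EcoRV leaves GAC, with NruI leaves UCG, at
the 3′ end — every construct is insert + 6 nt (656 → 662).

Dosing equivalence between RNAs of different lengths: in
`equimolar_nucleotides` mode the nucleotide molarity c·L is conserved, so
the target concentration is c_ref · L_ref / L_target; `equal_mass` mode
conserves mass concentration, which under a single mean residue mass
(default 320.5 g/mol per residue, a conventional value — the package does
not infer it from data) reduces to the same length ratio. A mass variant
returns c·L·m/1000 in ng/μl. Whether a dose is computed against the insert
length or the full transcript length is the caller's choice; published
figure legends are internally consistent only under full-transcript lengths
for the equimolar series and insert length for the equal-mass series, and
the worked examples follow that usage.

## Problem sizes

The test suite and the acceptance script use enumeration oracles at
L ≤ 14 nt (200 draws), brute-force centroid search at ≤ 6 candidate pairs
(500 draws), double-loop score checks at L ≤ 60 (1000 draws), and a
100-run recovery sweep at L = 120 — sizes at which the oracles are exact
and the whole battery completes in seconds.

## Known limitations

- No pseudoknots, no suboptimal-structure sampling, no temperature or
  Turner thermodynamics in the built-in model.
- Printed domain endpoints from published work on Eleanor2 (250–302,
  320–447) are not block-aligned; reproducing them would require the exact
  hg19-derived sequence and the output of a specific external folder
  version, so the scanner reports block-aligned candidates only and those
  coordinates are not a contract of this package.
- `maximal_passing` prefers larger passing candidates by construction; for
  strong stems the reported maximal domain can be wider than the minimal
  hairpin-bearing interval.
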