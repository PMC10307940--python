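# Methods

## Model

An STR locus is specified by a repeat expression over IUPAC nucleotide
codes: literal blocks, `{...}` skippable blocks, `(...)` blocks traversed at
least once and arbitrarily often. The expression, framed by reference flank
sequence, compiles to a nucleotide-level finite-state automaton whose
language is exactly `left_flank · w · right_flank` for every word `w` the
expression can spell. Repeat groups get a back transition from their exits
to their entries; optional blocks are bypassed by direct edges; IUPAC
symbols stay symbolic at this level.

The automaton is then expanded to k-mer space (k from the pore model,
default 6): each length-k path becomes a state carrying the expected current
level of its k-mer; two states connect when their k-mers overlap by k−1 and
the underlying base transition exists. IUPAC symbols are instantiated into
one concrete state per nucleotide choice at this stage, because pore models
are defined over {A,C,G,T} only. **State identity is positional**: two
length-k paths merge only if they share both the k-mer string and the base
automaton's end state. Identical k-mers at different structural positions
stay distinct, which is what makes transition counting equal repeat length.
A consequence worth knowing: the forward and reverse-strand automata accept
exactly reverse-complementary languages but need not have identical state
counts, because reversal exchanges path end states for start states and so
changes which paths merge.

Two automata are built per locus, forward and reverse; the reverse one is
the forward construction applied to the reverse-complemented, order-reversed
expression with swapped, reverse-complemented flanks. A read's mapped strand
selects the automaton; signal is always consumed in its native temporal
order.

### Alignment

For signal points s₁…sₘ and states with expected levels eⱼ, the dynamic
program M[i,j] = min over k ∈ {j} ∪ pred(j) of M[i−1,k] + |sᵢ − eⱼ| finds the
cheapest warping path that consumes every point in order, starts in the
first left-flank k-mer state and ends in the last right-flank k-mer state
(global anchoring over the extracted segment). A minimum event size s
(default 4 points) is enforced by augmenting the DP state with a capped
"points still owed" counter: a transition out of a state is allowed only
once its run has met the requirement looked up at the run's first signal
index. Complexity is O(m · n · d · s). Ties prefer staying in the current
state, then predecessors in lexicographic k-mer order, making paths
reproducible. STR length = number of transitions between distinct states
whose destination is a repeat-region state; each `(...)` group's entry
boundary crossings give per-unit counts, and optional-block traversals are
tallied separately (so `(CAGG{CAGM})` reports CAGG units and interruptions).

Note the anchored optimum is **not** monotone in signal length (truncating
an (m+1)-point optimal path need not end in an accept state); what does
hold, and is tested, is cost(m+1) ≤ cost(m) + the cost of dwelling one more
point in the previous end state.

### Normalization and the pore-model scale

Median normalization: shift = (perc₄₆.₅(R) + perc₅₃.₅(R))/2 (linear
interpolation between order statistics), scale = medianᵢ|rᵢ − shift|. It is
computed on the extracted locus-spanning segment (flanks + repeat), which is
what gets aligned, not on the whole read. The pore-model table is put on the
same dimensionless scale by applying the identical statistics to its 4^k
levels once per model. The residual mismatch between the two — the segment's
level composition is repeat-skewed, the table's is uniform — is the
systematic deviation the polishing phase corrects; it exists even for
perfectly clean signal.

### Polishing

After the first pass, every state's aligned points are pooled into
(mean mⱼ, SD σⱼ, count); pairs with |mⱼ − eⱼ| > 2.0 normalized units or
σⱼ > 1.5 × median σ are dropped as likely misalignments. Control points
within 0.05 normalized units of each other are merged (near-coincident
abscissae are contradictory evidence from misaligned states and also
destabilize smoothing-parameter selection), the expected levels are
projected onto a nondecreasing sequence (isotonic regression — the map is
monotone by construction of the signal scale), and a cubic smoothing
B-spline with GCV-selected smoothing is fitted; if that fit fails a
monotonicity/range check on the control range, a monotone piecewise-cubic
(PCHIP) interpolant through the same points is used instead. Outside the
control range the map extrapolates linearly with the boundary slope. With
fewer than 8 retained pairs polishing is skipped (identity, warning). The
whole signal is mapped pointwise and re-aligned.

### Adaptive event-size restriction

The first-pass path is split into windows of m = 6 events. Each window of w
points is scanned with a sliding 2p subwindow (p = 3 points), computing
Welch's t between the two halves with the population-variance convention
t = (S̄₁ − S̄₂)/√((σ²₁ + σ²₂)/p); |t| peaks above 3.0 (strict local optima;
plateaus count once at their earliest index) mark context changes. A window
with more peaks than events presumably hides events shorter than s, and its
minimum is reduced by one (never below 1) for the second pass; a run's
requirement is looked up at its first signal index. p, the threshold, and m
are configurable and recorded in output metadata; the defaults were fixed
once as reasonable operating points, since only m is externally prescribed.

### Genotyping

Per-read final lengths are filtered (estimates further than 2 population
SDs from the mean are removed; an SD of 0 removes nothing) and clustered by
a Bayesian Gaussian mixture (scikit-learn; ≤ 2 components, tied covariance,
weight-concentration prior 0.25, 5 initializations, 1000 iterations, fixed
seed). The locus is homozygous when the smaller cluster does not exceed 20 %
of the *unfiltered* read count (the literal reading; a post-filter
denominator is available by configuration), reporting the overall median;
otherwise heterozygous with the two cluster medians. Integer medians use the
lower median. Fewer than 3 reads → no-call with a reason.

### Truth derivation and metrics

Gold-standard alleles come from benchmark variant records: per haplotype,
reference length plus signed indel length deltas (unphased heterozygous
records put the alternative on the second haplotype slot; overlapping
records discard the locus). Multi-caller estimates are combined by
consensus: one caller → discard; two callers must agree exactly; k ≥ 3 need
k−1 in agreement. Metrics: per-read error = distance to the nearer truth
allele (MAE mean, MedAE median); genotype distance D = |ŷ₁−m₁| + |ŷ₂−m₂| on
sorted pairs, with a homozygous side's single allele duplicated when the
other side is heterozygous, and D = |ŷ−m| when both are homozygous. The
benchmark locus-selection filter (motif length 2–6, region > 30 bp, no
homopolymer run > 6) is provided as a standalone predicate.

## Simulator

The simulator is the package's sequencing stand-in: for each overlapping
k-mer of a known sequence it emits a dwell of points at the k-mer's expected
level plus Gaussian noise, applies a per-read baseline shift and scale, and
records the exact move map, dwells, and STR boundaries as truth (truth is
always recorded at generation, never re-derived). Reads are split between
alleles and strands; basecalls are idealized, with optional uniform
substitution noise to exercise flank localization and the basecall-distance
baseline.

Key modelling choices, with rationale:

- **Dwell**: shifted geometric, mean 8.5 points per context (the typical
  translocation rate), minimum 3 points. The minimum matters: a
  minimum-event-size aligner cannot represent events shorter than its
  constraint, and with a hard floor of 1 point about a third of events fall
  below s = 4, making whole-unit drops the cheapest explanation on every
  read. Real segmentation pipelines impose a comparable lower bound on
  event durations (~3–5 samples at this rate), so minimum 3 is the
  realistic operating condition and the package's default.
- **Synthetic pore model**: the 4^k levels are an evenly spaced grid over
  [60, 120] (model units) shuffled deterministically; callers may name
  groups of k-mers that co-occur in one automaton (e.g. a repeat cycle per
  strand), and the permutation is redrawn until each group is pairwise
  separated by ≥ 12 units, guaranteeing neighboring states are
  distinguishable above the noise floor. Separation is per group, not
  global — forcing all focus k-mers apart jointly is infeasible and
  unnecessary, since opposite-strand cycles never share an automaton.
- **Distortion**: optional monotone level distortion, either affine or
  piecewise-affine around a pivot. A *global* affine distortion is removed
  exactly by median normalization (both are affine maps), so the distortion
  used to exercise polishing is piecewise-affine — monotone and invertible
  but globally non-linear, the kind of table-vs-signal deviation the spline
  is built to undo.

What the simulator does **not** model: basecaller error beyond uniform
substitutions, event skips/stalls beyond dwell dispersion, level-dependent
(heteroscedastic) noise, or real pore chemistry. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms
under controlled squiggle statistics, not end-to-end accuracy on real
flowcell data.

## Numerical and test-design choices

- Alignment DP: float64 costs; infeasibility (no dwell-feasible path)
  raises a typed error counted as a per-read discard.
- Flank localization: Biopython local alignment, match +1 / mismatch −1 /
  gap −1, acceptance at 0.7 × flank length; hits must be ordered. Default
  flank length 110 bases; the automaton models a configurable innermost
  portion of each flank, and the signal segment is excised with a k−1 base
  offset so its first event is exactly the automaton's start context.
- Problem sizes in the test suite were chosen to keep the exhaustive
  brute-force path oracle exact and fast: ≤ 8-state automata with signals of
  ≤ 13/20/24 points for minimum dwells 1/2/4 (the enumeration count grows
  exponentially at small dwell), ~120 instances. Simulation-based checks use
  k = 3, 40-nt flanks, repeat counts 5–50 with 50 reads per count, and 100
  diploid replicates of 16 reads at noise 0.25–0.3 × the minimum cycle-level
  gap.
- Determinism: every stochastic component (simulator, mixture fit) takes an
  explicit seed; pipeline reruns produce byte-identical reports.

## Known limitations

- Homopolymer repeats are out of scope (single-state self-loops tie with
  dwelling under the cost model; the tie-break prefers dwelling).
- The automaton has match states only — no insertion/deletion states and no
  probabilistic emission model — so previously unseen variation inside the
  repeat can only be absorbed as alignment cost.
- Dinucleotide motifs (two alternating levels) remain intrinsically hard to
  distinguish from noise, as for any level-based method.
- FAST5/POD5/BAM ingestion is not bundled; the canonical input is the
  documented JSONL per-read container (raw signal, basecall, move map,
  strand), which any adapter can produce.
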