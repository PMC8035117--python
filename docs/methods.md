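# Methods

`procliq` implements a two-step procedure for identifying common response
processes in time-stamped action sequences, the kind of log produced by
interactive assessment items, simulations, or instrumented user
interfaces. Step 1 quantifies the pairwise similarity of *action
patterns*; Step 2 partitions a thresholded similarity graph into
homogeneous cliques by exact weighted cluster edge deletion. Each clique
is then profiled as a response process.

## Data model

An action pattern for person *i* is a length-*u* sequence of pairs
(a_im, t_im): the *m*-th action label and its time-to-action — the
seconds elapsed since the previous action, or since task onset for the
first action. Total task time T_tot is the sum of all times-to-action;
the log is assumed to end at the final (task-advancing) action, so no
post-final time exists. In timestamp mode, times-to-action are first
differences of timestamps, with the first measured from a caller-supplied
onset (whether timing starts at item administration or interface exposure
is a property of the logging system, so the onset is an explicit
parameter rather than a convention). Zero times are allowed (events below
timer resolution); negative computed times are rejected as corrupt input.

Preprocessing supports dropping labels (e.g. an automatic "start" event
whose time-to-action is zero by construction) and aggregating raw labels
into higher-level categories. A dropped action's time is removed with it
rather than folded into the successor: for the canonical zero-time drop
the two choices coincide, and removal is the simpler general rule. A
fold-forward variant was considered and not built; the recoding table is
the extension point if it is ever needed.

## Similarity measures

All measures are built on the longest common subsequence (LCS) of the
two action sequences — the longest sequence of labels occurring in order
(not necessarily contiguously) in both — together with the index maps
embedding it into each sequence, which attribute times-to-action to the
shared actions.

- **original**: the mean of min(t_i, t_j)/max(t_i, t_j) over the
  LCS-mapped time pairs, weighted by importance (below). Sensitive to
  per-action timing differences.
- **modified**: min/max of the two *total* times spent on the LCS,
  weighted by importance. Sensitive only to aggregate pacing over the
  area of overlap, hence more robust when single-action latencies are
  noisy.
- **action_only**: sqrt((|LCS|/u_i)(|LCS|/u_j)); a timing-free baseline.

**Importance** is sqrt((T_LCS^i/T_tot^i)(T_LCS^j/T_tot^j)), the geometric
mean of the share of each person's total task time spent on LCS-mapped
actions; it down-weights incidental overlap (ubiquitous framing actions)
relative to overlap that dominates both people's time budgets.

Numerical conventions: a min/max ratio with both operands zero is defined
as 1 (identical timing; the limit of equality), with one operand zero as
0. An empty LCS gives similarity 0 under all measures without evaluating
the timing terms. Importance requires positive total task time and raises
otherwise. All measures lie in [0, 1], equal 1 on identical patterns, and
are invariant under common rescaling of both patterns' times (property-
tested).

**LCS tie-break.** Multiple maximal common subsequences can exist, and
the timing measures depend on which is chosen. The traceback is
canonicalised: matches are taken greedily left-to-right, always choosing
the lexicographically smallest feasible index pair. Additionally, each
unordered pair of patterns is oriented canonically (by sorted action/time
content) before the traceback, so the similarity value is independent of
argument order; the pairwise driver also computes each unordered pair
exactly once. The same canonical LCS is reused by the clique-summary
stage. This convention is ours; any fixed deterministic tie-break would
do, and differently tied implementations can legitimately differ in the
third decimal on tie-prone pairs.

## Graph construction

Vertices are the N patterns; the edge {i, j} with weight s_ij is included
iff s_ij ≥ κ. The comparison is inclusive: the convention is that edges
*below* the threshold are excluded, so boundary equality keeps the edge.
κ ∈ (0, 1] encodes the minimum similarity required for two patterns to be
allowed into the same clique downstream; the default κ = 0.50 treats a
medium similarity as sufficient. Isolated vertices are retained — they
become singleton (idiosyncratic) cliques. Raising κ only removes edges;
the vertex set never depends on κ. Automatic κ selection is out of scope.

## Cluster edge deletion

A cluster graph is a disjoint union of cliques, equivalently a graph with
no induced P3. Weighted cluster edge deletion removes a minimum-weight
edge set to turn the input graph into a cluster graph; insertions are not
allowed, so every pair inside a resulting clique was connected (s ≥ κ) in
the input. This deletion-only restriction is what makes cliques readable
as "everyone here is at least κ-similar to everyone else here".

The problem is NP-hard and solved exactly as a 0/1 ILP: binary x_ij per
input edge, maximize Σ s_ij·x_ij subject to the transitivity/P3
constraints x_ij + x_jk − x_ik ≤ 1 over vertex triples, with x fixed to 0
on non-edges. Only triples carrying at least two input edges generate
constraints — for a triple with two edges and a missing third the
constraint tightens to x_ij + x_jk ≤ 1, and triples with fewer edges are
vacuous. This pruning changes nothing about the optimum (the dropped
constraints are implied by the zero-fixing) and keeps the model size
proportional to paths in the graph rather than N³; it is cross-checked
against an exhaustive oracle. The MILP is solved by HiGHS through
`scipy.optimize.milp`, deterministic for a fixed input; default time
limit one hour, with the solver status (`optimal` vs `feasible`
incumbent) reported honestly in results metadata. Maximizing retained
weight and minimizing deleted weight are complementary objectives;
retained weight is reported, and objective = total weight − deleted
weight is asserted in tests.

The brute-force oracle enumerates all set partitions (Bell-number many,
capped at 12 vertices), keeps those whose blocks are input cliques, and
maximizes retained within-block weight — exact by construction and
independent of the ILP path. Co-optimal solutions may differ in the
partition; equivalence is asserted on objectives (tolerance 1e−9).

Full cluster editing (insertions allowed at a configurable cost) exists
as a flagged variant for small graphs; it is off the default path and
outside the validated surface, because inserted edges break the
κ-guarantee above.

## Clique summaries

Each clique is profiled by: size; the *most common LCS* — the modal
canonical pairwise LCS over all member pairs (ties broken by
multiplicity, then length, then lexicographically); the share of members
containing that sequence; the median time-wise importance and median time
spent on it among containing members (times attributed via the leftmost-
greedy embedding — alternative embeddings could shift the time-on-LCS
medians slightly); and the median and middle-50% range of total task time
and sequence length over all members. A singleton clique's common LCS is
its member's own sequence. A multi-sequence LCS would be NP-hard and is
not what "most common LCS" denotes here; the modal pairwise LCS reuses
alignments that are already computed. The idiosyncrasy report contrasts
singleton cliques with dominant cliques (size ≥ 5 by default): medians
and ranges of total time and sequence length, and per-action occurrence
proportions.

## Synthetic data generator

Real logs of this kind show (a) groups sharing a core strategy — the same
actions in the same order, (b) idiosyncratic extra actions interleaved
(exploration, checks, help), (c) positively skewed per-action latencies
with group-specific pacing, and (d) a few outliers with long erratic
sequences. The generator reproduces exactly these features: per group a
core action sequence, member count, time-scale multiplier, log-normal
latency sigma, and a noise-insertion rate (an independent insertion
opportunity before each core action and at the end); outliers draw long
uniform-random sequences over the full vocabulary with high-variance
times.

Defaults — the study conditions used by the tests and left fixed:
three groups of 10 members plus 2 outliers; per-action median latency
2 s at scale 1 (a typical interface-action latency); log-normal
sigma 0.20 and insertion rate 0.10 (the upper ends of the low-noise
regime for which group recovery is claimed); group time scales 1.0 / 3.5
/ 1.0, where the first two groups share one core (separable only through
pacing — a 3.5× gap keeps the between-group min/max timing ratio below κ
with margin) and the third follows a different action route sharing only
the final confirm (separable through actions alone). With the modified
measure and κ = 0.5 the full pipeline recovers the planted partition
(mean adjusted Rand ≥ 0.8 over 10 seeds; in these conditions it is
typically 1.0) and isolates outliers as singletons.

What the generator does *not* emulate: realistic action vocabularies or
frequency profiles of any particular assessment item, within-group
strategy sub-variation, correlated latencies (e.g. person-level speed
factors), or missing/truncated logs. Passing recovery tests therefore
shows the pipeline is correct and well-calibrated under clean planted
structure, not that any particular κ or measure is right for a given real
instrument.

## Problem sizes and runtime

The test suite and acceptance checks run at deliberate desk scale: the
4-vertex illustration graph, ~200 random graphs with 4–8 vertices for the
ILP-vs-oracle equivalence, and ten 32-pattern synthetic cohorts for
recovery — chosen so the exact oracle (Bell-number enumeration) stays
trivially cheap and the whole suite completes in seconds. The ILP itself
scales much further (hundreds of vertices, depending on graph density);
the solver time limit and status reporting exist precisely because
worst-case running time is exponential.

## Known limitations

- Results can depend on the LCS tie-break convention on tie-prone pairs;
  the convention is fixed and documented but not the only defensible one.
- κ is user-set; no data-driven threshold selection is provided.
- Heuristic solvers for large instances are out of scope; beyond the
  practical ILP range the tool reports a `feasible` incumbent rather
  than an optimum.
- Clique summaries use the leftmost-greedy time attribution; timing
  medians on the common LCS are convention-dependent at the margin.
- The covariate-join surface (relating cliques to external variables) is
  a plain membership table; no statistical comparison across cliques is
  built in.
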