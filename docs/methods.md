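# Methods

## The problem

Network motif discovery asks whether a small subgraph (a feed-forward
loop, a mutual pair, a co-targeting switch) occurs in a regulatory
network more often than chance would allow.  "Chance" is operationalized
as a background ensemble of randomized networks with the same degree
structure as the real one; a class is a motif when its observed count is
extreme against the background count distribution.  The entire inference
therefore stands or falls with the randomizer.  Edge switching — the
default randomizer in most motif tools — preserves every node's exact
in- and out-degree by repeatedly exchanging the endpoints of two edges,
but on large networks with hub nodes it explores the space of admissible
graphs poorly: many proposed switches fail (they would create duplicate
edges), background count distributions come out too narrow, and classes
"stand out" spuriously.

This package implements a weighted-placement randomizer with reverse
swaps for multi-layer transcription-factor / microRNA / gene networks,
together with the edge-switch baseline, an exact colored subgraph census
(sizes 1–3), the motif statistics, a brute-force enumeration oracle for
uniformity experiments, and a synthetic-network generator so that every
stage is testable without external data.

## The network model

Nodes carry one of three types: TF, miRNA, or (non-TF protein-coding)
gene.  Genes never regulate, so a network decomposes into exactly five
layers: TF→TF, TF→miRNA, TF→gene, miRNA→TF, miRNA→gene.  Only the TF→TF
layer can contain self-loops (autoregulation).  Each layer is treated as
a directed bipartite graph with a prescribed out-degree per source and
in-degree per target; because the five layers have distinct
(source-type, target-type) signatures, independently randomized layers
recombine without ever colliding on an edge.

## The core randomizer

For one layer with m edges, sources are visited once in descending
out-degree order.  A source S with required degree deg(S) fills its
quota by weighted sampling without replacement over the targets, with
attraction weight

    w(S,T) = cap(S) · cap(T) · (1 − deg(S)·deg(T) / (p·m))

where cap(·) are residual capacities and deg(·) total required degrees.
The multiplicative correction damps hub–hub placements, which would
otherwise be grossly over-selected by pure capacity-proportional
sampling.  The integer multiplier p defaults to 6, the smallest value
that keeps the correction inside (0, 1) for hub-heavy regulatory
networks of the scale this method targets; whenever a layer's maximum
degree product makes the correction non-positive, p is escalated
per-layer to the smallest valid integer (logged).

Because heavy sources go first, a later source can reach a state where
every remaining unsaturated target is already among its targets.  A
reverse swap resolves this: pick such a target T_si uniformly, pick
uniformly a placed edge S′→T′ with T′ not targeted by S and T_si not
targeted by S′, redirect S′ to T_si and give S the freed target T′.
When self-loops are disallowed, the stuck source's own in-slot is a
valid swap destination (the relocated edge comes from another source)
even though the source could not fill it directly.  Each swap resolves
one unplaced edge, so the pass always terminates; infeasible sequences
(no valid swap exists) raise an explicit error.  On realistic layers
swaps are rare — hub-heavy synthetic networks need well under one swap
per randomized network on average.

The complete method additionally permutes each layer's target in-degrees
before sampling.  Binding sites are gained and lost over evolutionary
time, so the null preserves each layer's in-degree *distribution* rather
than pinning every target to its exact in-degree.  By default the
permutation universe is the targets that carry at least one edge; a flag
widens it to all nodes of the target type, allowing target-set turnover.
Out-degrees are always realized exactly.

### What the sampler does and does not guarantee

The weighted placement is a near-uniform heuristic, not an exact uniform
sampler.  On the packaged 13-realization bipartite example its exact
distribution (computed by path enumeration) has total-variation distance
0.027 from uniform and a maximum per-realization bias of +18% — every
realization is sampled, frequencies sit within ±25% of uniform, and on
the extreme large-hub example the unique no-hub-hub realization is
slightly *over*-sampled rather than starved.  But a chi-square test
against exact uniformity will reject given enough draws (the bias is
real), and on miniature near-regular instances a well-budgeted edge-
switch chain can actually be closer to uniform, because such chains mix
essentially completely on graphs this small.  The regimes where edge
switching degrades — large hub-heavy layers with high failed-switch
rates and too-narrow background distributions — are exactly the regimes
the weighted sampler is built for; the miniature examples exist to make
uniformity *measurable*, not to rank the methods at scale.

## Edge-switch baseline

Switches are drawn within layers (a cross-layer switch would change a
node's per-layer degree profile), with a budget of `attempts_per_edge ×
m` per layer (default 3).  An attempt fails — counted, graph unchanged —
if it would create a duplicate edge or a self-loop, including the
degenerate shared-endpoint attempts that would recreate the existing
pair.  We report failures/attempts; the failure rate is an intrinsic
property of the degree structure and stays roughly constant as the
budget grows.  Self-loops are removed before switching in this mode.

## Subgraph census

Connected induced colored subgraphs of sizes 1–3 are enumerated exactly
(ESU-style growth from each vertex over the undirected skeleton, so each
subgraph is produced once), and classified by the lexicographically
minimal color-preserving relabeling — brute force over at most 3! = 6
permutations.  Counts stay integers end to end; frequencies are never
stored, avoiding precision loss for rare classes.  Two modes:

* **plain** — self-loops ignored entirely (for comparison with
  loop-unaware tools);
* **decorated** — a TF carrying a self-loop becomes a fourth color and
  loop edges are then dropped, so e.g. a feed-forward loop whose two
  regulators may each be autoregulatory splits into four classes.

Size-2 classes distinguish single edges from mutual ("two-loop") pairs;
size-1 classes are self-loop counts per color.

## Motif statistics

Per class: background mean and sample SD (N−1) over N randomized
networks, z = (observed − mean)/SD, and the one-sided empirical
P = #{background ≥ observed}/N, reported as "< 1/N" when zero.  A class
is a motif only when simultaneously P < 0.01, z > 2.0 and SD > 1 — the
SD gate rejects exactly the too-narrow backgrounds that signal
insufficient randomization, and classes with SD = 0 are flagged
degenerate and never called.  Only over-representation can gate a call.
No multiple-testing correction is applied: the analyses this serves
compare nested, mutually dependent networks where a correction has no
clean interpretation, and the output is a hypothesis-generation ranking.

A stability curve quantifies how many backgrounds are enough: for each
checkpoint n, the distribution over classes of |P(n) − P(n_max)|.  On
the packaged synthetic networks the maximum difference between P at
2,500 and at 10,000 backgrounds falls below 0.02, which is why 2,500 is
the pipeline default.

## Enumeration oracle and the canonical examples

For small degree sequences, `enumerate_realizations` lists every labeled
simple realization by depth-first assignment (sources in descending
degree order, capacity pruning, explicit expansion budget).  Three
sequences are packaged, with their totals asserted at load:

| name | sequence | realizations |
|---|---|---|
| small_bipartite | out (3,2,1,1) / in (3,2,1,1) | 13, exactly 1 without the hub–hub edge |
| medium_bipartite | out (3,2,2,1) / in (3,2,1,1,1) | 58 |
| large_hub | shared nodes: out-hub (10,0), in-hub (0,10), ten spokes (1,1) | 101 with loops; 91 without; 10 containing a loop |

The large-hub example is the canonical hard case: its unique no-hub-hub
realization is the double star (out-hub → every spoke → in-hub), the 90
remaining loopless realizations contain the hub–hub edge, and 10
realizations carry a spoke self-loop.  `evaluate_sampler` maps sampled
graphs to realization fingerprints (hard error on a degree violation)
and reports frequencies, total-variation distance, chi-square
goodness-of-fit and never-sampled realizations; an exact-uniform
reference sampler calibrates the metrics.

## Synthetic networks

The generator emulates the hub-heavy regime: truncated-Zipf out-degrees
(default exponent 1.8, which yields TF hubs with out-degree well above
10× the median), heavy-tailed target attractiveness so in-degrees are
uneven too, TF self-loops at rate 0.1, and per-layer edge budgets met to
within ~5%.  Defaults produce a ~570-node network (50 TF, 20 miRNA, 500
gene, ~1,200 edges).  What it does **not** model: nested parameterized
network families, promoter-scanning noise, correlated targeting of
paralogous TFs, or any fit to a real organism's networks — so passing
tests demonstrate algorithmic correctness and calibration under a
realistic degree regime, not biological fidelity.

Motif planting inserts fresh instances (all edges new) of a named class
for recovery experiments.  Planting is only detectable when the planted
edges are not explainable by degrees alone: in a small dense network the
planted degree surplus lets degree-matched nulls reproduce the count,
and the pipeline — correctly — calls nothing.  The packaged recovery
experiment therefore plants 30 instances into a sparse, mild-hub
background (245 nodes, Zipf 2.5, out-degree cap 25), where both the
miRNA-mediated FFL and the sustained-input switch are recovered at
P < 0.002 with 500 backgrounds.  The hub-heavy generator remains the
condition for the self-null calibration (false-positive class fraction
≤ 2 × P cutoff) and the stability analysis.

## Numerical and design choices

* All tie-breaks and iteration orders are lexicographic in node id;
  randomness flows through one `numpy` Generator per replicate, seeded
  from a master seed by counter-based spawning — replicate i is
  identical whether replicates run serially or in parallel.
* Weighted draws within a source recompute weights after each placement;
  for this weight form that is provably identical to one-shot weighted
  sampling without replacement, since a chosen target's capacity change
  affects only itself.
* Empirical P uses r/N (not (r+1)/(N+1)) for comparability with the
  count-based convention of existing motif tools; zeros are displayed as
  bounds.
* Duplicate rows in input edge lists collapse with a warning (target
  prediction pipelines emit duplicates); typed-but-unconnected nodes are
  retained and excluded from randomization by default.
* The stability experiment in the test suite runs on a ~150-node
  synthetic network with 10,000 backgrounds; the self-null uses ten
  ~70-node networks at 150 backgrounds each.  These sizes keep the full
  experiment suite in the tens of minutes on one core while preserving
  the statistical content of the checks.

## Known limitations

* The sampler is near-uniform, not exactly uniform; do not use it where
  exact uniformity over realizations is required (use rejection from the
  enumeration oracle on small instances instead).
* The census is exact only to size 3; larger motifs need sampling
  schemes out of scope here.
* Reverse swaps slightly perturb uniformity in principle; they are rare
  (average well below one per network on hub-heavy synthetics) and
  bounded per layer by the stuck source's unplaced degree.
* Empirical P has resolution 1/N; calls at P < 0.01 need N ≥ 100 and
  sensible backgrounds need far more (the default is 2,500).
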