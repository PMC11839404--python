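# Methods

## The damage model

`adnaplace` implements the Briggs model of post-mortem damage for
double-stranded sequencing libraries. One damage pass over a source
sequence proceeds in four steps:

1. **Nicking.** Every junction between consecutive non-gap residues is an
   independent Bernoulli(ν) trial. Junctions exist only between physical
   nucleotides: gap columns of aligned input carry no junctions.
2. **Fragmentation.** The sequence is cut at the nicked junctions. Each
   cut falls immediately before the next non-gap residue, so gap columns
   adjacent to a nick travel with the preceding fragment and the
   fragments tile the source exactly.
3. **Overhang.** Each fragment receives one single-stranded overhang, on
   the 5′ side with probability 1/2, otherwise the 3′ side. Its length is
   geometric counted as failures before the first success,
   P(L = k) = (1 − λ)^k λ for k ≥ 0, so λ = 1 always gives length zero
   ("no damage" for this parameter is λ = 1, not 0). The length is
   counted in non-gap residues and capped at the fragment's non-gap
   length.
4. **Deamination.** On a 5′-overhang read, each C (case-insensitive)
   flips to T with probability δ_ss inside the overhang and δ_ds
   outside; G is never touched. A 3′-overhang read is the mirror image
   with G→A. This asymmetry reflects library preparation: deamination on
   the 3′ overhang is read back as G→A on the reported strand, and a
   single read therefore never mixes the two substitution kinds. Gaps
   and IUPAC ambiguity codes are never altered; case is preserved.

Every flip is recorded as an event (position within the read, kind,
single- vs double-stranded region), and the damage log (TSV: one summary
row per read plus one row per event) exposes the entire process for
downstream analysis — the main reason to simulate damage transparently
rather than with a black-box read simulator.

### Filters and accumulation

After each pass, in order: reads consisting entirely of gap/ambiguity
characters are removed unconditionally; reads with fewer than
`min_length` non-gap sites are removed (default 15 bp — the permissive
end of the usual aDNA length prefilter, where ~30 bp cutoffs are common);
with a reference alignment given, reads sharing no non-gap column with
any reference row are removed (*premasking* — such reads could not be
aligned, hence never placed). Passes repeat, accumulating survivors,
until `min_reads` (default 10, enough for stable per-source summary
statistics) survive. The loop is bounded by `max_accumulation_passes`
(default 1000) so that unsatisfiable settings terminate: hitting the
bound with zero survivors is an error naming the source sequence;
hitting it with some survivors returns them with a warning. If
`max_reads` is set, the final set is downsampled uniformly without
replacement.

### Randomness and reproducibility

All draws come from one `numpy.random.Generator` per `simulate` call, in
a fixed order: nicks left-to-right (one uniform per junction; skipped
entirely when ν = 0), then per fragment the overhang side, the overhang
length, and one uniform per eligible base left-to-right. Given the same
inputs and seed, FASTA and log outputs are byte-identical.

## Closed forms

* **Median fragment length.** Fragment lengths are geometric with
  success probability ν, so the theoretical median is
  ⌊−ln 2 / ln(1 − ν)⌋ (∞ at ν = 0, 1 at ν = 1). Realized medians on
  finite sequences sit above this once short reads are filtered, and
  below the source length always.
* **Misincorporation profile.** At 0-based position i from the 5′ end,
  P(C→T) = ½[(1 − λ)^{i+1} δ_ss + (1 − (1 − λ)^{i+1}) δ_ds], conditional
  on the base being a C; the ½ is the probability the read's overhang is
  5′. G→A mirrors from the 3′ end. Summing both kinds gives the familiar
  U-shaped curve whenever δ_ss > δ_ds and λ < 1.
* **Crossover overhang length.** The smallest k with
  k·δ_ss > L·δ_ds — the overhang length at which expected
  single-stranded damage overtakes the entire double-stranded remainder
  of an L bp read. At L = 100, δ_ss = 0.65, δ_ds = 0.015 this is 3:
  almost all damage sits at read ends.
* **Standardized regression.** `standardized_linear_fit` regresses eND
  on z-scored ν, λ, δ_ds, δ_ss by OLS (statsmodels), making coefficient
  magnitudes comparable across parameters with different natural scales.
  Constant predictors and rank-deficient designs are rejected with the
  offending predictors named.

## Placement metrics

Branches are identified by jplace edge numbers. The node distance
between two branches is the shortest-path length in the branch-adjacency
graph (branches sharing a tree node are at distance 1); it is computed
on the tree as parsed — the arbitrary rooting of the Newick string is
part of the numbering convention, and trees written by this package
number edges 0..E−1 in post-order when no `{N}` annotations are present.
eND sums LWR(p)·d(p, truth) over all reported placements, with LWRs used
as reported (a strict mode rejects sets summing above 1). The best
placement for ND is the highest-LWR row, ties broken toward the lowest
edge number. Reads with no reported placements are an error rather than
a silent zero.

## The benchmark harness

One scenario prunes a uniformly chosen eligible subtree: eligibility
requires leaving at least `min_remaining_taxa` (default 4) tips, removing
at most 25% of tips (small enough to keep the reference informative),
and not hanging directly off the root (so the attachment node can always
be suppressed). The attachment node's two remaining branches merge
(lengths summed) and the merged branch is the true placement edge; the
pruned tree is renumbered post-order. The pruned taxa's aligned rows
become the queries.

The loop order is Pruning → Damage → Placement → Assessment, with
alignment an identity step: damage is injected into the already-aligned
queries (premasked against the remaining reference alignment), so
placement error is measured free of alignment error.

### The naive placer

To keep the loop self-contained, a deliberately naive placer stands in
for real placement tools (which are integrated only by ingesting their
jplace output per scenario): per query, normalized Hamming distance to
every reference row over columns where both are non-gap; candidates are
the pendant branches of the `top_k` (default 3) closest leaves, ranked
by distance with ties toward the lowest edge number. Candidate weights
are a softmax of negative *mismatch counts* (distance × overlap size) —
the log-likelihood analogue under a uniform error model — rather than of
the normalized distances themselves, whose [0, 1] range would make the
weights nearly uniform regardless of how much sequence supported the
best candidate. A long clean query thus yields a near-one-hot weight
vector, while a short noisy read spreads its weight; eND then responds
to read length the way a likelihood-based tool's does. This placer is a
benchmark stand-in, not a scientific method: it can only ever propose
pendant branches, so placements on internal true branches are off by at
least one node even in the best case.

That pendant-only limitation shapes the clean-recovery check: the
zero-damage "median ND = 0" test runs with single-leaf prunings
(`max_removed_frac = 1/n_taxa`), the only regime in which exact recovery
is even defined for a pendant-only placer, and uses 40 prunings so the
pooled median is insensitive to which leaves happen to be drawn. The
direction-of-effect check (heavier nicking ⇒ larger median normalized
eND) uses the default mixed prunings.

## Synthetic fixtures

Test data are generated, never downloaded: i.i.d. random sequences with
a set GC fraction (G/C each gc/2, A/T each (1−gc)/2 — GC content matters
because only C and G are damage-eligible); random topologies grown by
sequentially splitting a uniformly chosen leaf (a birth process, the
standard null model for species trees), with exponential branch lengths
(mean 0.1) and a trifurcating root (2n − 3 branches); and gap-free
alignments evolved down the tree under the one-parameter equal-rates
(Jukes–Cantor) model. The default fixture is 32 taxa × 1500 sites at
GC 0.4 with substitution scale 1.0 — large enough that nearest-neighbor
signal is unambiguous for full-length queries, small enough that the
full benchmark loop runs in seconds.

What the fixtures do *not* emulate: indels (so damaged reads stay
trivially aligned, matching the damage-after-alignment design — alignment
error is deliberately out of scope), rate heterogeneity and realistic
substitution models, sequencing error and quality strings, contamination,
and single-stranded library chemistry (C→T at both ends). Passing tests
therefore demonstrate correctness of the damage model and metrics and
the *direction* of damage effects on a clean placement problem; they do
not predict absolute accuracy on empirical alignments, where gaps,
model misfit, and alignment error all add to placement difficulty.

## Numerical and convention notes

* Coordinates are 0-based half-open; overhang sides are `five_prime` /
  `three_prime`; event kinds `C_to_T` / `G_to_A`.
* Lowercase residues are accepted everywhere; damage eligibility is
  case-insensitive and flips preserve case.
* jplace: version ≥ 3 layout, both `n` and `nm` name lists accepted,
  `nm` multiplicities ignored (only edge numbers and LWRs are consumed).
* The geometric convention for overhangs (failures before first success,
  support including 0) is what makes λ = 1 the no-damage setting.
* Read ids are `<source_id>/<pass>/<ordinal>` so accumulation passes
  remain distinguishable in the log.
* Monte-Carlo checks in the test suite use 10^5 draws (3-standard-error
  bands; χ² goodness-of-fit at α = 0.001), a 1 Mb source for the median
  fragment-length check, and 10^5 reads × length 60 for the profile
  oracle; the uniform-downsampling and uniform-pruning χ² checks use
  10^4 and 2×10^3 repetitions respectively, where binomial standard
  errors are already far below the effects tested.
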