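# Methods

## The problem and the model

A genetic linkage map orders the markers of a chromosome and spaces them
by recombination fraction.  When several mapping populations (datasets)
of the same species are genotyped on partially overlapping marker panels,
a *consensus* map must order the union of markers such that no pair of
*shared* markers (markers genotyped, by name, in two or more populations)
appears in opposite relative order in any two populations.

consmap implements a two-phase analysis:

**Phase 1** orders each dataset independently.  Multilocus ordering with
the minimum-total-map-length criterion is an open-path traveling-salesperson
problem (TSP) on the matrix of pairwise recombination fractions: find the
permutation minimising the sum of adjacent-pair fractions.  Order stability
is assessed by jackknife resampling of individuals, and skeleton maps are
produced by removing markers that (i) are absolutely linked to another
marker, (ii) violate monotone growth of recombination with successive
neighbours, or (iii) are jackknife-unstable.

**Phase 2** selects the consensus order g of the shared-marker set R by
minimising the weighted sum of map lengths over all datasets,

    S(g) = Σ_i  w_i · min_{u ∈ U(i, g(i))} S_i(g(i), u),

where g(i) is g restricted to dataset i's markers, U(i, g(i)) is the set of
full orders of dataset i embedding g(i) as a subsequence (its *unique*
markers are free), and S_i is the sum of adjacent recombination fractions.
This is a *synchronized TSP*: each dataset solves its own path problem
under the constraint of one common anchor order.  The cheap *skeleton*
criterion S_shared(g) = Σ_i w_i · S_i(g(i)) evaluates g on the shared
markers only and screens candidates.

Two phase-2 strategies are combined:

* **Local (exact) analysis.** Conflicts between phase-1 maps are detected
  pairwise (after orientation alignment) and merged transitively into
  *conflict regions* — windows containing the conflicting shared markers,
  any shared markers between them, and the interleaved unique markers,
  bounded by frozen non-conflicting flanks (a side touching the linkage-group
  end stays free).  Each region with k shared and n_i unique markers is
  solved exactly by tabulation: stage 1 precomputes, per dataset, the
  optimal path a → T → b for every anchor pair (a, b) and every subset T of
  unique markers (2^{n_i}·((k+2)(k+1)/2 − 1) entries, by dynamic programming
  over (subset, last-marker) states); stage 2 enumerates the k! shared
  suborders, and for each one every dataset distributes its unique markers
  among the k+1 intervals by a subset-partition dynamic program over
  stage-1 entries — provably equal to the (k+1)^{n_i} assignment
  enumeration, which the tests retain as the oracle.  The scheme is exact
  within the feasibility bound k + n_i < 15 with k, n_i < 11; the pipeline
  applies tighter operational caps (k ≤ 6, n_i ≤ 7 by default) so a region
  solves in well under a second, and falls back to the GES heuristic above
  them.
* **Global (GES) analysis.** A guided evolution strategy mutates the
  incumbent shared order (segment reversal, segment translocation, point
  exchange; segment lengths follow a 2 + geometric law; mutation sites are
  biased toward positions with long adjacent intervals).  Mutants are
  screened by S_shared against a learned threshold q; survivors are fully
  evaluated by placing each dataset's unique markers around the anchors
  (cheapest insertion refined by Reinsert, Reverse-Reinsert and
  Exchange-1×1 moves that never disturb the anchor order).  The search is
  elitist, so the incumbent criterion is non-increasing, and every
  candidate solution is conflict-free by construction.  The global search
  starts from the better of the merged local solution g* and a quick
  skeleton-only optimum g**.

Before conflict analysis, maps containing an interval with recombination
fraction ≥ 0.3 are screened for whole-segment inversion/transposition
artifacts (a hallmark of large-gap maps): reversing or relocating the
distal segment is accepted when it strictly reduces the total conflict
count while inflating that map's own length by at most 0.02 (criterion
units).

## Criterion units and orientation

The criterion is the plain sum of recombination fractions (Morgans without
a mapping function); reported lengths are 100 × that sum, in cM.  No
Haldane/Kosambi transform is applied to the criterion because the summed
two-point fractions are what the optimisation compares.  A map and its
full reversal are one solution; all comparisons first align orientation by
maximising the count of concordant shared pairs (ties keep the reference
orientation, dataset 0 by convention).

## Recombination-fraction estimation

Two-point estimates per cross type: direct recombinant counting for BC;
single-parameter maximum likelihood on the 3×3 joint genotype table for
codominant F2 (the double-heterozygote class mixes phases, probability
((1−r)² + r²)/2; the likelihood is maximised by a vectorised grid scan
with parabolic refinement, accuracy ≈ 5·10⁻⁴); and the fixed-line
discordance inversion r = R/(2(1−R)) for RIL.  Estimates are clamped to
[0, 0.5].  Pairs with fewer than 10 informative individuals are imputed by
the minimum two-hop sum over reliable entries (the criterion needs a
complete matrix) and flagged.  Two-point estimation is a deliberate,
self-contained stand-in for multipoint likelihood distances; its
consequences are discussed under Limitations.

## Solvers

* Exact single-dataset ordering: Held–Karp dynamic programming over
  (subset, last) states, used up to 16 markers (12 by default under
  `solver="auto"`).
* Heuristic ordering: multi-start greedy nearest-neighbour construction,
  2-opt and Or-opt (segment length ≤ 3, optionally reversed) descent,
  wrapped in an elitist evolution strategy with segment perturbations
  (stall limit 40, ≤ 400 perturbations).  On random 9-marker instances it
  matches Held–Karp in ≥ 95% of runs and never produces a shorter length
  than the optimum (it cannot, being a feasible order).
* Threshold learning: q sits a multiplicative margin (default 0.02) above
  the largest S_shared among the five best recorded solutions.  The margin
  doubles after every stall_limit/8 consecutive non-improving mutants
  (capped at 4.0) and snaps back to its base value on every accepted
  improvement.  The relaxation matters: S_shared and S correlate well on
  map-like data but not perfectly, and a fixed tight margin can screen the
  true optimum out permanently; the stall-coupled margin keeps the
  20–100× screening saving while restoring completeness on instances
  where the skeleton signal is weak.

## Weights

Dataset weights default to 1.  The `inverse_length` mode sets
w_i = 1/L_i with L_i the phase-1 map length in cM, down-weighting datasets
whose maps are inflated by scoring errors and missing data; map length is
a monotone proxy for noise because errors inflate every adjacent fraction.
For mixed clean/noisy designs this second-round weighting is the
recommended configuration: with equal weights, several noise-inflated
datasets can outvote one clean dataset on the orientation of a tightly
linked pair, while 1/L_i restores the clean data's influence.  The
acceptance checks on the mixed 4-clean + 4-noisy design use it.

## The simulator

`consmap.simulate` draws a true map (inter-marker intervals 75% from
U[1, 4] cM and 25% from U[4, 20] cM by default), simulates meiosis with no
crossover interference (Haldane: r = (1 − e^(−2d/100))/2 per interval;
gametes are generated marker-by-marker), and derives F2 (two independent
gametes), BC (one gamete against a tester) or RIL genotypes (drawn
directly from the fixed-line distribution with r_RIL = 2r/(1+2r) rather
than by iterating selfing — marginally equivalent and far cheaper).
Noise: per-cell missingness at a configurable rate, and stratified
misclassification — within a stratum of loci × individuals, a heterozygote
is scored as either homozygote with probability 0.05 each and each
homozygote as heterozygous with probability 0.10 (i.e. a 10% error rate at
affected loci).  Shared/unique structure is controlled by a shared
fraction or an explicit presence mask; shared markers keep the plain name
`mar{k}`, unique markers are suffixed `mar{k}_{i}` with the dataset
number.  Ground truth (true order, shared order, per-dataset projections)
is returned for recovery scoring.

What the simulator does *not* emulate: crossover interference (a hook for
a chi-square interference parameter is deliberately left unimplemented),
segregation distortion, dominant or mixed-dominance markers, non-uniform
missingness mechanisms, and between-population variation in recombination
rate along the chromosome.  Passing tests therefore demonstrate behaviour
under clean no-interference meiosis with independent noise — not
robustness to every artifact of real data.

## Scoring

The *recovery coefficient* is the fraction of shared markers whose
immediate neighbourhoods (both neighbours; one at the ends) in the
consensus shared order match the true order after orientation alignment.
`order_violations` counts the complementary markers.  The *cost of
consensus* of dataset i is Δ_i = L_cons,i − L_ind,i (cM); with exact
solvers Δ_i ≥ 0 because the consensus constrains the dataset's own
optimum.  Δ_i is attributed per marker as half the change of its incident
edge lengths (flank edges attributed fully to the inner marker), so the
attributions sum exactly to Δ_i.  Datasets with Δ above a threshold
(default 10 cM; 3–10 cM is moderate, above ~40 cM unaffordable) trigger
ranked marker-removal proposals: the top-attribution markers are
provisionally removed one at a time (the top pair jointly when no single
removal suffices) and the consensus re-run; proposals are never
auto-applied.

The *integral map* is a directed acyclic graph: the consensus shared
order forms the backbone; each dataset's unique markers appear as chains
between their flanking anchors with per-dataset distances (attributes
`d{i}`, cM).  When two or more datasets place unique markers between the
same anchor pair, their chains remain parallel branches sharing a loop
id — relative order across datasets is genuinely unidentifiable there, so
the map never interleaves them, and distances are never averaged across
datasets.

## Numerical and design choices

* Ties: equal-length single-dataset orders resolve deterministically
  (orientation normalised so the first marker name sorts before the last;
  DP backtracking prefers lexicographically smaller names).  Equal-total
  region suborders prefer the candidate closest (fewest discordant pairs)
  to the phase-1 maps, then lexicographic.
* Jackknife protocol: drop 20% of individuals, 100 replicates by default
  (pipeline default is 0 — stability analysis is opt-in because each
  replicate re-estimates and re-orders), neighbour-match scoring, removal
  threshold 0.7.
* Monotonicity rule (ii) scans up to 4 subsequent neighbours in both
  directions with a 2·SE tolerance.
* Higher-order (cyclic) conflicts are detected as strongly connected
  components of the union precedence graph — every directed cycle lies in
  one, the whole component must be re-ordered together anyway, and
  component detection is linear whereas simple-cycle enumeration is
  exponential on noisy data.  Their markers are absorbed into conflict
  regions and resolved by the same machinery.
* Dataset exclusion: a dataset with fewer than two shared markers cannot
  constrain or be constrained; it keeps its phase-1 map and is excluded
  from conflict analysis with a warning.
* Problem sizes in the test-suite and acceptance runs (e.g. 8 populations
  × 50 markers × N = 100; 10 marker instances for exact-oracle checks)
  were chosen as the smallest designs that exhibit each behaviour clearly.

## Known limitations

* **Two-point distances bound phase-1 local accuracy.**  With two-point
  estimates at N = 100, adjacent ~1 cM intervals carry only ~2 observed
  recombinants, and the minimum-length criterion's own optimum then
  deviates from the true order at some tightly linked pair in roughly a
  quarter of clean 50-marker populations — no optimizer can do better
  while minimising that criterion on those inputs.  Multipoint likelihood
  distances, which penalise the double crossovers a local swap implies,
  would pin such pairs but are out of scope.  Consensus analysis pools
  populations and in practice recovers the true shared order even when
  individual phase-1 maps carry such local swaps.
* Dominant markers, sex-specific recombination, multi-chromosome linkage
  grouping and QTL analysis are out of scope; input is assumed to be one
  chromosome with codominant scoring.
* The exact region solver's operational caps are conservative for pure
  Python; regions above them are handled heuristically (with the exact
  guarantee lost but the conflict-free guarantee intact).
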