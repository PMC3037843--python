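# Methods

This note documents the models, algorithms and design choices behind
`groupfix`: what is computed, under which assumptions, and where the
design was genuinely open.

## Problem statement

A mate-selection analysis chooses, for one mating round, which
candidates are used, how often, and who is mated to whom. Inputs are a
candidate table (id, sex, group, merit index, use limits, MOET flag), a
pedigree, a binary male-group × female-group permission matrix, and
per-female-group selection proportions. The output is a mating list
whose per-candidate counts respect the use limits and whose pairs all
fall in permitted group combinations.

The search is posed as an evolutionary optimisation: a flat real vector
is decoded into a mating list, the list is scored, and differential
evolution improves the vectors. Constraints are handled by *fixing*
(repair during decoding), not penalising, so every evaluated solution
is legal; a penalising baseline is retained solely for comparison
studies.

## Pedigree computations

Kinship f(a,b) is the probability that alleles sampled from a and b are
identical by descent; it equals the inbreeding coefficient of a
prospective offspring of a×b, and f(a,a) = (1 + F_a)/2. Two routes are
implemented:

* the **tabular method**: the additive relationship matrix A is built
  row by row in topological order over the ancestor closure of the
  requested animals; kinship is A/2. O(n²) in the closure size, exact,
  and comfortably fast for the few thousand animals of a practical
  candidate set.
* a **Meuwissen–Luo-style recursion** for inbreeding alone: per
  non-founder, ancestors of the parent pair are traced youngest-first
  with path coefficients L, giving F = Σ L²D − ½ − ¼(F_s + F_d) with
  Mendelian-sampling terms D. No matrix is materialised.

The two routes are cross-checked against each other and against a
third, test-only implementation (explicit Wright path counting and a
memoised recursion on the definitions) to 1e-12.

Unknown parents — including parents named in a record but never listed
themselves — are treated as founders: unrelated, non-inbred. Two
animals naming the same unlisted parent do share it. Pedigree CSVs use
the common `id,sire,dam` dialect with `0` or empty for unknown.
Genomic (marker-based) relationships are out of scope.

## Use-count repair

Per candidate, Nm is constrained to {0} ∪ [Minuse, Maxuse], with
AbsMinuse > 0 removing the zero state. Raw integer counts are first
snapped: a value strictly inside (0, Minuse) moves to the nearer bound
with linearly graded probability (value v moves up with probability
v/Minuse); values beyond Maxuse/AbsMinuse are clamped. A random ±1
adjustment loop then drives the group total to its target, reversing
any step that violates a limit. Two numerical choices matter:

* **Zero-use damping** (default 0.1): proposals that re-activate a male
  at Nm = 0 are accepted with reduced probability, since good solutions
  leave many males unused. The value is configurable; the behaviour,
  not the constant, is what the design fixes.
* **Plateau moves**: crossing a Minuse gap changes the total by more
  than one, so the loop also accepts moves that leave the distance to
  the target unchanged (probability ½) and, after a stall, occasionally
  ones that worsen it (probability ¼). Without these, targets reachable
  only through a gap jump would deadlock. Targets that are genuinely
  unreachable (e.g. a total of 1 from members that all carry Minuse 4)
  raise a feasibility error after a bounded number of iterations.

## The weight transform and group targets

Per female group, relative weights W over male groups are derived from
optimised raw weights R (truncated to [0, 1]):

* a single permitted male group takes W = 1 with no variable;
* last male group not permitted: W = R/ΣR (uniform fallback with a
  logged warning when all R are zero — the formula's 0/0 corner; the
  symmetric limit is uniform);
* last male group permitted: with k = #{R > 0} + 1 and
  D = 1 + (k−2)ΣR/(k−1) (D ≡ 1 when ΣR = 0), W_i = R_i/D for the
  others and W_last = 1 − ΣR/D.

This gives columns that sum to one, W_last = 1 when all R = 0, W_last
= 0 when some R = 1 and the rest 0, and W_last equal to the column
average when the positive R average ½ — an efficient coverage of the
weight simplex from a minimal number of variables. "Last" is purely
positional (the bottom row of the permission CSV); users choose which
group sits there by row order.

Integer targets use floor(W·Nt) plus one-at-a-time distribution of the
remainder with probability proportional to W, so cells with W = 0 never
receive a mating and column sums are exact. Male-group capacity is then
repaired by moving single matings between permitted rows within a
column: moves that reduce the total violation are kept, violation-
neutral moves are kept with probability ½ (letting stock drift through
full intermediate rows), and the loop aborts after 200 × N_MG × N_FG
proposals, which indicates capacities structurally incompatible with
the permission matrix. Row totals also avoid the gap (0, min member
Minuse), for the same reason individual counts do.

## Allocation and MOET

Male matings are walked in ranking order (largest value = rank 1, ties
by candidate order then slot); each takes the first unallocated,
permission-legal female mating whose group cell still has quota. With
consistent counts this walk provably completes with every cell exactly
on target. Female matings are listed in candidate-file order, fixed for
the analysis; each male owns min(Maxuse, Nt) ranking slots, of which
the first Nm are active — this bounds the genotype length even for AI
sires with Maxuse in the thousands.

MOET females (in-vivo fertilisation after superovulation) must keep one
sire across all their matings. This is repaired after the quota walk:
later matings are reassigned to the first-assigned sire, and counts are
rebalanced by swapping with one of that sire's non-MOET pairs in the
same female group (which leaves per-animal and per-cell counts
untouched). When no swap partner exists the decode is retried with
fresh repair randomness, up to 30 times; the retry bound has never been
hit in testing on realistically sized groups, but pathological setups
(a MOET female alongside almost no ordinary females) can exhaust it
and raise an explicit error.

## Objective

Components of a mating list: mean midparent index G; use-weighted
parental coancestry C = p′Kp with p_i = Nm_i/(2Nt); mean progeny
inbreeding F̄ = mean kinship of the mated pairs; and the illegal-pair
count (always 0 under repair decoding). The scalar fitness is

    cos(θ)·G′ − sin(θ)·C′ + w_F·F̄ − penalty_weight · illegal_pairs

where θ is the target angle on the G/C frontier and G′, C′ rescale G
and C linearly to [0, 1] between the frontier endpoints. The endpoints
("anchors") come from two short single-criterion runs (maximise G;
minimise C) under the full repair decode, 20 000 evaluations each by
default — anchors only normalise, so approximate endpoints suffice, and
both runs share one seed-derived stream for reproducibility. This
projected, anchor-normalised form is this package's own construction:
it realises the documented endpoint behaviour exactly (θ = 0 ranks by
G alone, θ = 90 by −C), supports an inbreeding weighting of −1 or 0,
and charges penalty-mode solutions exactly weight × illegal matings.
It is isolated behind `scalar_fitness` so a different scalarisation
(e.g. dynamic re-targeting during a run) can be swapped in.

A separate recovery objective scores a list by the number of sire×dam
pairs it shares with a fixed target list. It is used to probe coverage
of the legal space: a legal list produced independently of the search
is set as the optimum, and the optimiser must reach it exactly. This is
a sampled check, not a proof of full coverage.

## Optimiser

Classic DE/rand/1/bin: population 50, F = 0.8, CR = 0.9 by default,
greedy replacement (ties keep the trial, which preserves drift on
plateaus), all integer genotype segments kept real and rounded inside
the decoder. Initial raw counts are uniform integers in [0, Maxuse],
rankings and raw weights uniform in [0, 1]; generation one's best is
therefore the best of the random initial population. Because the
repair steps are stochastic, re-decoding a genotype can give a slightly
different list; each individual keeps the fitness of the list actually
decoded for it. All randomness derives from a single seed via separate
spawned streams for DE arithmetic and decoding, making trajectories
bit-reproducible. Self-adaptive DE variants and parallel evaluation
are deliberately out of scope.

Strategy comparisons run the repair decoder and one permission-blind
(penalty) run per weight at identical seeds and budgets, sharing the
same anchors so fitness values are directly comparable. Trajectory
generations whose incumbent best is illegal are flagged and censored in
summaries; a penalty run that never surfaces a legal best reports −∞ as
its final legal fitness.

## Synthetic populations

The generator emulates a multi-farm program with overlapping
generations: per cycle and farm, a standing team of sires (default 25)
is mated to a standing herd of dams (default 100), replacements are
chosen by within-farm truncation on an index proxy, and animals leave
through age culling (after 5 male / 8 female mating cycles, first
parity at age 3), random adult survival (0.95/year) and a calving rate
of 0.8. Defaults follow the three-farm, ten-cycle study conditions.
The index proxy is the true breeding value under the infinitesimal
model (midparent mean plus Mendelian sampling of variance ½) plus
observation noise scaled by an accuracy of 0.7 — a stand-in for BLUP
EBV that preserves selection differentials without a genetic
evaluation. Surplus calves leave at birth (male retention 0.5, female
0.8, as surplus bull calves and defect heifers would be sold); these
retentions are the one place the generator goes beyond the stated
study conditions, chosen once as realistic husbandry.

Emitted candidates comprise per-farm adults, a Juvenile group (below
first-parity age), an Embryo group (the expected pregnancies of the
final simulated round, carried as unborn records for virtual matings)
and a handful of retired top sires flagged as AI with Maxuse 1000. The
permission matrix isolates farms, restricts embryos to virtual
combinations and routes AI sires to every farm — so decoded analyses
exercise exactly the grouping structure of a cross-farm program. What
the generator does *not* reproduce: a real genetic evaluation,
non-random mating within farms, seasonal effects, and real-world
pedigree errors; passing tests on simulated data therefore demonstrate
algorithmic correctness and constraint handling, not predictive
accuracy on any particular livestock population.

The deterministic `small_fixture` (6 males, 12 females, three groups a
side, 9 matings, permission pattern with all three action types) backs
the recovery and comparison experiments at desk scale; its legal space
of group-target matrices is enumerable by hand, and its use limits
leave generous feasibility headroom.

## Problem sizes used in the shipped experiments

The recovery experiment uses the small fixture (genotype dimension 43)
with population 24 and a 50 000-generation cap, stopping early on
success; across seeds it typically recovers the hidden list within a
few hundred generations. The strategy comparison uses population 30
for 250 generations per strategy, repeated over three seeds — enough
for the repair runs to converge on the fixture while keeping the whole
comparison under a minute per seed. Decode-legality checks run 1 000
random genotypes on a six-male-group × five-female-group cross-farm
instance. These sizes were chosen so the full behavioural suite
documents the method's properties in minutes on a single core; all of
them scale up linearly in evaluations via the same configuration
objects.

## Known limitations

* The capacity-repair and use-count loops are randomised repairs with
  bounded budgets: structurally infeasible inputs are reported, but so
  (rarely) would be feasible inputs whose only repairs require long
  coordinated move chains; re-running with another seed resolves the
  latter.
* Per-pair (animal-level) exclusions, soft permissions, and transport
  or connection terms in the objective are not implemented.
* Female selection proportions are user inputs, not optimised, though
  the machinery to optimise them would only add genotype dimensions.
* The frontier steering is static per run; exploring a changing target
  angle requires separate runs (the `frontier` subcommand).
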