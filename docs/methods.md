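# Methods

This document describes the models, parameters and numerical choices
implemented in `termswitch`, and the boundaries of what they can claim.
Every empirical statement here is either a definition or something the
test suite (`tests/`) computes.

## 1. Terminator structure and quality filters

A terminator is modeled as a single hairpin: a stem of 5–19 base pairs
(`MIN_STEM_PAIRS`/`MAX_STEM_PAIRS`), a loop, and optionally a poly-U
tract. Structures are given in dot-bracket notation; multi-hairpin inputs
are rejected.

**Stem energy** is scored as the sum over adjacent stacked pairs of a
stack table derived from per-pair strengths (GC 1.65, AU 0.55, GU 0.25;
one stack scores minus the sum of its two pair strengths, in kcal/mol
units). A bulge between two pairs breaks the stack. This is a
coarse-grained score for *filtering*, not a thermodynamic prediction:
it preserves the ordering GC > AU > GU and penalizes interrupted helices,
which is all the downstream filters require.

**Filters** (`FilterThresholds`, defaults): stem energy ≤ −5 kcal/mol,
≥ 5 complementary (Watson-Crick or GU) pairs covering ≥ 70% of the
interacting pairs, ≤ 30% unpaired positions per arm, and ≥ 70% pairwise
sequence identity of every strain to the reference (gap–gap columns
excluded; a gap against a base and ambiguity codes count as mismatches).
A column pair is retained only when its *modal* dinucleotide across
strains is complementary; ties are kept when any tied mode is
complementary.

## 2. Ancestral reconstruction

Nucleotide columns evolve under the F81 model. With base frequencies
π (estimated per gene from the stem columns with a pseudocount of 1 per
base), the transition probability over branch length t (expected
substitutions per site) is

    P(i→j | t) = exp(−βt)·δij + (1 − exp(−βt))·πj,
    β = 1 / (1 − Σ πk²),

so that branch lengths are calibrated in substitutions/site. Likelihoods
use Felsenstein pruning; marginal posteriors add the standard outside
pass, giving the posterior distribution at every node in one sweep.
Missing strains enter as fully marginalized leaves. A node is **resolved**
to the state whose posterior is ≥ 0.8 (ties broken toward the larger
posterior; the comparison is `>=` so a threshold equal to the maximum
still resolves); otherwise it is UNRESOLVED. The 0.8 default trades
coverage against the cost of propagating wrong ancestral states into the
switch census — switch typing treats UNRESOLVED as an interruption rather
than guessing.

Correctness is pinned by an oracle: on random trees with ≤ 5 leaves,
likelihoods and all marginal posteriors match exhaustive enumeration over
every internal-state assignment to 1e−10 (1,000 instances,
`tests/test_acceptance.py`).

## 3. Blocks, switches and types

For one interacting column pair, every node carries a joint dinucleotide
state (or UNRESOLVED). **Blocks** are maximal connected components of
equal joint state; UNRESOLVED nodes sever connectivity. A **switch** is an
unordered pair of blocks with distinct Watson-Crick states whose
connecting path changes each column exactly once, with all path states
drawn from the two endpoint values per column. Because no two
Watson-Crick dinucleotides differ at exactly one position, both columns
must change, so artificial pairs combining a variable and an invariant
column can never produce a switch — the property the permutation null
relies on.

Types (LCA = last common ancestor of the two blocks, on the path):

| type | LCA resolution        | intermediate observed |
|------|-----------------------|-----------------------|
| 1    | resolved, terminal    | no                    |
| 2    | resolved, intermediate| at the LCA            |
| 3    | resolved, terminal    | elsewhere on the path |
| 4    | unresolved            | no                    |
| 5    | unresolved            | yes                   |

Intermediates are reported in the strand-symmetrized orientation of the
switch kind (AU⇄GC, AU⇄CG, AU⇄UA, GC⇄CG). For types 2 and 3, the two
substitutions can each be assigned to a branch; the **compensation
distance** is the path length between the two branch midpoints. By stated
convention, two events on one branch score half that branch's length,
although with fully resolved intermediates the two events of a type-2/3
switch necessarily sit on different branches; the convention is kept for
rule completeness. Distances are undefined for types 1, 4 and 5.

Switch enumeration is validated against an independent implementation
(networkx connected components plus explicit path scans) on simulated
histories where true node states are known, over 500 seeded replicates.

## 4. Statistics

- **TIR** = (n₁ + n₃) / n₂: switches whose LCA carries a terminal state
  over those whose LCA carries the intermediate. +∞ when n₂ = 0.
- **Intermediate-observation ratio** = (n₁ + n₄) / (n₂ + n₃ + n₅).
- Exact tests use scipy: two-sided binomial (minimum-likelihood
  convention), Fisher's exact test, Mann-Whitney U (exact when both
  groups have ≤ 8 untied observations). All three are verified against
  brute-force enumeration for binomial n ≤ 12 and tables/samples of total
  ≤ 20.

### Permutation null

Artificial column pairs are drawn from a pool containing **both columns
of every "active" pair** — every interacting pair with at least one
variable column — so the pool's composition matches the data the observed
census is computed from. Each of `n_permutations` draws picks two
distinct pool columns (possibly from different genes), forms their joint
states and runs the full block/switch/typing machinery, yielding a
per-permutation 5-vector of type counts.

A single artificial pair almost never defines a ratio, so ratio nulls are
built at dataset scale: `n_samples` (default 1,000) bootstrap batches of
`batch_size` rows (default: the number of active pairs, so one batch
mimics one dataset) are drawn with replacement from the permutation rows;
each batch's summed counts give one TIR and one ratio sample. Batches
where a statistic is undefined are dropped and counted. Interval bounds
use **order statistics** (`numpy.percentile` with `method="lower"` /
`"higher"`), not interpolation, because samples can legitimately be +∞
(a batch with no type-2 switch) and interpolating between a finite and an
infinite sample is undefined. An observed value is flagged when it falls
outside the 2.5–97.5% order-statistic interval.

This null is conservative by construction: artificial pairs inherit the
marginal column processes but destroy within-pair coordination, which is
exactly the signal being tested.

## 5. Simulator

The simulator exists to provide ground truth, not biological realism.

- **Tree**: a pure-birth (Yule) process, rescaled to an exact ultrametric
  tree with a requested mean root-to-tip depth in substitutions/site. The
  sampler runs one extra exponential interval after the last split so no
  pendant branch has zero length.
- **Stem pairs**: a 16-state dinucleotide continuous-time Markov chain.
  Only single-nucleotide changes have nonzero rate; the rate of a change
  is `mutation_rate × π(target base) × acceptance(resulting pair)` with
  acceptance 1 for Watson-Crick pairs, `g` (default 0.3) for GU/UG wobble
  and `m` (default 0.01) for mismatches, mirroring the selective ranking
  WC > GU > mismatch. The chain satisfies detailed balance with
  stationary density ∝ acceptance(s)·π_left·π_right, and at g = m = 1 it
  factorizes exactly into two independent F81 columns (both properties
  are unit-tested). Evolution uses an exact jump chain, so every
  intermediate visit and its position on the branch is recorded in the
  event log.
- **Neutral regions**: loop, poly-U and flanks evolve as independent F81
  columns; the poly-U root is a U run. **No indels are simulated**, no
  rate heterogeneity across genes beyond stem length, and no
  recombination or gene-tree/species-tree discordance.
- **Defaults**: 25 strains; ancestral pair composition 43.6% AU,
  52.4% GC, 4% GU (strand-symmetrized); root-to-tip depth 0.2, calibrated
  so that roughly 9% of stem columns are variable under the default
  selection model (the regime of a closely related strain panel; the
  realized fraction is asserted within ±3 percentage points of 8.2% in
  `tests/test_simulate.py`).
- **Gene layout**: consecutive genes are assigned cooriented, divergent
  or convergent orientations, including convergent pairs sharing one
  physical terminator read on opposite strands (the mirrored copy's
  events are logged once, under the first gene).

## 6. Selection-signal recovery and its null arm

The acceptance suite demonstrates that the whole pipeline recovers a
pairing-selection signal: with g = 0.3, m = 0.01 (25 taxa, 300 genes,
10,000 permutations) the observed TIR exceeds the null's 97.5th
percentile in ≥ 90 of 100 replicates, while a neutral regime flags ≤ 10
of 100.

The neutral arm uses g = m = 1 **and a uniform root composition over all
16 dinucleotide states**. With no pairing selection in the rates, a root
composition concentrated on Watson-Crick pairs would still correlate the
two columns of every real pair at the root — a correlation artificial
pairs cannot reproduce, so the permutation null would flag datasets with
no selection during their evolution. This is a genuine limitation of the
permutation design, not of the simulator: the null calibrates the
*evolutionary* coupling of columns and silently conditions on uncorrelated
root states. Analyses of panels whose ancestral pairing derives entirely
from deep history (rather than ongoing selection) would overstate
significance.

## 7. Other limitations

- One hairpin per terminator; alternative or overlapping structures are
  out of scope.
- The strain tree is taken as given; gene-tree discordance is not
  modeled, and reconstruction errors propagate to the switch census only
  insofar as the 0.8 posterior threshold suppresses them.
- The stack-energy table is a filtering heuristic, not a free-energy
  model.
- Compensation distances assume at most one substitution per column per
  branch when assigning events to branches; multiple hits within a branch
  are invisible to node-state reconstruction.
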