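# Methods

## Model and semantics

A CRN is a pair (Λ, 𝓡) of an ordered species list and a reaction list. Every
reaction is bimolecular — reactant and product stoichiometry vectors each sum
to two — so the total molecule count is invariant, every reachable state
space from a finite initial state is finite, and (at unit rates) the model
coincides with population protocols. Reactions must change the state
(**r** ≠ **p**) and be pairwise distinct.

States are integer count vectors. A reaction with reactants {S, S′} fires
with propensity k·x_S·x_S′, a homodimer {S, S} with k·x_S(x_S−1)/2. A state
where no reaction is enabled is *terminal*; terminal states are absorbing in
the induced continuous-time Markov chain (CTMC). The generator Q has
off-diagonal entries equal to summed propensities of all reactions mapping
state i to state j, diagonal entries the negative row sums, and zero rows at
terminal states. The transient law π_t solves the chemical master equation
dπ/dt = πQ.

## Specifications

A path predicate ψ = (ϕ⁰, ϕ^F) pairs an initial-state predicate with a
final-state predicate; a finite computation satisfies ψ iff it starts in a
ϕ⁰-state and ends in a *terminal* ϕ^F-state. A specification instantiates a
problem on a finite input set I with a deadline t_F (default 1000 time
units; rate bounds are chosen so that tuned circuits can equilibrate by
then). All built-in ϕ⁰ pin the exact initial state: the input counts plus
zero for every other species.

Default study conditions (the input sets double as the conditions under
which scores and counts are quoted):

* **Majority** — I = all (a, b) ∈ [1..4]² except (1, 1); 15 configurations.
  ϕ^F requires the winner species to hold all a+b molecules and everything
  else zero. Ties (a, a) accept either consensus (a disjunctive ϕ^F). The
  input (1, 1) is rejected outright: a single opposed pair cannot reach
  either consensus in the three-species networks of interest, and its
  inclusion empties the search space of them. Excluding ties entirely is
  *not* equivalent: without tie configurations the optimizer drives the
  three-reaction approximate-majority network into a fast-pairing/slow-
  recruitment regime that scores ≈ 1.0, whereas tie inputs punish that
  strategy (it deadlocks ties in the all-undecided state) and keep its
  tuned score near 0.93.
* **Maximum** — I = [1..6]² (36 configurations, ties included). ϕ^F
  requires the output X to hold max(a, b) copies *and both inputs to be
  consumed* (A = B = 0); the waste species stays free, although
  conservation then forces it to min(a, b). Pinning every non-output
  species to zero instead is unsatisfiable for any bimolecular network —
  conservation keeps the total at a+b while the output alone would hold
  max(a, b) — so that variant is not offered. Relaxing to "output count
  only" is available as a flag (`consume_inputs=False`) but admits a much
  larger, less interesting solution set (995 raw networks instead of 128
  for N=4, M=3).
* **Euclidean division** — ϕ^F requires X = ⌊a/b⌋ at a terminal state;
  I defaults to a ∈ {b, b+1, 2b, 2b+1, 3b} for each divisor b ∈ {2..5}
  (five dividends per divisor, quotients 1–3 with varied remainders), a
  compromise between response diversity and CME cost.
* **Division by two** — single input species; ϕ^F requires X = ⌊a/2⌋.

## Synthesis by exhaustive bounded model checking

For budgets (N, M, K_s) the enumerator visits every M-element subset of the
candidate reaction space over N role-labelled species (30 candidate
reactions for N = 3, 90 for N = 4). Structural constraints prune first:
every input species consumed by at least one reaction, every output species
produced by at least one, reactions distinct, **r** ≠ **p**. Each surviving
candidate must admit, for every ψ, a path of at most K_s *stutter
transitions* from the pinned initial state to a terminal ϕ^F-state; the
check is a breadth-first search over the stutter relation with witness
extraction, and every witness is replayed through an independent verifier
before a network is reported.

A stutter transition fires one reaction n ≥ 1 consecutive times. We use
*sequential feasibility*: firing r n times from x requires
x_s ≥ r_s + (n−1)·max(0, r_s − p_s) for every species s, i.e. each
intermediate firing must itself be enabled. (The superficially simpler
bound x_s ≥ n(r_s − p_s) over-counts: it lets 2A → A + X "fire twice" from
two A molecules, which no interleaved execution realizes.) For n = 1 the
ordinary transition relation is recovered, and terminal states carry a
self-loop so shorter computations also fit a K_s-step unrolling. Because a
bimolecular reaction with **r** ≠ **p** always nets-consumes some species,
n is always finitely bounded.

Since the whole finite candidate space is visited, `status="exhausted"`
certifies completeness for the given (N, M, K_s): majority admits 40
networks at N = M = 3 (22 unique), maximum admits none at N = 3 and 128 at
N = 4, M = 3 (66 unique). Solution sets are monotone in K_s and saturate
quickly (K_s = 4 suffices for the majority family above; K_s = 10 is the
default). Rather than re-solving at K_s = 1, 2, … and accumulating, a
single search at the target K_s records for each network the length of its
longest witness, which is the level an incremental schedule would have
found it at — the result sets are identical and the single pass is cheaper.

## Canonicalization

Two networks are *specification-isomorphic* if one maps onto the other by
reordering reactions and permuting species within role classes: auxiliary
species are always interchangeable, and the named inputs (and outputs) are
additionally interchangeable when the specification itself is symmetric in
them (both majority and maximum default input sets are swap-closed).
`canonical_key` takes the lexicographically least serialization over all
role-preserving permutations (brute force; intended for N ≤ 6) and is the
deduplication key throughout.

## Scoring by the chemical master equation

For each ψ the score is the probability that the chain, started at the
pinned initial state, sits at time t_F in a terminal state satisfying ϕ^F;
the specification score is the unweighted mean over ψ. Terminal states are
absorbing, so this equals the mass absorbed in correct states by the
deadline; only *final* accuracy is rewarded, by design — no credit for
reaching high probability early.

The evaluator precomputes, per (network, input): the reachable states, one
unit-rate propensity matrix per reaction (the generator is linear in the
rates), the terminal/accepting masks, and whether every transient state can
reach the terminal set. Per rate vector it then chooses between two exact
routes:

* **Absorption route** (when hitting the terminal set is almost sure): LU
  factorization of −Q_TT gives the absorption probabilities, and hitting-
  time moments m_k = k(−Q_TT)⁻¹m_{k−1} give the Chebyshev tail bound
  P(T > t_F) ≤ E[T⁴]/t_F⁴. When the bound is below 1e-9 the deadline
  correction is negligible and the absorption probabilities are returned.
* **Transient route** otherwise: dense matrix exponential π_0·e^{Q t_F}.
  This is exactly the stiff regime that matters for fast/slow rate
  mixtures (ratios up to 10⁵), where scaling-and-squaring remains robust;
  the public `transient_distribution` also offers a BDF integrator
  (rtol 1e-8, atol 1e-12) on the sparse generator for larger spaces, and
  both backends agree with first-step absorption probabilities to 1e-5 on
  randomized networks (tested).

`absorption_probabilities` and `expected_termination_time` solve the
first-step linear systems directly and verify absorption (every transient
state must reach a terminal state; otherwise a non-absorbing recurrent
class error is raised). Volume scaling divides every propensity by the
volume n — the classical density scaling — so expected hitting times are
exactly linear in n.

## Rate tuning

Metropolis–Hastings over log₁₀ rates in [−3, 2] (covering "slow ≈ 0.01"
through "fast ≈ 100" with headroom), Gaussian proposals of 0.5 log-units on
one coordinate per iteration (cyclic schedule, reflected at the bounds),
started at all rates 1, with 200 burn-in + 200 sampling iterations by
default. The acceptance probability is min(1, exp(β·Δ)) with
β = ln4/(0.01·current), calibrated so a 1%-worse proposal is accepted with
probability 0.25; uphill moves always pass. The optimizer reports the best
visited point, not a posterior; score evaluations are cached per rate
vector since CME solves dominate the cost. Chains are bit-reproducible
given the seed, and pipelines derive per-network seeds from one master
seed.

Tuned results under the default conditions: the best unique Maj(3,3)
network (an asymmetric pairing/recruitment scheme) reaches ≈ 0.99, the
second-best (the symmetric three-reaction approximate-majority network)
≈ 0.93 from 0.926 at unit rates, and the maximum schema
{A+B → X+Y, A+Y → X+Y, B+Y → X+Y} reaches ≈ 0.9997 by making the pairing
reaction ≈ 100× faster than the conversions — an accuracy–time trade-off,
since slow conversions dominate the halting time.

## Fixtures and what the tests do (and do not) show

`random_bimolecular_crn` draws valid reaction sets uniformly without
replacement for property tests (conservation, reachability versus a
recursive oracle, canonical-key invariance, CME-versus-absorption
agreement). These fixtures exercise the code paths, not chemistry: they
emulate no particular kinetics beyond mass action at random log-uniform
rates in [0.01, 100] and small copy numbers (≤ 8 molecules), matching the
low-copy regime the exact CME methods target. Passing tests certify the
discrete-stochastic semantics and numerics; they say nothing about how a
physical implementation (e.g. strand displacement) would realize the rate
constants.

## Problem sizes and limitations

Enumeration is exhaustive, so cost grows as C(|candidates|, M): N = M = 3
problems solve in about a second, Max(4, 3) in a few seconds, and the full
optimization of all 22 unique majority networks (3 seeds × 400 iterations,
15 CME solves per iteration) in about a minute on one CPU. The default
run sizes keep every reachable space below a few hundred states; the
explicit-state cap (2·10⁶ states) guards memory. Larger budgets (e.g.
N = M = 4 majority, or division at N ≥ 4, M ≥ 4) are supported by the same
code paths but take hours and are not part of the default suites.

Known limitations: no non-bimolecular stoichiometries (parse-time
rejection); no temporal-logic specifications or intermediate-path
constraints; no stochastic-simulation estimator of the score (exact CME
only); no symmetry breaking inside the search beyond candidate-set
enumeration, keeping counts directly comparable to the
unique-under-isomorphism summary; specifications whose ϕ⁰ admits multiple
states are not supported at the synthesis stage (all built-ins pin one
state per input).
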