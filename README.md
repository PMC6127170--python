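# crnsynth

Design of discrete-stochastic chemical reaction networks (CRNs) from
functional specifications.

Molecular programmers — whether they target DNA strand displacement circuits
or engineered gene networks — often need a *small* reaction network that
computes a function (majority decision, maximum, division) on molecule
counts. Hand-designing such networks is hard because correctness at low copy
number is a property of a stochastic process, not of the deterministic rate
equations. `crnsynth` automates the search in two stages:

1. **Synthesis.** For a species budget *N* and reaction budget *M*, the
   complete space of bimolecular reaction sets is searched exhaustively
   under a bounded-model-checking encoding with *stutter transitions*
   (a single step fires one reaction *n* consecutive times). A network is
   kept iff, for every input configuration, some computation of at most
   `K_s` stutter steps ends in a *terminal* state (no reaction enabled)
   satisfying the output predicate. Termination with no further solutions
   certifies exhaustion of the candidate space, and every returned network
   carries machine-checked witness paths.
2. **Rate tuning.** Existence of a correct computation says nothing about
   its probability. Each candidate's rate constants **k** are tuned by a
   Metropolis–Hastings random walk in log₁₀-rate space that maximizes the
   *score*

   P<sub>Ψ</sub>(**k**) = (1/|I|) Σ<sub>i</sub> P[ computation from input *i*
   has halted in its correct final state by time t<sub>F</sub> ],

   computed exactly per input by integrating the chemical master equation
   over the reachable state space (terminal states are absorbing, so the
   score is absorbed-mass-in-correct-states at the deadline). The
   acceptance rule is rescaled so a proposal 1% worse than the current
   score is accepted with probability 0.25.

Built-in problem families: **majority** (the larger of two populations
absorbs the whole population), **maximum** (halt with `max(a, b)` copies of
the output species, inputs consumed), **Euclidean division** and
**division by two**. Continuous-time Markov chain utilities compute
absorption probabilities and expected termination times, with density
(volume) scaling for studying how completion time grows with total molecule
count.

## Worked example

The three-species network

```text
A + B -> X + X   (pairing, rate r1)
X + A -> A + A   (recruitment by A, rate r2)
X + B -> B + B   (recruitment by B, rate r3)
```

is the classic three-reaction approximate-majority scheme: opposed voters
produce an undecided species X that either side recruits.

```python
from crnsynth.library import worked_example
from crnsynth.specs import majority_spec
from crnsynth.cme import (spec_score, build_ctmc, absorption_probabilities,
                          expected_termination_time)
from crnsynth.model import reachable_states

crn = worked_example()
space = reachable_states(crn, [crn.state(A=2, B=2)])
print(f"reachable states from {{2A,2B}}: {len(space)}")
probs = absorption_probabilities(build_ctmc(crn, initial=[crn.state(A=2, B=2)]))
print(f"P[absorb in 4X]  = {probs[(0, 0, 4)]:.6f}")
print(f"P[absorb in 4A]  = {probs[(4, 0, 0)]:.6f}")
report = spec_score(crn, spec=majority_spec())
print(f"majority score at unit rates = {report.average:.4f}")
print(f"E[time to halt] from {{3A,2B}} = "
      f"{expected_termination_time(crn, x0=crn.state(A=3, B=2)):.4f}")
```

prints

```text
reachable states from {2A,2B}: 15
P[absorb in 4X]  = 0.238095
P[absorb in 4A]  = 0.380952
majority score at unit rates = 0.9258
E[time to halt] from {3A,2B} = 1.2500
```

From {2A, 2B} the chain deadlocks in the all-undecided state {4X} with
probability 5/21 ≈ 0.238; the two consensus states split the rest evenly.
Averaged over the default majority input set (all pairs (a, b) ∈ [1..4]²
except the undecidable (1, 1); ties accept either consensus), the network
halts correctly by t_F = 1000 with probability 0.926 at unit rates.

A full design run — enumerate all 3-species/3-reaction majority networks,
deduplicate up to role-preserving species renaming, score and tune each —
is one command:

```sh
crnsynth -v pipeline --config examples/majority.yaml -o runs/maj33
```

which finds 40 networks (22 unique), the best of which reaches a tuned
score of ≈ 0.99.

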