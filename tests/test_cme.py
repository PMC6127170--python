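"""CTMC construction, master-equation transients, absorption probabilities,
scores and hitting times."""

import itertools

import numpy as np
import pytest

from crnsynth.cme import (
    NonAbsorbingError,
    ScoreEvaluator,
    absorption_probabilities,
    build_ctmc,
    expected_termination_time,
    spec_score,
    transient_distribution,
)
from crnsynth.model import (
    CRN,
    Reaction,
    Species,
    propensity,
    random_bimolecular_crn,
)
from crnsynth.specs import division_by_two_spec, majority_spec
from crnsynth.textio import parse_crn


@pytest.fixture
def example_ctmc(worked_example):
    return build_ctmc(worked_example, initial=[(2, 2, 0)])


class TestGenerator:
    def test_rows_sum_to_zero(self, example_ctmc):
        rows = np.asarray(example_ctmc.Q.sum(axis=1)).ravel()
        assert np.allclose(rows, 0.0, atol=1e-12)

    def test_initial_transition_rate(self, worked_example, example_ctmc):
        i = example_ctmc.space.index[(2, 2, 0)]
        j = example_ctmc.space.index[(1, 1, 2)]
        assert example_ctmc.Q[i, j] == pytest.approx(4.0)
        assert example_ctmc.Q[i, i] == pytest.approx(-4.0)

    def test_terminal_rows_are_zero(self, example_ctmc):
        for idx in np.flatnonzero(example_ctmc.terminal):
            assert example_ctmc.Q[idx].count_nonzero() == 0

    def test_singleton_initial_set_is_unit_mass(self, example_ctmc):
        assert example_ctmc.pi0.sum() == pytest.approx(1.0)
        i = example_ctmc.space.index[(2, 2, 0)]
        assert example_ctmc.pi0[i] == 1.0

    def test_parallel_reactions_sum_propensities(self):
        crn = parse_crn("A + B -> X + X @ 1.0\nA + B -> X + W @ 0.5")
        ctmc = build_ctmc(crn, initial=[(1, 1, 0, 0)])
        i = ctmc.space.index[(1, 1, 0, 0)]
        assert ctmc.Q[i, i] == pytest.approx(-1.5)


class TestTransient:
    def test_time_zero_returns_initial_distribution(self, example_ctmc):
        assert np.array_equal(transient_distribution(example_ctmc, 0.0),
                              example_ctmc.pi0)

    @pytest.mark.parametrize("method", ["expm", "ode"])
    def test_probability_conservation(self, example_ctmc, method):
        for t in (0.1, 1.0, 10.0, 1000.0):
            pi = transient_distribution(example_ctmc, t, method=method)
            assert abs(pi.sum() - 1.0) < 1e-8
            assert (pi >= 0).all()

    def test_symmetric_absorbers_equal_at_all_times(self, example_ctmc):
        for t in (0.2, 1.0, 5.0, 50.0):
            pi = transient_distribution(example_ctmc, t)
            a = pi[example_ctmc.space.index[(4, 0, 0)]]
            b = pi[example_ctmc.space.index[(0, 4, 0)]]
            assert a == pytest.approx(b, abs=1e-12)

    def test_terminal_mass_nondecreasing(self, example_ctmc):
        masses = []
        for t in (0.1, 0.5, 1.0, 5.0, 20.0, 100.0):
            pi = transient_distribution(example_ctmc, t)
            masses.append(pi[example_ctmc.terminal].sum())
        assert all(m2 >= m1 - 1e-12 for m1, m2 in zip(masses, masses[1:]))

    def test_methods_agree(self, example_ctmc):
        a = transient_distribution(example_ctmc, 3.0, method="expm")
        b = transient_distribution(example_ctmc, 3.0, method="ode")
        assert np.allclose(a, b, atol=1e-7)


class TestAbsorption:
    def test_worked_example_hand_solution(self, example_ctmc):
        # First-step analysis on the 15-state chain gives P[{4X}] = 5/21 and
        # P[{4A}] = P[{4B}] = 8/21 at unit rates.
        probs = absorption_probabilities(example_ctmc)
        assert probs[(0, 0, 4)] == pytest.approx(5 / 21, abs=1e-12)
        assert probs[(4, 0, 0)] == pytest.approx(8 / 21, abs=1e-12)
        assert probs[(0, 4, 0)] == pytest.approx(8 / 21, abs=1e-12)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_long_time_transient(self, example_ctmc):
        pi = transient_distribution(example_ctmc, 1e6)
        probs = absorption_probabilities(example_ctmc)
        for state, p in probs.items():
            assert pi[example_ctmc.space.index[state]] == pytest.approx(p, abs=1e-6)

    def test_nonterminating_chain_detected(self):
        # A + B -> B + A alternative encoding is invalid; use a 2-cycle:
        # X + A -> 2A and A + A -> A + X cycle forever without any terminal
        crn = parse_crn("X + A -> A + A\nA + A -> A + X")
        ctmc = build_ctmc(crn, initial=[(1, 1)])
        with pytest.raises(NonAbsorbingError):
            absorption_probabilities(ctmc)

    def test_terminal_mass_matches_absorption_on_random_networks(self):
        """Transient mass on terminal states at long times equals the
        first-step absorption probabilities (20 random networks)."""
        rng = np.random.default_rng(2024)
        checked = 0
        seed = 0
        while checked < 20:
            seed += 1
            n = int(rng.integers(2, 5))
            crn = random_bimolecular_crn(n, int(rng.integers(1, 5)), seed)
            total = int(rng.integers(2, 9))
            x0 = [0] * n
            for _ in range(total):
                x0[int(rng.integers(0, n))] += 1
            rates = 10.0 ** rng.uniform(-2, 2, size=len(crn.reactions))
            ctmc = build_ctmc(crn, rates=rates, initial=[tuple(x0)])
            if not ctmc.terminal.any():
                continue
            try:
                probs = absorption_probabilities(ctmc)
            except NonAbsorbingError:
                continue
            amin = min(abs(ctmc.Q.data).min(), 1.0) if ctmc.Q.nnz else 1.0
            pi = transient_distribution(ctmc, 1e4 / amin)
            for state, p in probs.items():
                assert pi[ctmc.space.index[state]] == pytest.approx(p, abs=1e-5)
            checked += 1


class TestHittingTimes:
    def test_single_exponential(self):
        crn = parse_crn("A + B -> X + X @ 1.0")
        assert expected_termination_time(crn, x0=(1, 1, 0)) == pytest.approx(1.0)

    def test_volume_scales_times_linearly(self, worked_example):
        base = expected_termination_time(worked_example, x0=(2, 2, 0))
        for vol in (2, 5, 17):
            scaled = expected_termination_time(worked_example, x0=(2, 2, 0),
                                               volume=vol)
            assert scaled == pytest.approx(vol * base, rel=1e-10)

    def test_worked_example_equals_independent_linear_solve(self, worked_example):
        # independent dense first-step construction of E[T] from propensities
        from crnsynth.model import reachable_states, is_terminal
        space = reachable_states(worked_example, [(2, 2, 0)])
        trans = [s for s in space.states if not is_terminal(worked_example, s)]
        pos = {s: i for i, s in enumerate(trans)}
        A = np.zeros((len(trans), len(trans)))
        b = np.ones(len(trans))
        for s in trans:
            out = 0.0
            for r in worked_example.reactions:
                a = propensity(r, s)
                if a > 0:
                    out += a
                    y = tuple(v - rr + pp for v, rr, pp in
                              zip(s, r.reactants, r.products))
                    if y in pos:
                        A[pos[s], pos[y]] -= a
            A[pos[s], pos[s]] += out
        tau = np.linalg.solve(A, b)
        expected = tau[pos[(2, 2, 0)]]
        assert expected_termination_time(worked_example, x0=(2, 2, 0)) == \
            pytest.approx(expected, rel=1e-10)

    def test_terminal_start_is_zero(self, worked_example):
        assert expected_termination_time(worked_example, x0=(4, 0, 0)) == 0.0


class TestSpecScore:
    def test_stable_computation_scores_one(self, div2):
        spec = division_by_two_spec([2, 3, 4, 5, 6, 7])
        rep = spec_score(div2, spec=spec)
        assert rep.average == pytest.approx(1.0, abs=1e-9)

    def test_unreachable_goal_scores_zero(self):
        # A + B -> 2B can never end with A in the majority
        crn = parse_crn("inputs: A B\noutputs: A B\nA + B -> B + B")
        rep = spec_score(crn, spec=majority_spec([(2, 1)]))
        assert rep.average == 0.0

    def test_invariant_under_auxiliary_relabeling(self, max_schema):
        from crnsynth.specs import maximum_spec
        spec = maximum_spec([(2, 1), (1, 2), (2, 2)])
        relabeled = parse_crn("""species: A B X Q
inputs: A B
outputs: X
A + B -> X + Q @ 1.0
A + Q -> X + Q @ 1.0
B + Q -> X + Q @ 1.0""")
        a = spec_score(max_schema, spec=spec).average
        # auxiliary species name differs; scores must match
        b = spec_score(relabeled, spec=spec).average
        assert a == pytest.approx(b, abs=1e-12)

    def test_evaluator_matches_direct_ode_solution(self, worked_example):
        from crnsynth.specs import eval_predicate
        spec = majority_spec([(2, 1), (3, 2), (2, 2)])
        ev = ScoreEvaluator(worked_example, spec)
        for rates in ([1.0, 1.0, 1.0], [50.0, 0.02, 0.03], [0.004, 1.0, 3.0]):
            per = ev.per_predicate(rates)
            names = worked_example.species_names
            for psi, got in zip(spec.predicates, per):
                ctmc = build_ctmc(worked_example, rates=rates,
                                  initial=[psi.initial_state(names)])
                pi = transient_distribution(ctmc, spec.t_F, method="ode")
                want = sum(p for s, p, t in
                           zip(ctmc.states, pi, ctmc.terminal)
                           if t and eval_predicate(psi.phiF, s, names))
                assert got == pytest.approx(want, abs=5e-7)

    def test_score_mean_is_arithmetic(self, worked_example):
        spec = majority_spec([(2, 1), (1, 2), (3, 1)])
        rep = spec_score(worked_example, spec=spec)
        assert rep.average == pytest.approx(rep.per_predicate.mean())
        assert ((rep.per_predicate >= 0) & (rep.per_predicate <= 1)).all()
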