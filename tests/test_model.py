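"""Discrete CRN semantics: propensities, transitions, reachability,
canonicalization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from crnsynth.model import (
    CRN,
    CRNError,
    Reaction,
    ReactionDisabledError,
    Species,
    StateSpaceCapError,
    apply_reaction,
    bimolecular_reaction_space,
    canonical_key,
    is_terminal,
    propensity,
    random_bimolecular_crn,
    reachable_states,
)


def _r(reactants, products, rate=1.0):
    return Reaction(tuple(reactants), tuple(products), rate)


class TestReactionInvariants:
    @pytest.mark.parametrize("reactants,products", [
        ((1, 1, 1), (2, 1, 0)),   # three reactant molecules
        ((1, 1, 0), (1, 0, 0)),   # one product molecule
        ((1, 1, 0), (1, 1, 0)),   # no state change
        ((2, -1, 1), (1, 1, 0)),  # negative stoichiometry
    ])
    def test_invalid_reactions_rejected(self, reactants, products):
        with pytest.raises(CRNError):
            _r(reactants, products)

    def test_duplicate_reactions_rejected(self):
        sp = (Species("A"), Species("B"), Species("X"))
        r = _r((1, 1, 0), (0, 0, 2))
        with pytest.raises(CRNError):
            CRN(sp, (r, _r((1, 1, 0), (0, 0, 2), rate=2.0)))


class TestPropensity:
    def test_heterodimer_counts_pairings(self, worked_example):
        # two A's can each meet two B's: 4 ways
        r1 = worked_example.reactions[0]
        assert propensity(r1, (2, 2, 0)) == 4.0
        r1_fast = Reaction(r1.reactants, r1.products, 2.5)
        assert propensity(r1_fast, (2, 2, 0)) == 10.0

    def test_homodimer_counts_unordered_pairs(self):
        r = _r((2, 0), (0, 2))
        assert propensity(r, (2, 0)) == 1.0   # 2*1/2
        assert propensity(r, (5, 0)) == 10.0  # 5*4/2

    def test_zero_iff_disabled(self):
        r = _r((2, 0), (0, 2))
        assert propensity(r, (1, 3)) == 0.0
        with pytest.raises(ReactionDisabledError):
            apply_reaction(r, (1, 3))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(CRNError):
            propensity(_r((1, 1), (0, 2)), (1, 1, 0))


class TestApplyReaction:
    def test_worked_example_path(self, worked_example):
        r1 = worked_example.reactions[0]
        assert apply_reaction(r1, (2, 2, 0)) == (1, 1, 2)
        assert apply_reaction(r1, (1, 1, 2)) == (0, 0, 4)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_conservation_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        crn = random_bimolecular_crn(int(rng.integers(2, 5)),
                                     int(rng.integers(1, 5)), seed)
        x = tuple(int(v) for v in rng.integers(0, 5, size=crn.n_species))
        for r in crn.reactions:
            if all(a >= b for a, b in zip(x, r.reactants)):
                y = apply_reaction(r, x)
                assert sum(y) == sum(x)
                assert all(v >= 0 for v in y)


class TestTerminality:
    def test_worked_example_states(self, worked_example):
        assert is_terminal(worked_example, (0, 0, 4))
        assert is_terminal(worked_example, (4, 0, 0))
        assert not is_terminal(worked_example, (2, 2, 0))
        # all-undecided deadlock of the approximate-majority network
        assert is_terminal(worked_example, (0, 0, 2))


class TestReachability:
    def test_worked_example_space(self, worked_example):
        space = reachable_states(worked_example, [(2, 2, 0)])
        assert len(space) == 15
        absorbing = set(space.terminal_states)
        assert absorbing == {(4, 0, 0), (0, 4, 0), (0, 0, 4)}
        assert all(sum(s) == 4 for s in space.states)

    def test_terminal_initial_state_is_closed(self, worked_example):
        space = reachable_states(worked_example, [(4, 0, 0)])
        assert space.states == [(4, 0, 0)]

    def test_cap_exceeded_raises(self, worked_example):
        with pytest.raises(StateSpaceCapError):
            reachable_states(worked_example, [(2, 2, 0)], cap=5)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_agrees_with_recursive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 4))
        crn = random_bimolecular_crn(n, int(rng.integers(1, 4)), seed)
        total = int(rng.integers(1, 7))
        x0 = [0] * n
        for _ in range(total):
            x0[int(rng.integers(0, n))] += 1
        x0 = tuple(x0)

        def oracle(x, seen):
            if x in seen:
                return
            seen.add(x)
            for r in crn.reactions:
                if all(a >= b for a, b in zip(x, r.reactants)):
                    y = tuple(a - b + c for a, b, c in
                              zip(x, r.reactants, r.products))
                    oracle(y, seen)

        seen: set = set()
        oracle(x0, seen)
        assert set(reachable_states(crn, [x0]).states) == seen


class TestCanonicalKey:
    def _maj_crn(self, reactions):
        sp = (Species("A", True, True), Species("B", True, True),
              Species("X"), Species("Y"))
        return CRN(sp, tuple(reactions))

    def test_invariant_under_reaction_reorder_and_aux_swap(self):
        rxns = [
            _r((1, 1, 0, 0), (0, 0, 2, 0)),
            _r((1, 0, 1, 0), (0, 0, 0, 2)),
            _r((0, 1, 0, 1), (0, 2, 0, 0)),
        ]
        swapped = [  # exchange the two auxiliary species X <-> Y
            _r((1, 1, 0, 0), (0, 0, 0, 2)),
            _r((1, 0, 0, 1), (0, 0, 2, 0)),
            _r((0, 1, 1, 0), (0, 2, 0, 0)),
        ]
        a = self._maj_crn(rxns)
        b = self._maj_crn(reversed(rxns))
        c = self._maj_crn(swapped)
        assert canonical_key(a) == canonical_key(b) == canonical_key(c)

    def test_input_swap_only_with_flag(self, worked_example):
        mirror_text = [(r.reactants[1], r.reactants[0], r.reactants[2])
                       for r in worked_example.reactions]
        mirror = CRN(worked_example.species, tuple(
            Reaction((r.reactants[1], r.reactants[0], r.reactants[2]),
                     (r.products[1], r.products[0], r.products[2]))
            for r in worked_example.reactions))
        # the network is symmetric in A and B, so even the rigid key matches
        assert canonical_key(mirror) == canonical_key(worked_example)
        asym = CRN(worked_example.species, (
            _r((1, 1, 0), (0, 0, 2)),
            _r((1, 0, 1), (2, 0, 0)),
            _r((0, 0, 2), (0, 2, 0)),
        ))
        asym_mirror = CRN(worked_example.species, (
            _r((1, 1, 0), (0, 0, 2)),
            _r((0, 1, 1), (0, 2, 0)),
            _r((0, 0, 2), (2, 0, 0)),
        ))
        assert canonical_key(asym) != canonical_key(asym_mirror)
        assert (canonical_key(asym, permute_inputs=True)
                == canonical_key(asym_mirror, permute_inputs=True))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_random_role_preserving_permutation(self, seed):
        rng = np.random.default_rng(seed)
        crn = random_bimolecular_crn(5, 4, seed, n_inputs=2, n_outputs=1)
        classes = {}
        for i, sp in enumerate(crn.species):
            classes.setdefault((sp.is_input, sp.is_output), []).append(i)
        perm = list(range(5))
        for idxs in classes.values():
            shuffled = list(rng.permutation(idxs))
            for o, nw in zip(idxs, shuffled):
                perm[o] = nw
        rxns = []
        for r in crn.reactions:
            rv, pv = [0] * 5, [0] * 5
            for i in range(5):
                rv[perm[i]] = r.reactants[i]
                pv[perm[i]] = r.products[i]
            rxns.append(Reaction(tuple(rv), tuple(pv)))
        rng.shuffle(rxns)
        permuted = CRN(crn.species, tuple(rxns))
        assert (canonical_key(permuted, permute_inputs=True)
                == canonical_key(crn, permute_inputs=True))


class TestRandomFixtures:
    def test_deterministic_in_seed(self):
        assert (random_bimolecular_crn(3, 3, 7)
                == random_bimolecular_crn(3, 3, 7))

    def test_emitted_reactions_are_valid_bimolecular(self):
        crn = random_bimolecular_crn(4, 10, 123)
        for r in crn.reactions:
            assert sum(r.reactants) == 2 and sum(r.products) == 2
            assert r.reactants != r.products

    def test_infeasible_request_raises(self):
        # only 30 distinct bimolecular reactions exist over 3 species
        assert len(bimolecular_reaction_space(3)) == 30
        with pytest.raises(CRNError):
            random_bimolecular_crn(3, 31, 0)
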