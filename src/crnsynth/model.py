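"""Discrete-state model of bimolecular chemical reaction networks.

A chemical reaction network (CRN) is a finite set of species together with a
finite set of reactions.  Here every reaction is *bimolecular*: it consumes
exactly two reactant molecules and produces exactly two product molecules, so
the total molecule count is conserved along every trajectory.  States are
vectors of non-negative integer molecule counts, one entry per species, and
the stochastic semantics is the usual continuous-time Markov jump process with
mass-action propensities:

* homodimer  ``2S -> ...``  fires with propensity ``k * x_S * (x_S - 1) / 2``
* heterodimer ``S + S' -> ...`` fires with propensity ``k * x_S * x_S'``

This module holds the concrete data model (:class:`Species`,
:class:`Reaction`, :class:`CRN`), the discrete transition semantics
(:func:`propensity`, :func:`apply_reaction`, :func:`is_terminal`,
:func:`reachable_states`), canonicalization of CRNs up to specification
isomorphism (:func:`canonical_key`), and random CRN fixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "State",
    "Species",
    "Reaction",
    "CRN",
    "StateSpace",
    "CRNError",
    "ReactionDisabledError",
    "StateSpaceCapError",
    "DEFAULT_STATE_CAP",
    "propensity",
    "is_enabled",
    "apply_reaction",
    "is_terminal",
    "enabled_reactions",
    "reachable_states",
    "canonical_key",
    "bimolecular_reaction_space",
    "random_bimolecular_crn",
]

#: A system state: molecule counts indexed by the CRN's species order.
State = tuple[int, ...]

#: Default cap on the number of explicitly enumerated states.
DEFAULT_STATE_CAP = 2_000_000


class CRNError(ValueError):
    """Contract violation in CRN construction or use."""


class ReactionDisabledError(CRNError):
    """A reaction was applied to a state that does not enable it."""


class StateSpaceCapError(CRNError):
    """Reachable state enumeration exceeded the configured cap."""


@dataclass(frozen=True)
class Species:
    """A named species with an interface role.

    A species may simultaneously be an input and an output (the majority
    problem reports its answer in the input species themselves); a species
    that is neither is auxiliary.
    """

    name: str
    is_input: bool = False
    is_output: bool = False

    @property
    def role(self) -> str:
        if self.is_input and self.is_output:
            return "input+output"
        if self.is_input:
            return "input"
        if self.is_output:
            return "output"
        return "auxiliary"


@dataclass(frozen=True)
class Reaction:
    """A bimolecular reaction: reactant/product stoichiometry vectors + rate.

    ``reactants`` and ``products`` are tuples of non-negative integers indexed
    by the owning CRN's species order; each must sum to 2, and the two vectors
    must differ (a reaction must change the state).
    """

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate: float = 1.0

    def __post_init__(self) -> None:
        if len(self.reactants) != len(self.products):
            raise CRNError("reactant/product vectors have different lengths")
        if any(v < 0 for v in self.reactants + self.products):
            raise CRNError("negative stoichiometry")
        if sum(self.reactants) != 2 or sum(self.products) != 2:
            raise CRNError(
                "only bimolecular reactions (two reactants, two products) are supported"
            )
        if self.reactants == self.products:
            raise CRNError("reaction must change the state (reactants == products)")
        if not self.rate > 0:
            raise CRNError("rate constants must be strictly positive")

    @property
    def delta(self) -> tuple[int, ...]:
        """Net stoichiometric change ``p - r``."""
        return tuple(p - r for r, p in zip(self.reactants, self.products))


@dataclass(frozen=True)
class CRN:
    """A chemical reaction network: ordered species plus a reaction list.

    The species order is part of the data model; all stoichiometry vectors and
    states are indexed by it.  Reactions must be pairwise distinct as
    (reactants, products) pairs.
    """

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise CRNError("species names must be unique")
        n = len(self.species)
        seen = set()
        for r in self.reactions:
            if len(r.reactants) != n:
                raise CRNError("reaction dimension does not match species count")
            key = (r.reactants, r.products)
            if key in seen:
                raise CRNError(f"duplicate reaction {key}")
            seen.add(key)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        for i, s in enumerate(self.species):
            if s.name == name:
                return i
        raise CRNError(f"unknown species {name!r}")

    @property
    def rates(self) -> np.ndarray:
        return np.array([r.rate for r in self.reactions], dtype=float)

    def with_rates(self, rates) -> "CRN":
        """Return a copy of this CRN with the given rate vector."""
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (len(self.reactions),):
            raise CRNError("rate vector length must equal the number of reactions")
        new = tuple(
            Reaction(r.reactants, r.products, float(k))
            for r, k in zip(self.reactions, rates)
        )
        return CRN(self.species, new)

    def state(self, **counts: int) -> State:
        """Build a state from species-name keyword counts (others zero)."""
        x = [0] * self.n_species
        for name, c in counts.items():
            x[self.species_index(name)] = int(c)
        return tuple(x)


def _check_dim(reaction: Reaction, state: State) -> None:
    if len(reaction.reactants) != len(state):
        raise CRNError("reaction and state are over different species lists")


def propensity(reaction: Reaction, state: State) -> float:
    """Mass-action propensity of ``reaction`` in ``state``.

    Returns 0 exactly when the reaction is not enabled.
    """
    _check_dim(reaction, state)
    k = reaction.rate
    idx = [i for i, r in enumerate(reaction.reactants) if r > 0]
    if len(idx) == 1:  # homodimer 2S -> ...
        xs = state[idx[0]]
        return k * xs * (xs - 1) / 2.0
    i, j = idx
    return k * state[i] * state[j]


def is_enabled(reaction: Reaction, state: State) -> bool:
    _check_dim(reaction, state)
    return all(x >= r for x, r in zip(state, reaction.reactants))


def apply_reaction(reaction: Reaction, state: State) -> State:
    """Fire ``reaction`` once: ``x' = x - r + p``.

    Raises
    ------
    ReactionDisabledError
        If some species count is below the reaction's reactant stoichiometry.
    """
    if not is_enabled(reaction, state):
        raise ReactionDisabledError(f"reaction disabled in state {state}")
    return tuple(x - r + p for x, r, p in
                 zip(state, reaction.reactants, reaction.products))


def enabled_reactions(crn: CRN, state: State) -> list[int]:
    return [m for m, r in enumerate(crn.reactions) if is_enabled(r, state)]


def is_terminal(crn: CRN, state: State) -> bool:
    """True iff no reaction of ``crn`` is enabled in ``state``."""
    return not any(is_enabled(r, state) for r in crn.reactions)


@dataclass
class StateSpace:
    """Explicit reachable state set of a CRN from a set of initial states."""

    crn: CRN
    states: list[State]
    index: dict[State, int]
    terminal: np.ndarray  # bool per state
    initial_indices: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def terminal_states(self) -> list[State]:
        return [s for s, t in zip(self.states, self.terminal) if t]


def reachable_states(crn: CRN, initial, cap: int = DEFAULT_STATE_CAP) -> StateSpace:
    """Breadth-first closure of ``initial`` under single-reaction transitions.

    Finite for bimolecular CRNs because the total molecule count is conserved.

    Raises
    ------
    StateSpaceCapError
        If more than ``cap`` states are discovered.
    """
    initial = [tuple(int(v) for v in x) for x in initial]
    if not initial:
        raise CRNError("initial state set must be non-empty")
    for x in initial:
        if len(x) != crn.n_species or any(v < 0 for v in x):
            raise CRNError(f"invalid initial state {x}")
    states: list[State] = []
    index: dict[State, int] = {}
    frontier: list[State] = []
    for x in initial:
        if x not in index:
            index[x] = len(states)
            states.append(x)
            frontier.append(x)
    while frontier:
        nxt: list[State] = []
        for x in frontier:
            for r in crn.reactions:
                if is_enabled(r, x):
                    y = tuple(v - a + b for v, a, b in
                              zip(x, r.reactants, r.products))
                    if y not in index:
                        if len(states) >= cap:
                            raise StateSpaceCapError(
                                f"state space too large (cap {cap})")
                        index[y] = len(states)
                        states.append(y)
                        nxt.append(y)
        frontier = nxt
    terminal = np.array([is_terminal(crn, s) for s in states], dtype=bool)
    return StateSpace(crn=crn, states=states, index=index, terminal=terminal,
                      initial_indices=[index[x] for x in initial])


# ---------------------------------------------------------------------------
# Canonicalization under specification isomorphism
# ---------------------------------------------------------------------------

def _role_class(sp: Species) -> tuple[bool, bool]:
    return (sp.is_input, sp.is_output)


def canonical_key(crn: CRN, permute_inputs: bool = False):
    """Canonical encoding of a CRN up to specification isomorphism.

    Two CRNs receive equal keys iff one maps onto the other by (a) reordering
    its reaction list and (b) permuting species within role classes: auxiliary
    species are always interchangeable, and species sharing the same
    (input, output) role flags are additionally interchangeable when
    ``permute_inputs`` is set (appropriate when the specification itself is
    symmetric in its named inputs, e.g. majority or maximum with an
    input set closed under swapping).

    Implemented by brute force over role-preserving permutations (intended for
    small N) taking the lexicographically least serialization.
    """
    n = crn.n_species
    # group species indices by role class
    groups: dict[tuple[bool, bool], list[int]] = {}
    for i, sp in enumerate(crn.species):
        groups.setdefault(_role_class(sp), []).append(i)

    per_group_perms = []
    for cls, idxs in groups.items():
        movable = (cls == (False, False)) or permute_inputs
        if movable:
            per_group_perms.append([list(p) for p in itertools.permutations(idxs)])
        else:
            per_group_perms.append([idxs])
    group_order = list(groups.values())

    best = None
    for combo in itertools.product(*per_group_perms):
        perm = [0] * n  # perm[old_index] = new position of that species
        for orig_idxs, new_idxs in zip(group_order, combo):
            for o, nw in zip(orig_idxs, new_idxs):
                perm[o] = nw
        rxns = []
        for r in crn.reactions:
            rv = [0] * n
            pv = [0] * n
            for i in range(n):
                rv[perm[i]] = r.reactants[i]
                pv[perm[i]] = r.products[i]
            rxns.append((tuple(rv), tuple(pv)))
        key = tuple(sorted(rxns))
        if best is None or key < best:
            best = key
    return best


# ---------------------------------------------------------------------------
# Candidate reaction spaces and random fixtures
# ---------------------------------------------------------------------------

def bimolecular_reaction_space(n_species: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All distinct bimolecular (reactants, products) pairs over ``n_species``.

    Both sides range over all multisets of size two; pairs with equal sides
    are excluded.  For 3 species this yields 30 candidate reactions, for 4
    species 90.
    """
    sides = []
    for i in range(n_species):
        for j in range(i, n_species):
            v = [0] * n_species
            v[i] += 1
            v[j] += 1
            sides.append(tuple(v))
    return [(r, p) for r in sides for p in sides if r != p]


def random_bimolecular_crn(n_species: int, n_reactions: int, seed: int,
                           n_inputs: int = 0, n_outputs: int = 0) -> CRN:
    """Random valid bimolecular CRN; identical seed gives an identical CRN.

    Species are named ``S0..S{n-1}``; the first ``n_inputs`` are flagged as
    inputs and the following ``n_outputs`` as outputs.  All rates are 1.
    """
    space = bimolecular_reaction_space(n_species)
    if n_reactions > len(space):
        raise CRNError(
            f"only {len(space)} distinct bimolecular reactions exist over "
            f"{n_species} species; cannot draw {n_reactions}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(space), size=n_reactions, replace=False)
    species = tuple(
        Species(f"S{i}", is_input=i < n_inputs,
                is_output=n_inputs <= i < n_inputs + n_outputs)
        for i in range(n_species))
    reactions = tuple(Reaction(*space[int(c)]) for c in sorted(chosen))
    return CRN(species, reactions)
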