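"""Exhaustive synthesis of bimolecular CRNs from path-predicate specifications.

Given a species budget ``N``, a reaction budget ``M`` and a stutter bound
``K_s``, the enumerator visits the complete candidate space of ``M``-element
sets of distinct bimolecular reactions over ``N`` role-labelled species and
keeps exactly those networks that admit, for *every* path predicate
``psi = (phi0, phiF)`` of the specification, a computation of at most ``K_s``
stutter transitions from the phi0-pinned initial state to a terminal state
satisfying phiF.  The search is a bounded-model-checking procedure made
explicit: structural constraints (bimolecularity, every input consumed by at
least one reaction, every output produced by at least one reaction, pairwise
distinct reactions, reactants != products) carve the candidate space, and a
breadth-first search over the stutter transition relation decides the bounded
reachability obligation and extracts a witness path.

A *stutter transition* compresses ``n >= 1`` consecutive firings of one
reaction into a single step (feasible iff each intermediate firing is
enabled), and adds a self-loop at terminal states so that computations
shorter than ``K_s`` steps are also found.  For ``n = 1`` the ordinary
one-step transition relation is recovered.

Because the whole finite candidate space is visited, termination with
``status='exhausted'`` certifies that no further CRN satisfies the
specification for the given ``(N, M, K_s)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .model import (
    CRN,
    Reaction,
    State,
    bimolecular_reaction_space,
    is_enabled,
    is_terminal,
)
from .specs import PathPredicate, Specification, eval_predicate

__all__ = [
    "SynthesisProblem",
    "SynthesisResult",
    "WitnessStep",
    "stutter_successors",
    "max_stutter_firings",
    "encode_synthesis",
    "enumerate_crns",
    "verify_witness",
]

#: One stutter step of a witness: fire reaction ``reaction`` ``n`` times,
#: arriving at ``state``.
WitnessStep = tuple[int, int, State]


@dataclass(frozen=True)
class SynthesisProblem:
    """Search-space bounds plus the specification to satisfy."""

    spec: Specification
    n_species: int
    n_reactions: int
    stutter_bound: int = 10
    solution_limit: int | None = None

    def __post_init__(self) -> None:
        if self.n_reactions < 1 or self.stutter_bound < 1:
            raise ValueError("need at least one reaction and one stutter step")


@dataclass
class SynthesisResult:
    """Enumerated CRNs (discovery order, unit rates) with their witnesses.

    ``witnesses[i][j]`` is the witness path of CRN ``i`` for path predicate
    ``j``: a list of :data:`WitnessStep` starting after the pinned initial
    state.  ``levels[i]`` is the smallest stutter bound at which CRN ``i``
    would have been found (the length of its longest witness).  ``status`` is
    ``'exhausted'`` when the whole candidate space was visited, else
    ``'limit_reached'``.
    """

    problem: SynthesisProblem
    crns: list[CRN] = field(default_factory=list)
    witnesses: list[list[list[WitnessStep]]] = field(default_factory=list)
    levels: list[int] = field(default_factory=list)
    status: str = "exhausted"
    n_candidates: int = 0

    def __len__(self) -> int:
        return len(self.crns)


def max_stutter_firings(reaction: Reaction, state: State) -> int:
    """Largest ``n`` such that ``reaction`` can fire ``n`` consecutive times
    from ``state`` (every intermediate firing enabled).

    Sequential feasibility requires ``x_s >= r_s + (n-1) * max(0, r_s - p_s)``
    for every species ``s``; every bimolecular reaction with ``r != p`` has at
    least one net-consumed species, so the bound is always finite.
    """
    if not is_enabled(reaction, state):
        return 0
    n = None
    for x, r, p in zip(state, reaction.reactants, reaction.products):
        d = r - p
        if d > 0:
            bound = (x - p) // d
            n = bound if n is None else min(n, bound)
    return int(n)


def stutter_successors(crn: CRN, state: State) -> set[tuple[State, int | None, int]]:
    """All stutter transitions from ``state``: ``(x', m, n)`` meaning reaction
    ``m`` fired ``n >= 1`` consecutive times, plus the self-loop
    ``(state, None, 0)`` when ``state`` is terminal."""
    out: set[tuple[State, int | None, int]] = set()
    any_enabled = False
    for m, r in enumerate(crn.reactions):
        nmax = max_stutter_firings(r, state)
        if nmax == 0:
            continue
        any_enabled = True
        d = r.delta
        x = state
        for n in range(1, nmax + 1):
            x = tuple(v + dv for v, dv in zip(x, d))
            out.add((x, m, n))
    if not any_enabled:
        out.add((state, None, 0))
    return out


# ---------------------------------------------------------------------------
# Encoding: candidate space + compiled path obligations
# ---------------------------------------------------------------------------

@dataclass
class _CompiledPredicate:
    initial: State
    accept: object  # callable State -> bool (phiF, excluding terminality)
    label: str


@dataclass
class SynthesisEncoding:
    """Explicit encoding of a synthesis problem: the role-labelled species,
    the structurally admissible candidate reactions with coverage masks, and
    one compiled bounded-reachability obligation per path predicate."""

    problem: SynthesisProblem
    species: tuple
    candidates: list[tuple[tuple[int, ...], tuple[int, ...]]]
    consumes_mask: list[int]   # bitmask over input species per candidate
    produces_mask: list[int]   # bitmask over output species per candidate
    compiled: list[_CompiledPredicate]
    full_input_mask: int
    full_output_mask: int


def _compile_predicate(psi: PathPredicate, names: tuple[str, ...]) -> _CompiledPredicate:
    initial = psi.initial_state(names)
    phiF = psi.phiF
    alts = phiF.alternatives if hasattr(phiF, "alternatives") else (phiF,)
    try:
        targets = frozenset(
            tuple(p.pinned_counts().get(n, 0) for n in names) for p in alts)

        def accept(state: State, _t=targets) -> bool:
            return state in _t
    except Exception:
        def accept(state: State, _p=phiF, _n=names) -> bool:
            return eval_predicate(_p, state, _n)
    return _CompiledPredicate(initial=initial, accept=accept, label=psi.label)


def encode_synthesis(problem: SynthesisProblem) -> SynthesisEncoding:
    """Build the explicit constraint encoding of a synthesis problem.

    Models of this encoding (reaction sets passing the structural masks and
    all bounded-reachability obligations) are exactly the CRNs admitting a
    ``<= K_s``-step stutter witness per path predicate.
    """
    spec = problem.spec
    species = spec.make_species(problem.n_species)
    names = tuple(s.name for s in species)
    in_idx = [i for i, s in enumerate(species) if s.is_input]
    out_idx = [i for i, s in enumerate(species) if s.is_output]

    candidates = bimolecular_reaction_space(problem.n_species)
    consumes, produces = [], []
    for r, p in candidates:
        cm = sum(1 << k for k, i in enumerate(in_idx) if r[i] > 0)
        pm = sum(1 << k for k, i in enumerate(out_idx) if p[i] > 0)
        consumes.append(cm)
        produces.append(pm)

    compiled = [_compile_predicate(psi, names) for psi in spec.predicates]
    # cheap obligations first: small state spaces fail/succeed fastest
    compiled.sort(key=lambda c: sum(c.initial))
    return SynthesisEncoding(
        problem=problem, species=species, candidates=candidates,
        consumes_mask=consumes, produces_mask=produces, compiled=compiled,
        full_input_mask=(1 << len(in_idx)) - 1,
        full_output_mask=(1 << len(out_idx)) - 1)


# ---------------------------------------------------------------------------
# Bounded witness search over the stutter relation
# ---------------------------------------------------------------------------

def _prep_reaction(rp: tuple[tuple[int, ...], tuple[int, ...]]):
    """Precompute (reactant vector, delta, positive-drain terms) for speed."""
    r, p = rp
    delta = tuple(b - a for a, b in zip(r, p))
    drains = tuple((i, r[i] - p[i], p[i]) for i in range(len(r)) if r[i] > p[i])
    return (r, delta, drains)


def _bounded_witness(prepped, x0: State, accept, ks: int):
    """BFS over stutter transitions; returns the witness path (list of
    WitnessStep) if a terminal accepting state is reachable within ``ks``
    steps, else None.  A path shorter than ``ks`` is implicitly padded by the
    terminal self-loop."""

    def terminal(x: State) -> bool:
        for r, _, _ in prepped:
            if all(a >= b for a, b in zip(x, r)):
                return False
        return True

    def reconstruct(x: State):
        path = []
        while True:
            prev, m, n = parent[x]
            if m is None:
                break
            path.append((m, n, x))
            x = prev
        path.reverse()
        return path

    parent: dict[State, tuple[State | None, int | None, int]] = {x0: (None, None, 0)}
    if terminal(x0):
        return [] if accept(x0) else None
    frontier = [x0]
    for _ in range(ks):
        nxt = []
        for x in frontier:
            for m, (r, delta, drains) in enumerate(prepped):
                if not all(a >= b for a, b in zip(x, r)):
                    continue
                nmax = min((x[i] - p) // d for i, d, p in drains)
                y = x
                for n in range(1, nmax + 1):
                    y = tuple(a + dv for a, dv in zip(y, delta))
                    if y in parent:
                        continue
                    parent[y] = (x, m, n)
                    if terminal(y):
                        if accept(y):
                            return reconstruct(y)
                    else:
                        nxt.append(y)
        frontier = nxt
        if not frontier:
            break
    return None


def enumerate_crns(problem: SynthesisProblem) -> SynthesisResult:
    """Enumerate every CRN of the candidate space satisfying the
    specification, to exhaustion (or ``solution_limit``).

    Returned CRNs carry placeholder rate 1 (reachability is rate-free); no
    two share the same reaction set, and each comes with one verified-format
    witness per path predicate.
    """
    enc = encode_synthesis(problem)
    ks = problem.stutter_bound
    prepped_all = [_prep_reaction(rp) for rp in enc.candidates]
    result = SynthesisResult(problem=problem)

    idxs = range(len(enc.candidates))
    for combo in itertools.combinations(idxs, problem.n_reactions):
        result.n_candidates += 1
        cm = pm = 0
        for c in combo:
            cm |= enc.consumes_mask[c]
            pm |= enc.produces_mask[c]
        if cm != enc.full_input_mask or pm != enc.full_output_mask:
            continue
        prepped = [prepped_all[c] for c in combo]
        wits = []
        ok = True
        for comp in enc.compiled:
            w = _bounded_witness(prepped, comp.initial, comp.accept, ks)
            if w is None:
                ok = False
                break
            wits.append(w)
        if not ok:
            continue
        crn = CRN(enc.species,
                  tuple(Reaction(*enc.candidates[c]) for c in combo))
        # restore specification order of the witnesses
        wit_by_label = {c.label: w for c, w in zip(enc.compiled, wits)}
        ordered = [wit_by_label[psi.label] for psi in problem.spec.predicates]
        result.crns.append(crn)
        result.witnesses.append(ordered)
        result.levels.append(max((len(w) for w in ordered), default=0) or 1)
        if (problem.solution_limit is not None
                and len(result.crns) >= problem.solution_limit):
            result.status = "limit_reached"
            return result
    result.status = "exhausted"
    return result


def find_witnesses(crn: CRN, spec: Specification, stutter_bound: int = 10):
    """Bounded witness search for a *concrete* CRN: one witness path per path
    predicate, or None if some predicate has no computation within
    ``stutter_bound`` stutter steps."""
    names = tuple(s.name for s in crn.species)
    prepped = [_prep_reaction((r.reactants, r.products)) for r in crn.reactions]
    out = []
    for psi in spec.predicates:
        comp = _compile_predicate(psi, names)
        w = _bounded_witness(prepped, comp.initial, comp.accept, stutter_bound)
        if w is None:
            return None
        out.append(w)
    return out


def verify_witness(crn: CRN, spec: Specification, witnesses) -> bool:
    """Independently replay witness paths under concrete stutter semantics.

    True iff, for every path predicate, the path starts at the phi0-pinned
    state, every step fires an enabled reaction the claimed number of
    consecutive times, and the final state satisfies phiF and is terminal.
    """
    names = crn.species_names
    if len(witnesses) != len(spec.predicates):
        return False
    for psi, path in zip(spec.predicates, witnesses):
        try:
            x = psi.initial_state(names)
        except Exception:
            return False
        for m, n, claimed in path:
            if not (0 <= m < len(crn.reactions)) or n < 1:
                return False
            r = crn.reactions[m]
            for _ in range(n):
                if not is_enabled(r, x):
                    return False
                x = tuple(v - a + b for v, a, b in
                          zip(x, r.reactants, r.products))
            if x != tuple(claimed):
                return False
        if not is_terminal(crn, x):
            return False
        if not eval_predicate(psi.phiF, x, names):
            return False
    return True
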