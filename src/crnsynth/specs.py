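"""Path-predicate specifications for CRN design.

A *state predicate* is a conjunction of linear integer constraints on species
counts.  A *path predicate* ``psi = (phi0, phiF)`` constrains the initial and
final state of a computation; satisfaction additionally requires the final
state to be terminal (no reaction enabled), so a satisfying computation halts
with the answer.  A :class:`Specification` is a named problem instantiated on
a finite set of integer input configurations ``I`` with a deadline ``t_F``.

Built-in problem families
-------------------------
* :func:`majority_spec` — convert the smaller of two populations ``A``/``B``
  into the larger; the winner must hold the whole population at the end.
* :func:`maximum_spec` — halt with ``max(a, b)`` copies of the output species.
* :func:`division_spec` — Euclidean division: halt with ``floor(a / b)``
  copies of the output species.
* :func:`division_by_two_spec` — division by the fixed constant 2, a single
  input species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import CRN, Species, State

__all__ = [
    "StatePredicate",
    "AnyPredicate",
    "PathPredicate",
    "Specification",
    "SpecificationError",
    "eval_predicate",
    "majority_spec",
    "maximum_spec",
    "division_spec",
    "division_by_two_spec",
    "DEFAULT_T_F",
    "DEFAULT_MAJORITY_INPUTS",
    "DEFAULT_MAXIMUM_INPUTS",
    "DEFAULT_DIVISION_INPUTS",
]

#: Default deadline (time units) for all built-in specifications.
DEFAULT_T_F = 1000.0

_OPS = {
    "=": lambda a, b: a == b,
    "<=": lambda a, b: a <= b,
    ">=": lambda a, b: a >= b,
    "<": lambda a, b: a < b,
    ">": lambda a, b: a > b,
}


class SpecificationError(ValueError):
    """Invalid specification request (ties, zero divisor, ...)."""


@dataclass(frozen=True)
class StatePredicate:
    """Conjunction of ``species <op> bound`` constraints over counts.

    ``constraints`` maps by position: each item is ``(species_name, op,
    bound)`` with ``op`` in ``{=, <=, >=, <, >}``.  When ``others_zero`` is
    set, every species *not* named in the constraints must have count 0; this
    lets a predicate written over the interface species extend to any CRN
    containing them.
    """

    constraints: tuple[tuple[str, str, int], ...] = ()
    others_zero: bool = False

    def species_mentioned(self) -> set[str]:
        return {name for name, _, _ in self.constraints}

    def __call__(self, state: State, species_names) -> bool:
        return eval_predicate(self, state, species_names)

    def pinned_counts(self) -> dict[str, int]:
        """Exact counts if every conjunct is an equality, else raise."""
        if not self.others_zero:
            raise SpecificationError("predicate does not pin unmentioned species")
        out = {}
        for name, op, bound in self.constraints:
            if op != "=":
                raise SpecificationError("predicate is not a pinned state")
            out[name] = bound
        return out


@dataclass(frozen=True)
class AnyPredicate:
    """Disjunction of state predicates: true iff any alternative holds.

    Used for final predicates with several acceptable outcomes, e.g. a
    majority tie where either consensus counts as a decision.
    """

    alternatives: tuple[StatePredicate, ...]

    def species_mentioned(self) -> set[str]:
        out: set[str] = set()
        for p in self.alternatives:
            out |= p.species_mentioned()
        return out

    def __call__(self, state: State, species_names) -> bool:
        return eval_predicate(self, state, species_names)


def eval_predicate(predicate, state: State, species_names) -> bool:
    """Evaluate a state predicate on a concrete state.

    ``species_names`` is the ordered name list matching ``state``.  The empty
    conjunction is vacuously true.  Disjunctions (:class:`AnyPredicate`) are
    true iff any alternative holds.
    """
    if isinstance(predicate, AnyPredicate):
        return any(eval_predicate(p, state, species_names)
                   for p in predicate.alternatives)
    names = list(species_names)
    pos = {n: i for i, n in enumerate(names)}
    for name, op, bound in predicate.constraints:
        if name not in pos:
            raise SpecificationError(f"unknown species {name!r} in predicate")
        if not _OPS[op](state[pos[name]], bound):
            return False
    if predicate.others_zero:
        mentioned = predicate.species_mentioned()
        for n, x in zip(names, state):
            if n not in mentioned and x != 0:
                return False
    return True


@dataclass(frozen=True)
class PathPredicate:
    """An (initial, final) state-predicate pair; the final state must also be
    terminal for the predicate to be satisfied."""

    phi0: StatePredicate
    phiF: StatePredicate
    label: str = ""

    def initial_state(self, species_names) -> State:
        """The unique state pinned by phi0 (built-in specs pin every count)."""
        counts = self.phi0.pinned_counts()
        return tuple(counts.get(n, 0) for n in species_names)


@dataclass(frozen=True)
class Specification:
    """A named problem over a finite input set with a deadline.

    ``input_species`` / ``output_species`` bind the interface roles that a
    candidate CRN must provide; auxiliary species are free.  ``predicates``
    holds one path predicate per configuration in ``input_set``.
    """

    name: str
    predicates: tuple[PathPredicate, ...]
    input_set: tuple[tuple[int, ...], ...]
    t_F: float
    input_species: tuple[str, ...]
    output_species: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.predicates) != len(self.input_set):
            raise SpecificationError("one path predicate per input configuration")

    @property
    def symmetric_inputs(self) -> bool:
        """True iff the problem is invariant under swapping the two inputs
        (two input species and an input set closed under reversal)."""
        if len(self.input_species) != 2:
            return False
        s = set(self.input_set)
        return all(tuple(reversed(i)) in s for i in s)

    def make_species(self, n_species: int, aux_names=("X", "Y", "Z", "U", "V", "W")) -> tuple[Species, ...]:
        """Species tuple for a candidate CRN of size ``n_species``: inputs,
        then pure outputs, then auxiliaries."""
        inputs = list(self.input_species)
        outputs = [o for o in self.output_species if o not in inputs]
        if n_species < len(inputs) + len(outputs):
            raise SpecificationError("n_species too small for interface species")
        species = [Species(n, is_input=True, is_output=n in self.output_species)
                   for n in inputs]
        species += [Species(n, is_output=True) for n in outputs]
        used = {s.name for s in species}
        pool = [a for a in aux_names if a not in used]
        species += [Species(pool[i]) for i in range(n_species - len(species))]
        return tuple(species)


# ---------------------------------------------------------------------------
# Built-in problem families
# ---------------------------------------------------------------------------

#: Majority input configurations: all pairs (a, b) with a, b in 1..4 except
#: the pathological (1, 1).  Ties (a, a) accept either consensus.
DEFAULT_MAJORITY_INPUTS: tuple[tuple[int, int], ...] = tuple(
    (a, b) for a in range(1, 5) for b in range(1, 5) if (a, b) != (1, 1)
)

#: Maximum input configurations: all pairs (a, b) with a, b in 1..6.
DEFAULT_MAXIMUM_INPUTS: tuple[tuple[int, int], ...] = tuple(
    (a, b) for a in range(1, 7) for b in range(1, 7)
)

#: Euclidean-division input configurations: five dividends for each divisor
#: in 2..5, spanning quotients 1..5 with varied remainders.
DEFAULT_DIVISION_INPUTS: tuple[tuple[int, int], ...] = tuple(
    (a, b) for b in (2, 3, 4, 5) for a in (b, b + 1, 2 * b, 2 * b + 1, 3 * b)
)


def _pinned_phi0(a: int, b: int) -> StatePredicate:
    return StatePredicate((("A", "=", a), ("B", "=", b)), others_zero=True)


def majority_spec(input_set=DEFAULT_MAJORITY_INPUTS, t_F: float = DEFAULT_T_F) -> Specification:
    """Majority (binary consensus): the larger initial population absorbs the
    whole population; the loser and every auxiliary species end at zero.

    Every configuration must have ``a, b >= 1``.  A tie ``a == b >= 2`` is
    allowed and accepts either consensus (all-A or all-B); the input (1, 1)
    is rejected as pathological — a single opposed pair cannot reach either
    consensus in the known three-species networks.
    """
    preds = []
    for a, b in input_set:
        if a < 1 or b < 1:
            raise SpecificationError("majority inputs must be >= 1")
        if a == b == 1:
            raise SpecificationError(
                "the input (1, 1) is a pathological configuration and is "
                "not allowed in a majority specification")
        consensus_a = StatePredicate(
            (("A", "=", a + b), ("B", "=", 0)), others_zero=True)
        consensus_b = StatePredicate(
            (("B", "=", a + b), ("A", "=", 0)), others_zero=True)
        if a > b:
            phiF = consensus_a
        elif b > a:
            phiF = consensus_b
        else:
            phiF = AnyPredicate((consensus_a, consensus_b))
        preds.append(PathPredicate(_pinned_phi0(a, b), phiF, label=f"({a},{b})"))
    return Specification(
        name="majority", predicates=tuple(preds), input_set=tuple(input_set),
        t_F=t_F, input_species=("A", "B"), output_species=("A", "B"))


def maximum_spec(input_set=DEFAULT_MAXIMUM_INPUTS, t_F: float = DEFAULT_T_F,
                 consume_inputs: bool = True) -> Specification:
    """Maximum: halt with ``max(a, b)`` copies of the output species ``X``.

    By default both input species must also be fully consumed in the final
    state (``A = 0 and B = 0``); waste species remain free, although for
    bimolecular networks conservation then fixes their total to ``min(a, b)``.
    ``consume_inputs=False`` relaxes the final predicate to the output count
    alone.  Note that pinning *all* non-output species to zero would be
    unsatisfiable outright: conservation keeps the total at ``a + b`` while
    the output alone would hold only ``max(a, b)``.
    """
    preds = []
    for a, b in input_set:
        if a < 0 or b < 0 or a + b < 1:
            raise SpecificationError("maximum inputs must be non-negative, not both 0")
        constraints = [("X", "=", max(a, b))]
        if consume_inputs:
            constraints += [("A", "=", 0), ("B", "=", 0)]
        phiF = StatePredicate(tuple(constraints))
        preds.append(PathPredicate(_pinned_phi0(a, b), phiF, label=f"({a},{b})"))
    return Specification(
        name="maximum", predicates=tuple(preds), input_set=tuple(input_set),
        t_F=t_F, input_species=("A", "B"), output_species=("X",))


def division_spec(input_set=DEFAULT_DIVISION_INPUTS, t_F: float = DEFAULT_T_F,
                  constrain_non_outputs: bool = False) -> Specification:
    """Euclidean division: halt with ``floor(a / b)`` copies of output ``X``."""
    preds = []
    for a, b in input_set:
        if b < 1:
            raise SpecificationError("division by zero requested")
        phiF = StatePredicate((("X", "=", a // b),),
                              others_zero=constrain_non_outputs)
        preds.append(PathPredicate(_pinned_phi0(a, b), phiF, label=f"({a},{b})"))
    return Specification(
        name="division", predicates=tuple(preds), input_set=tuple(input_set),
        t_F=t_F, input_species=("A", "B"), output_species=("X",))


def division_by_two_spec(input_set=(2, 3, 4, 5, 6, 7), t_F: float = DEFAULT_T_F) -> Specification:
    """Division by the constant 2: a single input species ``A``; halt with
    ``floor(a / 2)`` copies of output ``X``.  Stably computed by the
    single-reaction network ``A + A -> X + W``."""
    preds = []
    for a in input_set:
        a = int(a[0]) if isinstance(a, (tuple, list)) else int(a)
        if a < 1:
            raise SpecificationError("input must be >= 1")
        phi0 = StatePredicate((("A", "=", a),), others_zero=True)
        phiF = StatePredicate((("X", "=", a // 2),), others_zero=False)
        preds.append(PathPredicate(phi0, phiF, label=f"({a})"))
    return Specification(
        name="division_by_two", predicates=tuple(preds),
        input_set=tuple((int(a[0]) if isinstance(a, (tuple, list)) else int(a),)
                        for a in input_set),
        t_F=t_F, input_species=("A",), output_species=("X",))
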