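"""Named reference networks used throughout the package and its tests.

All constructors return CRNs with unit rates unless stated otherwise; roles
follow the owning problem (majority reports its answer in the input species
themselves, maximum/division in a dedicated output species).
"""

from __future__ import annotations

from .model import CRN
from .textio import parse_crn

__all__ = [
    "worked_example",
    "approximate_majority_3",
    "exact_majority_5",
    "maximum_schema",
    "minimum_crn",
    "division_by_two_crn",
]


def worked_example() -> CRN:
    """The three-species network used as the running illustration: a pairing
    reaction plus two catalytic conversions.

    From {2A, 2B} its CTMC has 15 reachable states and three absorbing
    states {4A}, {4B}, {4X}; at unit rates the all-X deadlock is absorbed
    with probability 5/21.
    """
    return parse_crn("""species: A B X
inputs: A B
outputs: A B
A + B -> X + X @ 1.0
X + A -> A + A @ 1.0
X + B -> B + B @ 1.0""")


def approximate_majority_3() -> CRN:
    """Three-reaction approximate majority: the two populations convert each
    other into an undecided species X, which either side recruits.  The
    same reaction set as :func:`worked_example`."""
    return worked_example()


def exact_majority_5() -> CRN:
    """The four-species exact-majority protocol (strong/weak states) plus two
    funnel reactions so the decision ends in a single all-winner state.

    The first three reactions are the classic four-state protocol: opposed
    strong molecules weaken each other, and strong molecules flip weak
    opponents.  The funnels convert weak supporters into strong winners, so a
    decided population collapses to all-A or all-B.
    """
    return parse_crn("""species: A B X Y
inputs: A B
outputs: A B
A + B -> X + Y @ 1.0
A + Y -> A + X @ 1.0
B + X -> B + Y @ 1.0
A + X -> A + A @ 1.0
B + Y -> B + B @ 1.0""")


def maximum_schema(f1: str = "Y", f2: str = "Y") -> CRN:
    """Probabilistic-maximum schema: inputs pair off into one output and one
    license molecule Y; leftover input is then converted to output one-for-
    one against Y.  ``f1``/``f2`` choose the second product of the two
    conversion reactions (from A, B or Y); the (Y, Y) instantiation is the
    one that satisfies the maximum specification.

    Accurate when the pairing reaction is fast and the conversions slow
    (accuracy-time trade-off).
    """
    for f in (f1, f2):
        if f not in {"A", "B", "Y"}:
            raise ValueError("schema products must be chosen from A, B, Y")
    return parse_crn(f"""species: A B X Y
inputs: A B
outputs: X
A + B -> X + Y @ 1.0
A + Y -> X + {f1} @ 1.0
B + Y -> X + {f2} @ 1.0""")


def minimum_crn() -> CRN:
    """Stable minimum: ``A + B -> X + W`` fires exactly min(a, b) times."""
    return parse_crn("""species: A B X W
inputs: A B
outputs: X
A + B -> X + W @ 1.0""")


def division_by_two_crn() -> CRN:
    """Stable division by two: ``A + A -> X + W`` halts with floor(a/2) X."""
    return parse_crn("""species: A X W
inputs: A
outputs: X
A + A -> X + W @ 1.0""")
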