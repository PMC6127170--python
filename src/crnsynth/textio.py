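"""Plain-text CRN format.

One reaction per line, ``A + B -> X + X @ 1.0``; a coefficient prefix is
accepted as sugar (``2A -> X + W @ 0.5`` means ``A + A``).  Comment lines
start with ``#``.  A header block declares the species order and roles::

    species: A B X
    inputs: A B
    outputs: A B

The ``species:`` line is optional on input (order of first appearance is used
when absent) but always written, so that writer output re-parses to an
identical in-memory CRN.
"""

from __future__ import annotations

import re

from .model import CRN, CRNError, Reaction, Species

__all__ = ["parse_crn", "format_crn", "CRNParseError"]


class CRNParseError(CRNError):
    """Malformed CRN text; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


_TERM = re.compile(r"^(\d*)\s*([A-Za-z_]\w*)$")


def _parse_side(text: str, line: int) -> list[tuple[str, int]]:
    terms = [t.strip() for t in text.split("+")]
    out = []
    for t in terms:
        m = _TERM.match(t)
        if not m:
            raise CRNParseError(f"cannot parse species term {t!r}", line)
        coeff = int(m.group(1)) if m.group(1) else 1
        out.append((m.group(2), coeff))
    return out


def parse_crn(text: str) -> CRN:
    """Parse the documented reaction grammar into a :class:`CRN`.

    Raises :class:`CRNParseError` (with line numbers) for non-bimolecular
    reactions, duplicate reactions, or reactions with reactants == products.
    """
    species_order: list[str] = []
    inputs: set[str] = set()
    outputs: set[str] = set()
    raw: list[tuple[int, list, list, float]] = []

    def note(name: str) -> None:
        if name not in species_order:
            species_order.append(name)

    declared_order = False
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        low = line.lower()
        if low.startswith(("species:", "inputs:", "outputs:")):
            key, _, rest = line.partition(":")
            names = rest.split()
            if key.lower() == "species":
                declared_order = True
                for n in names:
                    note(n)
            elif key.lower() == "inputs":
                inputs.update(names)
                if not declared_order:
                    for n in names:
                        note(n)
            else:
                outputs.update(names)
                if not declared_order:
                    for n in names:
                        note(n)
            continue
        if "->" not in line:
            raise CRNParseError("expected a reaction ('->' missing)", ln)
        lhs, _, rhs = line.partition("->")
        rate = 1.0
        if "@" in rhs:
            rhs, _, rate_s = rhs.partition("@")
            try:
                rate = float(rate_s.strip())
            except ValueError:
                raise CRNParseError(f"bad rate {rate_s.strip()!r}", ln)
        lterms = _parse_side(lhs, ln)
        rterms = _parse_side(rhs, ln)
        for name, _ in lterms + rterms:
            note(name)
        raw.append((ln, lterms, rterms, rate))

    if not raw:
        raise CRNParseError("no reactions found")

    species = tuple(
        Species(n, is_input=n in inputs, is_output=n in outputs)
        for n in species_order)
    idx = {n: i for i, n in enumerate(species_order)}
    reactions = []
    seen = set()
    for ln, lterms, rterms, rate in raw:
        r = [0] * len(species)
        p = [0] * len(species)
        for name, c in lterms:
            r[idx[name]] += c
        for name, c in rterms:
            p[idx[name]] += c
        if sum(r) != 2 or sum(p) != 2:
            raise CRNParseError("reaction is not bimolecular "
                                "(needs two reactants and two products)", ln)
        if tuple(r) == tuple(p):
            raise CRNParseError("reactants equal products", ln)
        key = (tuple(r), tuple(p))
        if key in seen:
            raise CRNParseError("duplicate reaction", ln)
        seen.add(key)
        try:
            reactions.append(Reaction(tuple(r), tuple(p), rate))
        except CRNError as e:
            raise CRNParseError(str(e), ln)
    return CRN(species, tuple(reactions))


def format_crn(crn: CRN) -> str:
    """Serialize a CRN; ``parse_crn(format_crn(crn))`` reproduces it exactly."""
    lines = [
        "species: " + " ".join(crn.species_names),
        "inputs: " + " ".join(s.name for s in crn.species if s.is_input),
        "outputs: " + " ".join(s.name for s in crn.species if s.is_output),
    ]
    names = crn.species_names
    for r in crn.reactions:
        def side(v):
            terms = []
            for n, c in zip(names, v):
                terms.extend([n] * c)
            return " + ".join(terms)
        lines.append(f"{side(r.reactants)} -> {side(r.products)} @ {r.rate!r}")
    return "\n".join(lines) + "\n"
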