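"""Molecular formula parsing and writing over the CHONSP alphabet.

FT-MS formula assignment tools report either a formula string per peak
(e.g. ``"C8H14O7"``) or one integer column per element.  This module converts
between the two representations.  The canonical string dialect writes elements
in the order C, H, O, N, S, P with an explicit multiplicity for every present
element (including 1) and omits absent elements; the parser is more liberal and
accepts any element order and implicit multiplicities of one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .constants import ELEMENTS, FORMULA_ORDER, MONOISOTOPIC_MASS

__all__ = ["ElementCounts", "parse_formula", "write_formula", "monoisotopic_mass"]

_TOKEN = re.compile(r"([A-Za-z])(\d*)")


@dataclass(frozen=True)
class ElementCounts:
    """Non-negative element counts of a molecular formula."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            v = getattr(self, el)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"element count {el}={v!r} must be a non-negative integer")

    def as_dict(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in ELEMENTS}


def parse_formula(text: str) -> ElementCounts:
    """Parse a formula string into element counts.

    Accepts the elements C, H, N, O, S, P in any order, with optional integer
    multiplicities (an omitted multiplicity means 1).  Elements absent from the
    string get a count of zero.

    Raises
    ------
    ValueError
        On an unknown element symbol, a repeated element, a zero multiplicity,
        or a string that is not a sequence of element tokens.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError(f"not a formula string: {text!r}")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(s):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {text!r} at position {pos}")
        el, mult = m.group(1), m.group(2)
        if el not in ELEMENTS:
            raise ValueError(f"unknown element {el!r} in formula {text!r}")
        if el in counts:
            raise ValueError(f"repeated element {el!r} in formula {text!r}")
        n = int(mult) if mult else 1
        if n == 0:
            raise ValueError(f"zero multiplicity for {el!r} in formula {text!r}")
        counts[el] = n
        pos = m.end()
    if pos != len(s):
        raise ValueError(f"unparseable formula {text!r} at position {pos}")
    if not counts:
        raise ValueError(f"empty formula {text!r}")
    return ElementCounts(**counts)


def write_formula(counts: ElementCounts) -> str:
    """Write counts as a canonical formula string.

    Element order is C, H, O, N, S, P with an explicit multiplicity for every
    present element; absent elements are omitted.  A formula must contain at
    least one carbon and one hydrogen (the assignable-formula convention of
    CHONSP peak lists).
    """
    if counts.C < 1 or counts.H < 1:
        raise ValueError(f"formula requires C >= 1 and H >= 1, got C={counts.C}, H={counts.H}")
    return "".join(
        f"{el}{getattr(counts, el)}" for el in FORMULA_ORDER if getattr(counts, el) > 0
    )


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Monoisotopic (exact) mass of the neutral formula, in Da."""
    return sum(MONOISOTOPIC_MASS[el] * getattr(counts, el) for el in ELEMENTS)
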