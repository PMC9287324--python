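"""Set algebra over IUPAC nucleotide ambiguity codes.

A directly sequenced hybrid shows, at every site where its two parental
ribotypes differ, the superposition of both parental bases.  Chromatogram
software records that superposition as the IUPAC ambiguity code whose base
set is the union of the parental bases ("additive polymorphism").  This
module provides the exact code <-> base-set bijection and the union /
containment operations the site classifier is built on.

The gap character ``-`` is deliberately *not* a member of this algebra: an
indel between parents is a length difference, not a base superposition, and
is handled by the shifted-superposition logic in :mod:`hybridtrace.additivity`.
"""

from __future__ import annotations

from .errors import GapStateError

GAP = "-"

#: IUPAC code -> set of concrete bases it denotes.
CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in CODE_TO_BASES.items()}

#: All 15 valid single-letter codes.
CODES: frozenset[str] = frozenset(CODE_TO_BASES)


def base_set(code: str) -> frozenset[str]:
    """Return the set of concrete bases denoted by ``code``.

    Raises :class:`GapStateError` for the gap character and ``ValueError``
    for anything else outside the 15-letter IUPAC alphabet.
    """
    if code == GAP:
        raise GapStateError("gap '-' has no base set; gaps are handled outside the IUPAC algebra")
    try:
        return CODE_TO_BASES[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC code: {code!r}") from None


def union(a: str, b: str) -> str:
    """IUPAC code for base_set(a) | base_set(b) — the additive superposition."""
    return BASES_TO_CODE[base_set(a) | base_set(b)]


def union_many(codes) -> str:
    """Union over an iterable of codes (used for three-parent superpositions)."""
    acc: frozenset[str] = frozenset()
    n = 0
    for c in codes:
        acc = acc | base_set(c)
        n += 1
    if n == 0:
        raise ValueError("union_many requires at least one code")
    return BASES_TO_CODE[acc]


def subsumes(a: str, b: str) -> bool:
    """True iff base_set(b) is a subset of base_set(a)."""
    return base_set(b) <= base_set(a)


def is_ambiguous(code: str) -> bool:
    """True iff the code denotes more than one base (R, Y, ... N)."""
    return len(base_set(code)) > 1
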