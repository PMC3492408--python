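"""Fixed-length consensus-motif patterns and exhaustive scanning.

The supported dialect is the fixed-length PROSITE subset used for
nucleotide-binding consensus motifs: single residues, the wildcard ``X``, and
bracketed residue classes written either ``[RK]`` or ``[R/K]``. Scanning tests
every window, so mutually overlapping hits (e.g. two glycine-rich motifs two
residues apart) are all reported; nothing is deduplicated or merged here —
downstream inference decides containment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence_io import STANDARD_RESIDUES, ProteinSequence


class PatternSyntaxError(ValueError):
    """Raised on a malformed pattern string; message names the position."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled fixed-length consensus pattern.

    ``elements`` holds one frozenset of admissible residues per position;
    ``None`` marks the wildcard (any of the 20 standard residues).
    """

    id: str
    elements: tuple

    @property
    def length(self) -> int:
        return len(self.elements)

    def render(self) -> str:
        """Canonical pattern string; compiling it reproduces this pattern."""
        parts = []
        for el in self.elements:
            if el is None:
                parts.append("X")
            elif len(el) == 1:
                parts.append(next(iter(el)))
            else:
                parts.append("[" + "".join(sorted(el)) + "]")
        return "".join(parts)

    def matches(self, window: str, permissive_x: bool = False) -> bool:
        """Does ``window`` (length == pattern length) satisfy the pattern?

        An 'X' in the *sequence* matches nothing by default (it is an unknown
        residue, not a wildcard); ``permissive_x=True`` lets it match any
        position.
        """
        if len(window) != self.length:
            return False
        for residue, el in zip(window, self.elements):
            if residue == "X":
                if permissive_x:
                    continue
                return False
            if el is None:
                continue
            if residue not in el:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    """A located motif instance; ``start``/``end`` are 1-based inclusive."""

    pattern_id: str
    start: int
    end: int
    matched: str

    @property
    def span(self) -> tuple:
        return (self.start, self.end)


def compile_pattern(text: str, pattern_id: str | None = None) -> MotifPattern:
    """Compile a pattern string into a :class:`MotifPattern`.

    Raises :class:`PatternSyntaxError` (naming the offending position) for an
    unclosed bracket, an empty class, or an illegal character.
    """
    elements = []
    i = 0
    standard = set(STANDARD_RESIDUES)
    while i < len(text):
        c = text[i]
        if c == "X":
            elements.append(None)
            i += 1
        elif c in standard:
            elements.append(frozenset(c))
            i += 1
        elif c == "[":
            close = text.find("]", i)
            if close < 0:
                raise PatternSyntaxError(f"unclosed '[' at position {i + 1}: {text!r}")
            members = set()
            for j in range(i + 1, close):
                m = text[j]
                if m == "/":
                    continue
                if m not in standard:
                    raise PatternSyntaxError(
                        f"illegal class member {m!r} at position {j + 1}: {text!r}"
                    )
                members.add(m)
            if not members:
                raise PatternSyntaxError(f"empty class at position {i + 1}: {text!r}")
            elements.append(frozenset(members))
            i = close + 1
        else:
            raise PatternSyntaxError(f"illegal character {c!r} at position {i + 1}: {text!r}")
    if not elements:
        raise PatternSyntaxError("empty pattern")
    return MotifPattern(id=pattern_id or text, elements=tuple(elements))


#: Pattern strings of the three built-in nucleotide-binding consensus motifs.
BUILTIN_PATTERN_STRINGS = {
    "WALKER_A": "GXGXXG",
    "WALKER_B_PARTIAL": "[R/K]XXXGXXXL",
    "GROES": "Y[G/A/S/T][V/G][K/T/Q/S/N]",
}


def builtin_patterns() -> dict:
    """The three built-in consensus patterns, keyed by id.

    WALKER_A is the glycine-rich Walker-A motif GXGXXG; WALKER_B_PARTIAL is
    the partial Walker-B consensus [R/K]XXXGXXXL; GROES is the 4-residue
    consensus Y[G/A/S/T][V/G][K/T/Q/S/N] of the chaperonin GroES ATP-binding
    site (binds but does not hydrolyze ATP).
    """
    return {
        key: compile_pattern(text, pattern_id=key)
        for key, text in BUILTIN_PATTERN_STRINGS.items()
    }


def scan(
    seq: ProteinSequence,
    patterns,
    permissive_x: bool = False,
) -> list[MotifHit]:
    """Report every hit of every pattern on ``seq``.

    All windows are tested, so overlapping hits are all returned; the result
    is sorted by (start, pattern_id). ``patterns`` may be a list of compiled
    patterns or a dict keyed by pattern id.
    """
    if isinstance(patterns, dict):
        patterns = list(patterns.values())
    hits = []
    residues = seq.residues
    n = len(residues)
    for pattern in patterns:
        plen = pattern.length
        for start0 in range(0, n - plen + 1):
            window = residues[start0 : start0 + plen]
            if pattern.matches(window, permissive_x=permissive_x):
                hits.append(
                    MotifHit(
                        pattern_id=pattern.id,
                        start=start0 + 1,
                        end=start0 + plen,
                        matched=window,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.pattern_id))
    return hits
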