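"""Protease cleavage-site prediction and complete in-silico digestion.

The trypsin rule is the standard Keil rule: cleave C-terminal to K or R
unless the next residue is P. The rule table is externalized so alternative
specificities can be registered. A *complete* digest is the generative
primitive (every site cut); the limited proteolysis of the experiment is
represented downstream by admitting any span whose boundaries are cleavage
sites or protein termini.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence_io import MassTable, ProteinSequence, round_kda, segment_mass


class DigestError(ValueError):
    pass


@dataclass(frozen=True)
class CleavageRule:
    """Cleave after any residue in ``targets`` unless followed by a blocker."""

    id: str
    targets: frozenset
    blocked_by_next: frozenset


#: Registered cleavage rules, keyed by rule id.
CLEAVAGE_RULES = {
    "trypsin": CleavageRule(
        id="trypsin", targets=frozenset("KR"), blocked_by_next=frozenset("P")
    ),
}


@dataclass(frozen=True)
class CleavageMap:
    """Predicted cut positions: a site ``i`` separates residues i and i+1."""

    protein_id: str
    rule_id: str
    sites: tuple

    def __post_init__(self) -> None:
        if list(self.sites) != sorted(set(self.sites)):
            raise DigestError("cleavage sites must be strictly ascending")


@dataclass(frozen=True)
class PredictedFragment:
    start: int
    end: int
    calc_mass_da: float
    calc_kda: int


def cleavage_sites(seq: ProteinSequence, rule: str = "trypsin") -> CleavageMap:
    """Predict cleavage sites of ``seq`` under a registered rule.

    The terminal residue never yields a cut (there is nothing to separate).
    """
    try:
        r = CLEAVAGE_RULES[rule]
    except KeyError:
        raise DigestError(f"unknown cleavage rule {rule!r}; "
                          f"known: {sorted(CLEAVAGE_RULES)}") from None
    residues = seq.residues
    sites = tuple(
        i + 1
        for i in range(len(residues) - 1)
        if residues[i] in r.targets and residues[i + 1] not in r.blocked_by_next
    )
    return CleavageMap(protein_id=seq.id, rule_id=rule, sites=sites)


def complete_digest(
    seq: ProteinSequence,
    cmap: CleavageMap,
    table: MassTable | None = None,
    x_fallback: float | None = None,
) -> list[PredictedFragment]:
    """Cut at every site; fragments partition [1, length] in order."""
    boundaries = [0, *cmap.sites, seq.length]
    fragments = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        mass = segment_mass(seq, lo + 1, hi, table=table, x_fallback=x_fallback)
        fragments.append(
            PredictedFragment(
                start=lo + 1, end=hi, calc_mass_da=mass, calc_kda=round_kda(mass)
            )
        )
    return fragments
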