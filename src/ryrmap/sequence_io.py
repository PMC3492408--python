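"""Protein sequence I/O and average-mass arithmetic.

Coordinates are 1-based and inclusive throughout the package, matching the
"amino acids 427-1302" convention of the experimental literature. Masses are
average (isotope-abundance-weighted) residue masses in daltons; a peptide mass
is the sum of its residue masses plus one water.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Alphabet accepted in sequences; 'X' marks an unknown residue.
ALPHABET = frozenset(STANDARD_RESIDUES) | {"X"}


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty file, illegal residue codes)."""


class MassError(ValueError):
    """Raised for invalid mass computations (bad coordinates, 'X' in span)."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified protein sequence.

    Parameters
    ----------
    id:
        Accession or label (e.g. a Swiss-Prot accession).
    residues:
        Upper-case one-letter amino-acid string; 'X' permitted as unknown.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = [(i + 1, c) for i, c in enumerate(self.residues) if c not in ALPHABET]
        if bad:
            pos, char = bad[0]
            raise FastaFormatError(
                f"record {self.id!r}: illegal residue {char!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def segment(self, start: int, end: int) -> str:
        """Residue substring for a 1-based inclusive span."""
        _check_span(self, start, end)
        return self.residues[start - 1 : end]


def _check_span(seq: ProteinSequence, start: int, end: int) -> None:
    if not (1 <= start <= end <= seq.length):
        raise MassError(
            f"span {start}-{end} out of range for {seq.id!r} (length {seq.length})"
        )


@dataclass(frozen=True)
class MassTable:
    """Average residue masses in Da, plus the mass of one water.

    The default table is loaded from a versioned TSV shipped with the package
    so the mass convention is auditable.
    """

    masses: dict = field(default_factory=dict)
    water_mass: float = 18.01524

    def __post_init__(self) -> None:
        missing = [r for r in STANDARD_RESIDUES if r not in self.masses]
        if missing:
            raise MassError(f"mass table missing residues: {''.join(missing)}")
        nonpos = [r for r, m in self.masses.items() if m <= 0]
        if nonpos:
            raise MassError(f"non-positive masses for: {''.join(nonpos)}")

    @property
    def mean_residue_mass(self) -> float:
        return sum(self.masses[r] for r in STANDARD_RESIDUES) / len(STANDARD_RESIDUES)

    @classmethod
    def from_tsv(cls, path) -> "MassTable":
        masses = {}
        water = None
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("residue"):
                continue
            key, value = line.split("\t")
            if key == "water":
                water = float(value)
            else:
                masses[key] = float(value)
        if water is None:
            raise MassError(f"mass table {path} has no 'water' row")
        return cls(masses=masses, water_mass=water)

    @classmethod
    def default(cls) -> "MassTable":
        ref = importlib.resources.files("ryrmap") / "data" / "average_masses.tsv"
        return cls.from_tsv(ref)


_DEFAULT_TABLE = None


def default_mass_table() -> MassTable:
    """The packaged average-mass table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = MassTable.default()
    return _DEFAULT_TABLE


def read_fasta(path) -> list[ProteinSequence]:
    """Read a multi-record FASTA file into :class:`ProteinSequence` objects.

    Lower-case residues are upcased and a single terminal '*' (stop) is
    stripped. Raises :class:`FastaFormatError` on an empty file or on residue
    codes outside the 21-letter alphabet, naming the offending record and
    position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        out.append(ProteinSequence(id=rec.id, residues=residues))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path, width: int = 60) -> None:
    """Write sequences to FASTA, wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def segment_mass(
    seq: ProteinSequence,
    start: int,
    end: int,
    table: MassTable | None = None,
    x_fallback: float | None = None,
) -> float:
    """Average mass in Da of the peptide spanning ``start``-``end`` (1-based,
    inclusive): sum of residue masses plus one water.

    'X' residues in the span are an error unless ``x_fallback`` provides a
    substitute mass (e.g. ``table.mean_residue_mass``).
    """
    table = table or default_mass_table()
    _check_span(seq, start, end)
    total = table.water_mass
    for offset, residue in enumerate(seq.residues[start - 1 : end]):
        if residue == "X":
            if x_fallback is None:
                raise MassError(
                    f"unknown residue 'X' at position {start + offset} in span "
                    f"{start}-{end}; pass x_fallback to assign it a mass"
                )
            total += x_fallback
        else:
            total += table.masses[residue]
    return total


def round_kda(mass_da: float) -> int:
    """Round a mass in Da to the nearest integer kDa, halves up."""
    if mass_da < 0:
        raise MassError(f"negative mass: {mass_da}")
    return int(math.floor(mass_da / 1000.0 + 0.5))
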