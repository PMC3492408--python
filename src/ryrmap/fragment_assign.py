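"""Assignment of observed proteolytic fragments to protein coordinates.

An observed fragment is a gel band with an apparent SDS-PAGE mass and an
Edman N-terminal read. Its N-terminus is anchored by matching the read
against the protein sequence (low-confidence parenthesized calls, 'X'
unidentified cycles and '-' skipped cycles are wildcards), optionally
requiring the match to sit at a predicted cleavage junction. Its C-terminus
is then chosen among downstream cleavage sites (or the protein terminus) by
closeness of the calculated average mass to the apparent mass; the result is
a *ranked candidate list*, never a silently forced single answer — the
original analysis disambiguated with prior knowledge, and a ``known_end``
can pin an assignment the same way.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .digest import CleavageMap
from .sequence_io import MassTable, ProteinSequence, round_kda, segment_mass


class ReadFormatError(ValueError):
    pass


class NotLocatedError(ValueError):
    """The N-terminal read matches nowhere under the anchoring rules."""


class AnchoringError(ValueError):
    """The decoded read is too short for unique anchoring."""


class UnassignableError(ValueError):
    """No cleavage site yields a calculated mass within tolerance."""


@dataclass(frozen=True)
class ObservedFragment:
    """A gel/Edman observation.

    ``nterm_read`` uses the notation of the source tables: plain letters are
    confident calls, '(A)' a low-confidence call, 'X' an unidentified cycle,
    '-' a skipped cycle, and 'ND' (or empty) no read at all (e.g. N-terminal
    blockage). ``span`` may carry a fixed, externally supplied span for
    read-less fragments.
    """

    fragment_id: str
    apparent_kda: float | None = None
    nterm_read: str = ""
    labeled: bool = False
    parent_id: str | None = None
    span: tuple | None = None

    @property
    def has_read(self) -> bool:
        return bool(self.nterm_read) and self.nterm_read != "ND"


@dataclass(frozen=True)
class FragmentAssignment:
    fragment_id: str
    start: int
    end: int
    calc_mass_da: float
    calc_kda: int
    mass_error_fraction: float
    candidate_rank: int


_TOKEN = re.compile(r"\(([A-Z])\)|([A-Z])|(-)")


def decode_read(notation: str) -> tuple:
    """Decode an Edman read into per-cycle constraints.

    Returns a tuple with one entry per cycle: a one-letter residue for a
    confident call, or ``None`` for a wildcard cycle ('(A)' low-confidence,
    'X' unidentified, '-' skipped).
    """
    if not notation or notation == "ND":
        return ()
    out = []
    pos = 0
    for m in _TOKEN.finditer(notation):
        if m.start() != pos:
            raise ReadFormatError(
                f"cannot parse read {notation!r} at offset {pos}"
            )
        pos = m.end()
        low_conf, confident, skipped = m.groups()
        if skipped or low_conf:
            out.append(None)
        elif confident == "X":
            out.append(None)
        else:
            out.append(confident)
    if pos != len(notation):
        raise ReadFormatError(f"cannot parse read {notation!r} at offset {pos}")
    return tuple(out)


def _read_matches_at(residues: str, decoded: tuple, start0: int) -> bool:
    if start0 + len(decoded) > len(residues):
        return False
    for offset, want in enumerate(decoded):
        if want is None:
            continue
        if residues[start0 + offset] != want:
            return False
    return True


def locate_n_terminus(
    seq: ProteinSequence,
    read,
    min_length: int = 5,
    require_cleavage_junction: bool = True,
    cmap: CleavageMap | None = None,
) -> list[int]:
    """All candidate 1-based start positions where the Edman read matches.

    ``read`` is either a notation string or an already-decoded tuple. With
    ``require_cleavage_junction`` (strict mode, default) a candidate must be
    position 1 or sit immediately after a predicted cleavage site, in which
    case ``cmap`` is required. Multiple candidates are returned, not silently
    resolved; zero candidates raise :class:`NotLocatedError`.
    """
    decoded = decode_read(read) if isinstance(read, str) else tuple(read)
    anchored = sum(1 for r in decoded if r is not None)
    if anchored < min_length:
        raise AnchoringError(
            f"read has {anchored} confident cycles; {min_length} required "
            f"for unique anchoring"
        )
    if require_cleavage_junction:
        if cmap is None:
            raise ValueError("strict anchoring requires a CleavageMap")
        starts = [1, *(s + 1 for s in cmap.sites)]
    else:
        starts = range(1, seq.length + 1)
    hits = [s for s in starts if _read_matches_at(seq.residues, decoded, s - 1)]
    if not hits:
        raise NotLocatedError(
            f"read {read!r} not located in {seq.id!r}"
            + (" (strict cleavage-junction anchoring)" if require_cleavage_junction else "")
        )
    return hits


def assign_c_terminus(
    seq: ProteinSequence,
    start: int,
    apparent_kda: float,
    cmap: CleavageMap,
    tolerance: float = 0.15,
    fragment_id: str = "",
    table: MassTable | None = None,
    x_fallback: float | None = None,
) -> list[FragmentAssignment]:
    """Ranked candidate assignments for a fragment starting at ``start``.

    Candidate ends are every cleavage site at or beyond ``start`` plus the
    protein terminus. Candidates whose calculated mass differs from the
    apparent mass by more than ``tolerance`` (as a fraction of the apparent
    mass) are dropped; survivors are ranked by ascending mass error, ties
    broken toward the larger fragment. If nothing survives,
    :class:`UnassignableError` reports the nearest miss.
    """
    if not (0 < tolerance < 0.5):
        raise ValueError(f"tolerance must be in (0, 0.5), got {tolerance}")
    if apparent_kda <= 0:
        raise ValueError(f"apparent_kda must be positive, got {apparent_kda}")
    ends = sorted({s for s in cmap.sites if s >= start} | {seq.length})
    scored = []
    for end in ends:
        mass = segment_mass(seq, start, end, table=table, x_fallback=x_fallback)
        err = abs(mass / 1000.0 - apparent_kda) / apparent_kda
        scored.append((err, end, mass))
    kept = sorted(
        (t for t in scored if t[0] <= tolerance), key=lambda t: (t[0], -t[1])
    )
    if not kept:
        nearest = min(scored, key=lambda t: t[0])
        raise UnassignableError(
            f"fragment {fragment_id or start}: no cleavage site within "
            f"tolerance {tolerance:.0%} of {apparent_kda} kDa; nearest miss is "
            f"end {nearest[1]} ({nearest[2] / 1000:.1f} kDa, error {nearest[0]:.1%})"
        )
    return [
        FragmentAssignment(
            fragment_id=fragment_id,
            start=start,
            end=end,
            calc_mass_da=mass,
            calc_kda=round_kda(mass),
            mass_error_fraction=err,
            candidate_rank=rank,
        )
        for rank, (err, end, mass) in enumerate(kept, start=1)
    ]


# ---------------------------------------------------------------------------
# Tabular I/O

def read_fragments_tsv(path) -> list[ObservedFragment]:
    """Read observed fragments from TSV.

    Expected columns: fragment_id, apparent_kda, nterm_read, labeled,
    parent_id; optional start/end columns supply fixed spans (e.g. for
    read-less fragments or unlabeled fragments known only by their span).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        span = None
        if "start" in row and "end" in row:
            start_txt, end_txt = row["start"].strip(), row["end"].strip()
            if start_txt and end_txt:
                span = (int(float(start_txt)), int(float(end_txt)))
        apparent = row.get("apparent_kda", "").strip()
        out.append(
            ObservedFragment(
                fragment_id=row["fragment_id"].strip(),
                apparent_kda=float(apparent) if apparent else None,
                nterm_read=row.get("nterm_read", "").strip(),
                labeled=row.get("labeled", "0").strip() in {"1", "true", "True"},
                parent_id=row.get("parent_id", "").strip() or None,
                span=span,
            )
        )
    return out


def assignments_to_frame(assignments) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fragment_id": a.fragment_id,
                "start": a.start,
                "end": a.end,
                "calc_kda": a.calc_kda,
                "calc_mass_da": round(a.calc_mass_da, 3),
                "mass_error_fraction": round(a.mass_error_fraction, 6),
                "candidate_rank": a.candidate_rank,
            }
            for a in assignments
        ]
    )
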