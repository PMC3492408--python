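"""Inference of candidate ATP-binding regions from labeled-fragment evidence.

This is the core analytical step: photoaffinity-label flags on assigned
proteolytic fragments, the precursor/product derivation graph, consensus-motif
hits, membrane topology, and mutagenesis exclusions are combined into a
:class:`BindingCallSet`. Region refinement applies four rules per labeled
root fragment:

R1. If labeled products exist, the region narrows to each deepest labeled
    product's span (the label must reside inside it).
R2. Spans of unlabeled products are subtracted (a bound probe cannot lie in a
    sequence whose fragment carries no label), after shrinking each subtracted
    span at its C-terminus by an ambiguity window ``w`` (clustered cleavage
    sites near a fragment's C-terminus make that boundary soft).
R3. A labeled fragment *all* of whose direct products are unlabeled is
    demoted: its label position cannot be corroborated, since the label
    apparently vanished on further digestion.
R4. Overlapping surviving regions are merged.

Motif filtering then keeps only hits fully contained in a candidate region,
not overlapping any exclusion span, and lying entirely in cytoplasmic
topology; regions retaining no motif are reported as candidate non-canonical
binding regions. Every exclusion is logged with the rule that fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fragment_assign import ObservedFragment
from .motif_scan import MotifHit


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class TopologyInterval:
    start: int
    end: int
    compartment: str


COMPARTMENTS = {"cytoplasmic", "transmembrane", "luminal"}


@dataclass(frozen=True)
class TopologyAnnotation:
    """Sidedness of sequence segments relative to the SR membrane.

    Intervals must be non-overlapping; positions not covered by any interval
    default to cytoplasmic.
    """

    intervals: tuple = ()

    def __post_init__(self) -> None:
        ordered = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(ordered[:-1], ordered[1:]):
            if b.start <= a.end:
                raise InferenceError(
                    f"overlapping topology intervals {a.start}-{a.end} and "
                    f"{b.start}-{b.end}"
                )
        for iv in self.intervals:
            if iv.compartment not in COMPARTMENTS:
                raise InferenceError(f"unknown compartment {iv.compartment!r}")
            if iv.start > iv.end or iv.start < 1:
                raise InferenceError(f"bad topology interval {iv.start}-{iv.end}")

    def compartment_of(self, position: int) -> str:
        for iv in self.intervals:
            if iv.start <= position <= iv.end:
                return iv.compartment
        return "cytoplasmic"

    def is_fully_cytoplasmic(self, start: int, end: int) -> bool:
        """True iff *every* position of the span is cytoplasmic."""
        return all(
            self.compartment_of(p) == "cytoplasmic" for p in range(start, end + 1)
        )


@dataclass(frozen=True)
class Exclusion:
    start: int
    end: int
    reason: str


@dataclass(frozen=True)
class ExclusionList:
    exclusions: tuple = ()


@dataclass(frozen=True)
class CandidateRegion:
    start: int
    end: int
    supporting_fragments: tuple = ()


@dataclass(frozen=True)
class AuditEntry:
    subject: str  # e.g. "fragment 7" or "WALKER_A 4602-4607"
    rule: str  # e.g. "R3:demoted", "topology:luminal"
    detail: str = ""


@dataclass
class BindingCallSet:
    """Final inference output: regions, surviving motifs, and the audit."""

    candidate_regions: list = field(default_factory=list)
    candidate_motifs: list = field(default_factory=list)
    noncanonical_regions: list = field(default_factory=list)
    audit_log: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "candidate_regions": [
                {
                    "start": r.start,
                    "end": r.end,
                    "supporting_fragments": list(r.supporting_fragments),
                }
                for r in self.candidate_regions
            ],
            "candidate_motifs": [
                {
                    "pattern_id": h.pattern_id,
                    "start": h.start,
                    "end": h.end,
                    "matched": h.matched,
                }
                for h in self.candidate_motifs
            ],
            "noncanonical_regions": [
                {"start": r.start, "end": r.end} for r in self.noncanonical_regions
            ],
            "audit_log": [
                {"subject": e.subject, "rule": e.rule, "detail": e.detail}
                for e in self.audit_log
            ],
        }


# ---------------------------------------------------------------------------
# interval helpers (1-based inclusive)

def _subtract(intervals, cut):
    """Remove ``cut`` from each interval in the list."""
    cs, ce = cut
    out = []
    for s, e in intervals:
        if ce < s or cs > e:
            out.append((s, e))
            continue
        if s < cs:
            out.append((s, cs - 1))
        if e > ce:
            out.append((ce + 1, e))
    return out


def _merge(intervals):
    """Merge overlapping intervals; input need not be sorted."""
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------

def _fragment_graph(fragments):
    by_id = {f.fragment_id: f for f in fragments}
    if len(by_id) != len(fragments):
        raise InferenceError("duplicate fragment ids")
    children: dict = {fid: [] for fid in by_id}
    for f in fragments:
        if f.parent_id is not None:
            if f.parent_id not in by_id:
                raise InferenceError(
                    f"fragment {f.fragment_id}: unknown parent {f.parent_id}"
                )
            children[f.parent_id].append(f.fragment_id)
    # cycle check by walking parent chains
    for f in fragments:
        seen = set()
        cur = f
        while cur.parent_id is not None:
            if cur.fragment_id in seen:
                raise InferenceError("cyclic derivation graph")
            seen.add(cur.fragment_id)
            cur = by_id[cur.parent_id]
    # containment check where both spans are known
    for f in fragments:
        if f.parent_id is None or f.span is None:
            continue
        parent = by_id[f.parent_id]
        if parent.span is None:
            continue
        (ps, pe), (cs, ce) = parent.span, f.span
        if not (ps <= cs and ce <= pe):
            raise InferenceError(
                f"fragment {f.fragment_id} span {cs}-{ce} not contained in "
                f"parent {parent.fragment_id} span {ps}-{pe}"
            )
    return by_id, children


def _descendants(fid, children):
    stack = list(children[fid])
    out = []
    while stack:
        c = stack.pop()
        out.append(c)
        stack.extend(children[c])
    return out


def refine_regions(
    fragments,
    c_term_window: int = 0,
    demote_on_unlabeled_products: bool = True,
):
    """Apply rules R1-R4 to assigned fragments.

    ``fragments`` are :class:`ObservedFragment` objects carrying ``span``,
    ``labeled`` and ``parent_id``. Returns ``(regions, audit_log)`` where
    regions are :class:`CandidateRegion`, sorted by start. The output does
    not depend on the input order of the fragments.
    """
    fragments = sorted(fragments, key=lambda f: f.fragment_id)
    by_id, children = _fragment_graph(fragments)
    audit: list = []

    demoted = set()
    if demote_on_unlabeled_products:
        for f in fragments:
            kids = children[f.fragment_id]
            if f.labeled and kids and all(not by_id[k].labeled for k in kids):
                demoted.add(f.fragment_id)
                audit.append(
                    AuditEntry(
                        subject=f"fragment {f.fragment_id}",
                        rule="R3:demoted",
                        detail="all direct products unlabeled: "
                        + ",".join(sorted(kids)),
                    )
                )

    roots = [
        f
        for f in fragments
        if f.labeled and (f.parent_id is None or f.parent_id not in by_id)
    ]

    pieces = []  # (interval, supporting ids)
    for root in roots:
        if root.fragment_id in demoted:
            continue
        if root.span is None:
            raise InferenceError(
                f"labeled root fragment {root.fragment_id} has no span"
            )
        desc_ids = _descendants(root.fragment_id, children)
        labeled_desc = [
            by_id[d]
            for d in desc_ids
            if by_id[d].labeled and d not in demoted and by_id[d].span is not None
        ]
        # deepest labeled descendants: those with no labeled (non-demoted,
        # spanned) descendants of their own
        deepest = [
            d
            for d in labeled_desc
            if not any(
                by_id[x].labeled and x not in demoted and by_id[x].span is not None
                for x in _descendants(d.fragment_id, children)
            )
        ]
        if deepest:
            base = []
            for d in deepest:
                base.append((d.span, (root.fragment_id, d.fragment_id)))
                audit.append(
                    AuditEntry(
                        subject=f"fragment {root.fragment_id}",
                        rule="R1:intersect",
                        detail=f"narrowed to labeled product "
                        f"{d.fragment_id} span {d.span[0]}-{d.span[1]}",
                    )
                )
        else:
            base = [(root.span, (root.fragment_id,))]

        unlabeled_spans = [
            (by_id[d].span, d)
            for d in desc_ids
            if not by_id[d].labeled and by_id[d].span is not None
        ]
        for (interval, support) in base:
            remaining = [interval]
            for (us, ue), uid in unlabeled_spans:
                shrunk_end = ue - c_term_window
                if shrunk_end < us:
                    continue
                before = list(remaining)
                remaining = _subtract(remaining, (us, shrunk_end))
                if remaining != before:
                    audit.append(
                        AuditEntry(
                            subject=f"fragment {root.fragment_id}",
                            rule="R2:subtract",
                            detail=f"removed unlabeled product {uid} span "
                            f"{us}-{shrunk_end}",
                        )
                    )
            for piece in remaining:
                pieces.append((piece, support))

    merged = _merge([iv for iv, _ in pieces])
    regions = []
    for s, e in merged:
        support: set = set()
        contributing = [
            (iv, sup) for iv, sup in pieces if not (iv[1] < s or iv[0] > e)
        ]
        for _, sup in contributing:
            support.update(sup)
        if len(contributing) > 1:
            audit.append(
                AuditEntry(
                    subject=f"region {s}-{e}",
                    rule="R4:merge",
                    detail="merged overlapping refined regions",
                )
            )
        regions.append(
            CandidateRegion(start=s, end=e, supporting_fragments=tuple(sorted(support)))
        )
    regions.sort(key=lambda r: r.start)
    return regions, audit


def filter_motifs(
    hits,
    regions,
    topology: TopologyAnnotation | None = None,
    exclusions: ExclusionList | None = None,
    audit_log=None,
) -> BindingCallSet:
    """Filter scanned motif hits through the candidate regions.

    A hit survives iff it is fully contained in a candidate region, does not
    overlap any exclusion span, and every one of its positions is
    cytoplasmic. Dropped hits are logged with the rule that dropped them.
    Regions left without any surviving motif become non-canonical candidate
    regions.
    """
    topology = topology or TopologyAnnotation()
    exclusions = exclusions or ExclusionList()
    audit = list(audit_log) if audit_log else []
    surviving: list = []
    per_region: dict = {(r.start, r.end): 0 for r in regions}

    for hit in sorted(hits, key=lambda h: (h.start, h.pattern_id)):
        subject = f"{hit.pattern_id} {hit.start}-{hit.end}"
        container = next(
            (r for r in regions if r.start <= hit.start and hit.end <= r.end), None
        )
        if container is None:
            audit.append(
                AuditEntry(subject=subject, rule="not_contained",
                           detail="no candidate region fully contains this hit")
            )
            continue
        excl = next(
            (
                x
                for x in exclusions.exclusions
                if not (x.end < hit.start or x.start > hit.end)
            ),
            None,
        )
        if excl is not None:
            audit.append(
                AuditEntry(
                    subject=subject,
                    rule=f"excluded:{excl.reason}",
                    detail=f"overlaps exclusion span {excl.start}-{excl.end}",
                )
            )
            continue
        if not topology.is_fully_cytoplasmic(hit.start, hit.end):
            compartments = sorted(
                {
                    topology.compartment_of(p)
                    for p in range(hit.start, hit.end + 1)
                }
                - {"cytoplasmic"}
            )
            audit.append(
                AuditEntry(
                    subject=subject,
                    rule="topology:" + ",".join(compartments),
                    detail="hit not fully cytoplasmic",
                )
            )
            continue
        surviving.append(hit)
        per_region[(container.start, container.end)] += 1

    noncanonical = [r for r in regions if per_region[(r.start, r.end)] == 0]
    for r in noncanonical:
        audit.append(
            AuditEntry(
                subject=f"region {r.start}-{r.end}",
                rule="noncanonical",
                detail="labeled region retains no consensus motif",
            )
        )
    return BindingCallSet(
        candidate_regions=list(regions),
        candidate_motifs=surviving,
        noncanonical_regions=noncanonical,
        audit_log=audit,
    )


# ---------------------------------------------------------------------------
# Tabular I/O

def read_topology_tsv(path) -> TopologyAnnotation:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return TopologyAnnotation(
        intervals=tuple(
            TopologyInterval(int(r.start), int(r.end), str(r.compartment))
            for r in df.itertuples()
        )
    )


def read_exclusions_tsv(path) -> ExclusionList:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return ExclusionList(
        exclusions=tuple(
            Exclusion(int(r.start), int(r.end), str(r.reason)) for r in df.itertuples()
        )
    )
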