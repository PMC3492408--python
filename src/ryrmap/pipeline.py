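"""End-to-end orchestration: observations -> assignments -> binding calls."""

from __future__ import annotations

from dataclasses import replace

from .digest import cleavage_sites
from .fragment_assign import (
    ObservedFragment,
    assign_c_terminus,
    locate_n_terminus,
)
from .labeling_inference import (
    ExclusionList,
    TopologyAnnotation,
    filter_motifs,
    refine_regions,
)
from .motif_scan import builtin_patterns, scan
from .sequence_io import ProteinSequence


class PipelineError(ValueError):
    pass


def assign_fragments(
    seq: ProteinSequence,
    fragments,
    tolerance: float = 0.15,
    min_read_length: int = 5,
    strict_junctions: bool = True,
) -> list[ObservedFragment]:
    """Fill in spans for observed fragments that lack them.

    Fragments carrying a fixed span (externally assigned, e.g. read-less
    bands identified by antibody) are passed through. For the rest, the
    N-terminus is anchored from the Edman read; if several starts match, or
    if several C-terminal candidates tie within tolerance, the rank-1
    assignment at the first matching start is taken and the ambiguity left
    to the caller's audit (use the lower-level API for full candidate
    lists). Fragments with neither span nor read are passed through
    unassigned.
    """
    cmap = cleavage_sites(seq)
    out = []
    for frag in fragments:
        if frag.span is not None or not frag.has_read:
            out.append(frag)
            continue
        if frag.apparent_kda is None:
            raise PipelineError(
                f"fragment {frag.fragment_id}: read but no apparent mass"
            )
        starts = locate_n_terminus(
            seq,
            frag.nterm_read,
            min_length=min_read_length,
            require_cleavage_junction=strict_junctions,
            cmap=cmap,
        )
        candidates = assign_c_terminus(
            seq,
            starts[0],
            frag.apparent_kda,
            cmap,
            tolerance=tolerance,
            fragment_id=frag.fragment_id,
        )
        best = candidates[0]
        out.append(replace(frag, span=(best.start, best.end)))
    return out


def run_inference(
    seq: ProteinSequence,
    fragments,
    topology: TopologyAnnotation | None = None,
    exclusions: ExclusionList | None = None,
    tolerance: float = 0.15,
    c_term_window: int = 0,
    demote_on_unlabeled_products: bool = True,
    patterns=None,
):
    """scan -> assign -> refine -> filter; returns a BindingCallSet."""
    assigned = assign_fragments(seq, fragments, tolerance=tolerance)
    # span-less fragments still matter when they are somebody's proteolytic
    # product: their label flag drives the R3 demotion rule
    spanned = [
        f for f in assigned if f.span is not None or f.parent_id is not None
    ]
    regions, audit = refine_regions(
        spanned,
        c_term_window=c_term_window,
        demote_on_unlabeled_products=demote_on_unlabeled_products,
    )
    hits = scan(seq, patterns if patterns is not None else builtin_patterns())
    return filter_motifs(
        hits, regions, topology=topology, exclusions=exclusions, audit_log=audit
    )
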