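"""Loaders for the packaged study fixture.

The fixture ships everything the source study prints as data: the observed
fragment table (apparent masses, Edman reads, assigned spans, label flags,
parentage), the published motif locations, the membrane-topology intervals,
and the mutagenesis exclusion list. It does *not* include the real RyR1
sequence record; analyses of the real protein take a user-supplied FASTA,
and :mod:`ryrmap.synthetic_scaffold` provides a synthetic stand-in sequence
consistent with all of the printed constraints for self-contained testing.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .fragment_assign import ObservedFragment, read_fragments_tsv
from .labeling_inference import (
    ExclusionList,
    TopologyAnnotation,
    read_exclusions_tsv,
    read_topology_tsv,
)


def data_path(name: str):
    return importlib.resources.files("ryrmap") / "data" / name


def published_fragments(protein: str = "RyR1") -> list[ObservedFragment]:
    """Observed fragments of the study fixture, filtered by source protein.

    Pass ``protein=None`` for every row (including the SERCA and
    calsequestrin contaminant bands and the unidentifiable 30-kDa band).
    """
    with importlib.resources.as_file(data_path("observed_fragments.tsv")) as p:
        fragments = read_fragments_tsv(p)
        frame = pd.read_csv(p, sep="\t", comment="#", dtype=str).fillna("")
    keep = []
    for frag, (_, row) in zip(fragments, frame.iterrows()):
        if protein is None or row["protein"] == protein:
            keep.append(frag)
    return keep


def published_fragment_table() -> pd.DataFrame:
    """The raw fixture fragment table as a DataFrame."""
    with importlib.resources.as_file(data_path("observed_fragments.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str).fillna("")


def published_motif_spans() -> pd.DataFrame:
    """Published motif spans: columns pattern_id, start, end."""
    with importlib.resources.as_file(data_path("motif_spans.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def published_topology() -> TopologyAnnotation:
    with importlib.resources.as_file(data_path("topology.tsv")) as p:
        return read_topology_tsv(p)


def published_exclusions() -> ExclusionList:
    with importlib.resources.as_file(data_path("exclusions.tsv")) as p:
        return read_exclusions_tsv(p)
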