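# ryrmap

Mapping photoaffinity-crosslinked proteolytic fragments of the skeletal-muscle
ryanodine receptor (RyR1) onto its primary sequence, and calling candidate
ATP-binding regions.

## The problem

RyR1 is a ~5037-residue, tetrameric Ca²⁺ release channel of the sarcoplasmic
reticulum whose gating is modulated by millimolar ATP. One classic way to
localize nucleotide-binding sites on such a large membrane protein is
photoaffinity labeling: a photo-reactive, biotin-tagged ATP analog is
crosslinked into its binding site under UV light, the protein is cut into
large fragments by limited tryptic proteolysis, and the fragments that carry
the biotin tag (detected by streptavidin fluorescence) are mapped back onto
the sequence via their Edman N-terminal reads and SDS-PAGE masses. Crossing
the labeled intervals with glycine-rich nucleotide-binding consensus motifs —
Walker-A `GXGXXG`, partial Walker-B `[R/K]XXXGXXXL`, and the GroES-type
4-mer `Y[G/A/S/T][V/G][K/T/Q/S/N]` — then yields a short list of candidate
ATP-binding motifs.

`ryrmap` implements that entire computational chain as a tested library +
CLI:

* **sequence_io** — FASTA I/O and average-mass arithmetic (Expasy residue
  masses, 1-based inclusive coordinates).
* **motif_scan** — fixed-length PROSITE-style patterns; exhaustive scanning
  that reports *all* (including overlapping) hits.
* **digest** — Keil-rule tryptic cleavage prediction and complete digestion.
* **fragment_assign** — anchoring of Edman reads (with ambiguity codes) at
  cleavage junctions and ranked C-terminal assignment by apparent-vs-
  calculated mass (default tolerance 15%).
* **labeling_inference** — the core call: labeled/unlabeled fragments and
  their precursor relations refine candidate regions (narrow to labeled
  products, subtract unlabeled ones, demote fragments whose products all
  lost the label, merge overlaps); motif hits are then filtered by region
  containment, mutagenesis exclusions, and membrane topology (a motif must
  be entirely cytoplasmic). Every exclusion is logged in an audit trail.
* **binding_quant** — two-channel densitometry normalization
  `y = (F − F₀)/F_max` and one-site competition fitting
  `y = 1/(1 + (c/IC50)^h)` by nonlinear least squares.
* **synthetic_data** — a generator for proteins with planted motifs and
  binding sites, noisy partial digests, and competition curves, so every
  stage is testable without downloads.

Because the real Swiss-Prot P11716 record cannot be redistributed here, the
package ships a deterministic **synthetic scaffold** sequence
(`ryrmap.synthetic_scaffold`) that satisfies every published sequence-level
constraint (read anchors, fragment boundaries, motif locations, fragment
masses); pass your own FASTA to analyze the real protein.

## Worked example

Run the full inference on the packaged study fixture (fragment table,
topology, exclusion list) against the scaffold sequence:

```bash
ryrmap infer --scaffold --out calls.json
```

`calls.json` contains (abridged):

```json
{
 "candidate_regions": [
  {"start": 427,  "end": 1302, "supporting_fragments": ["3", "8"]},
  {"start": 2402, "end": 2795, "supporting_fragments": ["15"]},
  {"start": 4476, "end": 5037, "supporting_fragments": ["1", "11", "6"]}
 ],
 "candidate_motifs": [
  {"pattern_id": "WALKER_A", "start": 699,  "end": 704},
  {"pattern_id": "WALKER_A", "start": 701,  "end": 706},
  {"pattern_id": "GROES",    "start": 1081, "end": 1084},
  {"pattern_id": "WALKER_A", "start": 1195, "end": 1200}
 ],
 "noncanonical_regions": [
  {"start": 2402, "end": 2795},
  {"start": 4476, "end": 5037}
 ]
}
```

Three labeled regions survive the fragment-evidence rules; only the
N-terminal region 427–1302 retains consensus motifs (the overlapping
Walker-A pair 699–704/701–706, the GroES 4-mer 1081–1084, and Walker-A
1195–1200). The other two regions bind the probe but contain no surviving
motif — candidate non-canonical ATP-binding regions: in region 4476–5037 the
single consensus motif (4602–4607) is discarded because it faces the SR
lumen. The `audit_log` field names the rule behind every exclusion, e.g. the
102-kDa fragment (1509–2399) is demoted because both of its proteolytic
products lost the label.

Other subcommands: `ryrmap scan`, `digest`, `assign`, `fit`, `simulate`
(see `--help`).

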