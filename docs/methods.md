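# Methods

This note documents the models, conventions, and design choices behind
`ryrmap`, in the spirit of a methods appendix: what each stage assumes, which
knobs matter, and what the synthetic machinery does and does not emulate.

## Coordinates, masses, rounding

All coordinates are 1-based and inclusive ("amino acids 427–1302" means both
endpoints are part of the span). Peptide masses are *average* (isotope-
abundance-weighted) masses: the sum of Expasy average residue masses plus one
water (18.01524 Da). Average rather than monoisotopic masses are the right
convention at the 45–180 kDa fragment scale of SDS-PAGE work; monoisotopic
arithmetic would differ by >0.06% at these sizes and does not correspond to
anything a gel measures. The mass table ships as a TSV
(`ryrmap/data/average_masses.tsv`) so the convention is auditable and
swappable. Masses are reported in integer kDa using half-up rounding; the
published fragment table prints integer kDa, and agreement within ±1 kDa is
the honest comparison bar since the original mass table and rounding rule
are not stated. Unknown residues (`X`) are illegal inside a mass span unless
the caller supplies a fallback mass (e.g. the mean residue mass); silently
guessing would bias long spans.

## Consensus-motif scanning

The three built-in nucleotide-binding patterns are fixed-length PROSITE-style
consensi: Walker-A `GXGXXG` (6), partial Walker-B `[R/K]XXXGXXXL` (9), and
the GroES-type `Y[G/A/S/T][V/G][K/T/Q/S/N]` (4). Only the fixed-length
subset of the PROSITE dialect is supported (no variable-length `x(2,4)`
ranges) — all three patterns are fixed-length, and keeping the matcher
window-exhaustive makes its semantics trivial to verify: every window of
every pattern length is tested, so mutually overlapping hits (e.g. two
Walker-A instances two residues apart) are all reported, and nothing is
deduplicated — containment decisions belong to the inference stage. An `X`
in the *sequence* matches nothing by default (it is an unknown residue, not
a wildcard); a permissive flag exists for deliberately loose matching of
Edman reads. The scanner is tested against an independent lookahead-regex
oracle on ~1000 random sequences.

## Digestion

Trypsin uses the standard Keil rule: cleave C-terminal to K or R unless the
next residue is P. The rule is data (a registered `CleavageRule`), so other
specificities can be added without touching the digestion code. A complete
digest (every site cut) is the generative primitive; the 5–10 minute limited
proteolysis that actually produced the observed bands is represented
downstream by admitting *any* span whose boundaries are cleavage sites or
protein termini as an observable fragment.

## Fragment assignment

An observed fragment is a gel band: an apparent SDS-PAGE mass plus an Edman
N-terminal read in the source notation (`(A)` low-confidence call, `X`
unidentified cycle, `-` skipped cycle, `ND` no read). Low-confidence calls
are treated as wildcards — parenthesized calls in the source tables are
sometimes wrong, and treating them as exact would mislocate reads. Anchoring
requires at least 5 confident cycles (configurable) and, in the default
strict mode, a predicted cleavage junction (position 1 or preceded by an
unblocked K/R).

The C-terminus is chosen among all cleavage sites at or beyond the start
plus the protein terminus, keeping candidates whose calculated mass is
within a relative tolerance of the apparent mass (default **0.15**: observed
apparent-vs-calculated discrepancies in this kind of data reach ~9%, so a
10% tolerance would already be too tight) and ranking them by mass error,
ties broken toward the larger fragment. The result is deliberately a
*ranked list*, not a single answer: gel masses cannot discriminate between
cleavage sites a few residues apart, and the original analysis resolved such
ambiguities with prior knowledge. Read-less fragments (N-terminal blockage)
are supported by fixed, externally supplied spans.

Under limited proteolysis — roughly a dozen major sites across a
5000-residue protein — the true C-terminus lands in the tolerance-0.15
candidate list in ≳99% of 5%-mass-noise replicates and ranks first in >90%
(the in-list rate is not literally 1: a 5%-σ lognormal factor exceeds 15%
with probability ~0.3% per draw). Against a *complete* site map the rank-1
rate drops sharply, because neighboring candidates then differ by ~1 kDa;
this is a property of gel resolution, not of the algorithm, and is why the
ranked-list contract exists.

## Region inference

Per labeled root fragment (no precursor among the observations), four rules:

* **R1 — narrow.** If labeled proteolytic products exist, the region
  narrows to each deepest labeled product's span: the covalent label must
  reside within every labeled descendant.
* **R2 — subtract.** Spans of unlabeled products are removed: a bound probe
  cannot lie in a sequence whose fragment shows no label. Each subtracted
  span is first shrunk at its C-terminus by an ambiguity window `w`
  (default 0; ~20 residues is a reasonable setting when cleavage sites
  cluster near fragment C-termini, making that boundary soft).
* **R3 — demote.** A labeled fragment *all* of whose direct products are
  unlabeled is dropped: the label apparently vanished on further digestion,
  so its position cannot be corroborated. This encodes the treatment of the
  102-kDa central fragment, whose two products both lost the label. The rule
  is flag-controlled (`--demote-on-unlabeled-products`, default on) because
  label loss during digestion is a plausible alternative reading — the
  evidence is genuinely equivocal.
* **R4 — merge.** Overlapping surviving regions merge (e.g. the refined
  remnant 4476–4673 of the C-terminal precursor fragments merges into the
  directly observed 4476–5037).

Motif filtering then requires (i) strict containment of a hit in a candidate
region — a hit straddling a region boundary, like the Walker-B instance at
1302–1310 across the 1302 fragment end, is excluded; (ii) no overlap with a
mutagenesis-excluded span; (iii) *every* hit position cytoplasmic, which is
what removes the consensus motif on the luminal face of the transmembrane
assembly. Regions retaining no motif are reported as candidate non-canonical
binding regions, not discarded — probe binding there is evidence regardless
of consensus motifs. Every dropped hit and every fired rule lands in an
audit log, and the output is independent of the input order of fragments.

Two semantic consequences worth knowing. First, R2 can split a labeled span
into disconnected remnants, only one of which can contain a single true
binding site; both remnants remain candidates because the evidence cannot
say which. Second, R3 sacrifices soundness for skepticism: in a
zero-noise/zero-false-negative world, a labeled fragment whose sampled
products happen to all miss the binding site would be wrongly demoted, so
the end-to-end soundness property (every planted site inside some candidate
region) is guaranteed only with demotion off — which is how it is tested.
With labels driven by several distinct sites, R1 can also narrow away a site
held only by the precursor; soundness statements here assume one site per
derivation chain. Missing observations contribute nothing: a never-observed
region (like an undetected N-terminal 47-kDa piece) yields no candidate
region, because absence of evidence is not support.

## Competition-binding quantification

Specific probe binding per band is the two-channel ratio difference
`(F800/F700)_noATP − (F800/F700)_ATP` (streptavidin fluorescence over
total-protein stain, competitor lane subtracted); negative values are
reported but flagged, since they indicate normalization or lane-matching
problems. Curves are normalized as `y = (F − F0)/Fmax`; when raw lanes are
supplied, `F0` is taken from no-UV background lanes if present (otherwise
the minimum-signal lane) and `Fmax` from the crosslinked no-competitor
lanes.

The competition model is a one-site law `y = 1/(1 + (c/IC50)^h)` fitted by
unweighted nonlinear least squares with the Hill slope fixed at 1 by default
(a free-slope variant is a flag away). The starting IC50 is the geometric
mean of the non-zero concentrations, making the fit deterministic for given
data; the standard error comes from the fit covariance; non-convergence and
flat curves raise explicit errors. Unweighted least squares is the default
because no error model for the densitometry is available; replicate-SEM
weighting can be layered on by averaging replicates beforehand.

One statistical limitation is documented rather than papered over: with
additive noise σ = 0.05, 8 log-spaced concentrations and 3 replicates, the
Cramér–Rao bound for the IC50 standard error at a truth of 0.95 mM over
0.01–50 mM is ≈0.074 mM (the least-squares fit achieves ≈0.067). A ±0.1 mM
window is therefore only ~1.5 standard errors wide, and no estimator can
land inside it much more than ~87% of the time; the corresponding recovery
test records this as an expected shortfall. The ±0.2 mM window at 0.6 mM is
~5 standard errors and recovery there is essentially certain.

## Synthetic-data generator

The generator mirrors the observation process of the experiment, stage by
stage, under one seeded RNG:

* random protein from SwissProt-like (or uniform, or user-supplied) residue
  frequencies, default length 5037 — the scale of one channel subunit;
* planted motif instances overwrite residues at stated positions (wildcard
  positions keep the background draw) and are verified against their
  pattern; contradictory overlapping plants are an error;
* partial digests: ~8 observed spans per run with cleavage-site boundaries;
  apparent mass = calculated mass × exp(ε), ε ~ N(0, σ) with σ = 0.05 —
  multiplicative lognormal noise models SDS-PAGE mobility error, whose
  observed discrepancies are proportional (3–9%); 10-cycle Edman reads with
  a 5% per-cycle miscall rate (miscalls become `X` or a parenthesized
  wrong call); labels driven by planted-site containment with an optional
  false-negative rate (a fragment containing *any* site is labeled);
* competition curves `y = 1/(1+(c/IC50)^h) + N(0, 0.05)` per replicate,
  with presets at 0.6 mM (0.01–10 mM range) and 0.95 mM (0.01–50 mM range),
  8 log-spaced concentrations, 3 replicates.

What it does **not** emulate: gel-mobility anomalies (glycosylation, SDS
binding artifacts), co-migrating bands, incomplete transfer, Edman failure
modes beyond per-cycle ambiguity, cooperative or multi-site competition
binding, and any kinetics of the crosslinking chemistry. Passing tests on
synthetic data therefore validate the *computational* chain under the stated
noise model, not the wet-lab robustness of the original measurements.

## The synthetic scaffold

The real P11716 sequence record is not redistributed with the package, so
self-contained validation uses a deterministic synthetic scaffold
(`synthetic_scaffold.py`): a 5037-residue sequence built from a fixed-seed
SwissProt-frequency background and then constrained so that every published
sequence-level fact holds — the six Edman reads occur verbatim at their
assigned starts and nowhere else; every assigned fragment boundary is a
tryptic junction; the three consensus patterns match at exactly the sixteen
published motif spans and nowhere else; and the average mass of every
assigned span reproduces the printed integer-kDa value (block mass targets
are derived from the printed values by minimum-norm least squares and met by
residue swaps confined to non-anchor residues). Construction alternates
repair passes (destroy accidental motif hits / duplicate read matches) with
mass-tuning passes until stable, then verifies all constraints.

Where the published record itself is internally inconsistent (a figure
caption printing 2126–2234 and 4449–4452 where the running text prints
2126–2134 and 4449–4454), the spans whose lengths match their pattern
lengths are used. Results on the scaffold validate the pipeline's
computations; they say nothing about the identity of the real RyR1 residues,
and any claim about the real protein should be re-run with a user-supplied
FASTA.

## Problem sizes in the test suite

The suite favors sizes that exercise the mathematics without waste: oracle
equivalence on 1000 random sequences of ≤200 residues; digestion invariants
on 1000 random sequences; 500-replicate mass-noise recovery on a
5000-residue sparse-site protein; 200-replicate IC50 recovery per preset;
100-seed zero-noise end-to-end soundness on 1200-residue proteins. The whole
suite runs in well under a minute.
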