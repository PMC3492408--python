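"""Synthetic-data generation mirroring the photoaffinity-labeling study design.

The generator emulates the observation process of the experiment: a large
membrane-protein sequence with planted consensus motifs and planted
ATP-binding sites; limited tryptic proteolysis observed as gel bands with
multiplicative (lognormal) mass error and noisy Edman N-terminal reads;
label flags driven by whether a fragment's span contains a planted site
(with an optional false-negative rate); and competition-binding curves
y = 1/(1 + (c/IC50)^h) with additive Gaussian noise.

Defaults reproduce the study conditions: a 5037-residue subunit, ~8 observed
fragments per digest, 5% multiplicative mass noise (the experiment's
apparent-vs-calculated discrepancies run 3-9%), 10-cycle Edman reads, and
competition presets of IC50 = 0.6 mM over 0.01-10 mM ATP (SR membranes) and
0.95 mM over 0.01-50 mM (purified receptor), 8 log-spaced concentrations,
noise sigma 0.05, 3 replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .binding_quant import CompetitionCurve
from .digest import cleavage_sites
from .fragment_assign import ObservedFragment
from .motif_scan import builtin_patterns
from .sequence_io import (
    STANDARD_RESIDUES,
    ProteinSequence,
    round_kda,
    segment_mass,
    write_fasta,
)


class SimulationError(ValueError):
    pass


#: Approximate SwissProt-wide residue frequencies.
SWISSPROT_FREQUENCIES = {
    "A": 0.0826, "Q": 0.0393, "L": 0.0965, "S": 0.0660,
    "R": 0.0553, "E": 0.0672, "K": 0.0580, "T": 0.0535,
    "N": 0.0406, "G": 0.0708, "M": 0.0241, "W": 0.0110,
    "D": 0.0546, "H": 0.0227, "F": 0.0386, "Y": 0.0292,
    "C": 0.0138, "I": 0.0591, "P": 0.0472, "V": 0.0686,
}

#: Competition presets: true IC50 (mM) and ATP concentration range (mM).
IC50_SR_MEMBRANES = 0.6
IC50_PURIFIED = 0.95
CONC_RANGE_SR_MEMBRANES = (0.01, 10.0)
CONC_RANGE_PURIFIED = (0.01, 50.0)


def log_spaced(lo: float, hi: float, n: int = 8) -> tuple:
    return tuple(float(c) for c in np.geomspace(lo, hi, n))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; a fixed seed gives identical output."""

    seed: int = 0
    length: int = 5037
    #: "swissprot", "uniform", or a {residue: weight} mapping
    residue_frequencies: object = "swissprot"
    planted_motifs: tuple = ()  # (pattern_id, start)
    planted_sites: tuple = ()  # binding-site positions
    n_fragments: int = 8
    mass_noise_sigma: float = 0.05
    edman_read_length: int = 10
    miscall_rate: float = 0.05
    label_false_negative_rate: float = 0.0
    ic50_true_mM: float = IC50_SR_MEMBRANES
    hill: float = 1.0
    concentrations_mM: tuple = log_spaced(*CONC_RANGE_SR_MEMBRANES)
    curve_noise_sigma: float = 0.05
    curve_replicates: int = 3

    def __post_init__(self) -> None:
        for p in (self.miscall_rate, self.label_false_negative_rate):
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"probability out of [0,1]: {p}")
        for _, pos in self.planted_motifs:
            if not (1 <= pos <= self.length):
                raise SimulationError(f"planted motif position {pos} out of range")
        for pos in self.planted_sites:
            if not (1 <= pos <= self.length):
                raise SimulationError(f"planted site {pos} out of range")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What the generator actually planted and drew."""

    planted_motifs: tuple = ()
    planted_sites: tuple = ()
    true_spans: dict = field(default_factory=dict)  # fragment_id -> (start, end)
    true_labels: dict = field(default_factory=dict)  # fragment_id -> bool
    ic50_true_mM: float | None = None
    hill: float | None = None

    def to_dict(self) -> dict:
        return {
            "planted_motifs": [list(pm) for pm in self.planted_motifs],
            "planted_sites": list(self.planted_sites),
            "true_spans": {k: list(v) for k, v in self.true_spans.items()},
            "true_labels": dict(self.true_labels),
            "ic50_true_mM": self.ic50_true_mM,
            "hill": self.hill,
        }


def _frequencies(config: SimulationConfig):
    if isinstance(config.residue_frequencies, dict):
        freqs = config.residue_frequencies
        if any(r not in STANDARD_RESIDUES for r in freqs):
            raise SimulationError("frequency table has non-standard residues")
    elif config.residue_frequencies == "uniform":
        freqs = {r: 1.0 / 20.0 for r in STANDARD_RESIDUES}
    elif config.residue_frequencies == "swissprot":
        freqs = SWISSPROT_FREQUENCIES
    else:
        raise SimulationError(
            f"unknown frequency table {config.residue_frequencies!r}"
        )
    letters = sorted(freqs)
    probs = np.array([freqs[r] for r in letters], dtype=float)
    return letters, probs / probs.sum()


def simulate_protein(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Random protein with planted motif instances.

    Planted instances overwrite residues at their stated positions (wildcard
    positions keep the background draw) and are verified to match their
    pattern; overlapping plants with contradictory residue requirements raise
    :class:`SimulationError`.
    """
    rng = rng or np.random.default_rng(config.seed)
    letters, probs = _frequencies(config)
    residues = list(rng.choice(letters, size=config.length, p=probs))
    patterns = builtin_patterns()

    fixed: dict = {}
    for pattern_id, start in config.planted_motifs:
        if pattern_id not in patterns:
            raise SimulationError(f"unknown pattern id {pattern_id!r}")
        pattern = patterns[pattern_id]
        if start + pattern.length - 1 > config.length:
            raise SimulationError(
                f"planted {pattern_id} at {start} exceeds sequence length"
            )
        for offset, element in enumerate(pattern.elements):
            pos = start + offset
            if element is None:
                continue
            if pos in fixed:
                if fixed[pos] not in element:
                    raise SimulationError(
                        f"motif collision at position {pos}: {fixed[pos]!r} "
                        f"conflicts with {pattern_id}"
                    )
                continue
            choice = (
                next(iter(element))
                if len(element) == 1
                else str(rng.choice(sorted(element)))
            )
            fixed[pos] = choice
    for pos, residue in fixed.items():
        residues[pos - 1] = residue

    seq = ProteinSequence(id=f"synthetic-{config.seed}", residues="".join(residues))
    for pattern_id, start in config.planted_motifs:
        pattern = patterns[pattern_id]
        window = seq.segment(start, start + pattern.length - 1)
        if not pattern.matches(window):
            raise SimulationError(
                f"planted {pattern_id} at {start} does not match: {window!r}"
            )
    truth = GroundTruth(
        planted_motifs=tuple(config.planted_motifs),
        planted_sites=tuple(config.planted_sites),
    )
    return seq, truth


def simulate_observed_fragments(
    seq: ProteinSequence,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Sample a partial digest and its noisy gel/Edman observations.

    Fragment spans have cleavage-site (or terminus) boundaries. The apparent
    mass is the calculated mass times a lognormal factor exp(eps),
    eps ~ N(0, sigma). The Edman read is the true N-terminal prefix with
    seeded miscalls turned into 'X' or a parenthesized (low-confidence) call.
    A fragment is labeled iff its span contains a planted site, subject to a
    seeded false-negative rate. Parentage is emitted whenever one sampled
    span strictly contains another. Updates ``truth`` in place with the true
    spans and labels and returns the observed fragments.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    cmap = cleavage_sites(seq)
    boundaries = [0, *cmap.sites, seq.length]
    if len(boundaries) < 3:
        raise SimulationError("sequence has no cleavage sites to sample spans from")

    spans: list = []
    attempts = 0
    while len(spans) < config.n_fragments and attempts < 200 * config.n_fragments:
        attempts += 1
        a, b = sorted(rng.choice(len(boundaries), size=2, replace=False))
        start, end = boundaries[a] + 1, boundaries[b]
        if end - start + 1 < config.edman_read_length:
            continue
        if (start, end) in spans:
            continue
        spans.append((start, end))
    spans.sort(key=lambda se: (se[0] - se[1], se[0]))  # larger spans first

    parents: dict = {}
    for i, (s, e) in enumerate(spans):
        best = None
        for j, (ps, pe) in enumerate(spans):
            if j == i or not (ps <= s and e <= pe) or (ps, pe) == (s, e):
                continue
            if best is None or (pe - ps) < (spans[best][1] - spans[best][0]):
                best = j
        parents[i] = best

    fragments = []
    for i, (start, end) in enumerate(spans):
        fid = f"sf{i + 1}"
        calc_kda = segment_mass(seq, start, end) / 1000.0
        apparent = calc_kda * float(
            np.exp(rng.normal(0.0, config.mass_noise_sigma))
        )
        read_len = min(config.edman_read_length, end - start + 1)
        read_chars = []
        for offset in range(read_len):
            true_res = seq.residues[start - 1 + offset]
            if rng.random() < config.miscall_rate:
                if rng.random() < 0.5:
                    read_chars.append("X")
                else:
                    read_chars.append(f"({rng.choice(list(STANDARD_RESIDUES))})")
            else:
                read_chars.append(true_res)
        contains_site = any(start <= p <= end for p in truth.planted_sites)
        labeled = contains_site
        if contains_site and rng.random() < config.label_false_negative_rate:
            labeled = False
        fragments.append(
            ObservedFragment(
                fragment_id=fid,
                apparent_kda=round(apparent, 3),
                nterm_read="".join(read_chars),
                labeled=labeled,
                parent_id=f"sf{parents[i] + 1}" if parents[i] is not None else None,
            )
        )
        truth.true_spans[fid] = (start, end)
        truth.true_labels[fid] = labeled
    return fragments


def simulate_curve(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Seeded competition curve: y = 1/(1+(c/IC50)^h) + N(0, sigma)."""
    conc = tuple(config.concentrations_mM)
    if len(set(conc)) < 4 or any(c <= 0 for c in conc):
        raise SimulationError("need >= 4 distinct positive concentrations")
    rng = rng or np.random.default_rng(config.seed + 2)
    xs, ys, reps = [], [], []
    for rep in range(config.curve_replicates):
        for c in conc:
            model = 1.0 / (1.0 + (c / config.ic50_true_mM) ** config.hill)
            noise = (
                float(rng.normal(0.0, config.curve_noise_sigma))
                if config.curve_noise_sigma > 0
                else 0.0
            )
            xs.append(c)
            ys.append(model + noise)
            reps.append(rep)
    truth = GroundTruth(ic50_true_mM=config.ic50_true_mM, hill=config.hill)
    return CompetitionCurve(atp_mM=tuple(xs), y=tuple(ys), replicate=tuple(reps)), truth


def write_fixture(outdir, config: SimulationConfig) -> GroundTruth:
    """Emit a complete synthetic fixture directory.

    Writes protein.fasta, fragments.tsv, densitometry.tsv and
    ground_truth.json, all derived from ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seq, truth = simulate_protein(config, rng=rng)
    fragments = simulate_observed_fragments(seq, truth, config, rng=rng)
    curve, curve_truth = simulate_curve(config, rng=rng)
    truth.ic50_true_mM = curve_truth.ic50_true_mM
    truth.hill = curve_truth.hill

    write_fasta([seq], outdir / "protein.fasta")

    with open(outdir / "fragments.tsv", "w") as fh:
        fh.write("fragment_id\tapparent_kda\tnterm_read\tlabeled\tparent_id\n")
        for f in fragments:
            fh.write(
                f"{f.fragment_id}\t{f.apparent_kda}\t{f.nterm_read}\t"
                f"{int(f.labeled)}\t{f.parent_id or ''}\n"
            )

    # raw two-channel lanes consistent with the normalized curve: one no-UV
    # background lane, one zero-ATP (Fmax) lane per replicate, then the
    # competition lanes
    f700, f0_raw, fmax_raw = 400.0, 40.0, 800.0
    with open(outdir / "densitometry.tsv", "w") as fh:
        fh.write("lane\tatp_mM\tF800\tF700\tplus_crosslinker\n")
        fh.write(f"background\t0\t{f0_raw:.4f}\t{f700:.1f}\t0\n")
        for rep in range(config.curve_replicates):
            noise = (
                float(rng.normal(0.0, config.curve_noise_sigma))
                if config.curve_noise_sigma > 0
                else 0.0
            )
            f800 = max(0.0, (1.0 + noise) * fmax_raw + f0_raw)
            fh.write(f"noATP_r{rep + 1}\t0\t{f800:.4f}\t{f700:.1f}\t1\n")
        for i, (c, y) in enumerate(zip(curve.atp_mM, curve.y)):
            f800 = max(0.0, y * fmax_raw + f0_raw)
            fh.write(f"lane{i + 1}\t{c:.6g}\t{f800:.4f}\t{f700:.1f}\t1\n")

    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    return truth
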