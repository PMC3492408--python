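import numpy as np
import pytest

from ryrmap.digest import cleavage_sites, complete_digest
from ryrmap.fragment_assign import (
    AnchoringError,
    NotLocatedError,
    ReadFormatError,
    UnassignableError,
    assign_c_terminus,
    decode_read,
    locate_n_terminus,
)
from ryrmap.sequence_io import ProteinSequence, segment_mass


class TestDecodeRead:
    @pytest.mark.parametrize(
        "notation, expected",
        [
            ("GSGPPAGPAL", tuple("GSGPPAGPAL")),
            ("(E)GLDFPEYD(G)", (None, *"GLDFPEYD", None)),
            ("AVVAXFRMTP", ("A", "V", "V", "A", None, "F", "R", "M", "T", "P")),
            (
                "I(G)(F)(F)(L)(V)-(I)(E)(Y)",
                ("I", None, None, None, None, None, None, None, None, None),
            ),
            ("ND", ()),
            ("", ()),
        ],
    )
    def test_notation(self, notation, expected):
        assert decode_read(notation) == expected

    def test_malformed(self):
        with pytest.raises(ReadFormatError):
            decode_read("AB(C")


class TestLocate:
    def test_scaffold_reads_anchor_uniquely(self, scaffold):
        cmap = cleavage_sites(scaffold)
        for read, start in [
            ("GSGPPAGPAL", 427),
            ("TQVKGVGQN", 3120),
            ("KLGVDGEEEE", 4476),
            ("RREHFGEEPP", 2402),
            ("ISHTDLVIG", 1509),
            ("AVVAXFRMTP", 3631),
        ]:
            assert locate_n_terminus(scaffold, read, cmap=cmap) == [start]

    def test_min_length_guard(self):
        seq = ProteinSequence(id="s", residues="AAAA")
        with pytest.raises(AnchoringError):
            locate_n_terminus(seq, "AAAA", require_cleavage_junction=False)

    def test_not_located(self, scaffold):
        with pytest.raises(NotLocatedError):
            locate_n_terminus(
                scaffold, "WWWWWWWWWW", cmap=cleavage_sites(scaffold)
            )

    def test_strict_mode_requires_junction(self):
        # read present mid-peptide but not after a cleavage site
        seq = ProteinSequence(id="s", residues="AAGSGPPAGPALKAA")
        cmap = cleavage_sites(seq)
        with pytest.raises(NotLocatedError):
            locate_n_terminus(seq, "GSGPP", cmap=cmap)
        assert locate_n_terminus(
            seq, "GSGPP", require_cleavage_junction=False
        ) == [3]

    def test_multiple_candidates_reported(self):
        seq = ProteinSequence(id="s", residues="KGSGPPAKGSGPPAK")
        hits = locate_n_terminus(
            seq, "GSGPP", require_cleavage_junction=True, cmap=cleavage_sites(seq)
        )
        assert hits == [2, 9]


class TestAssignCTerminus:
    def test_zero_noise_identity(self):
        rng = np.random.default_rng(7)
        residues = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=400))
        seq = ProteinSequence(id="s", residues=residues)
        cmap = cleavage_sites(seq)
        frags = complete_digest(seq, cmap)
        target = max(frags, key=lambda f: f.end - f.start)
        ranked = assign_c_terminus(
            seq, target.start, target.calc_mass_da / 1000.0, cmap
        )
        assert ranked[0].end == target.end
        assert ranked[0].mass_error_fraction == pytest.approx(0.0, abs=1e-12)
        assert ranked[0].candidate_rank == 1

    def test_scaffold_fragment11_and_15(self, scaffold):
        cmap = cleavage_sites(scaffold)
        ranked = assign_c_terminus(scaffold, 4476, 70.0, cmap, fragment_id="11")
        by_end = {a.end: a for a in ranked}
        assert 5037 in by_end
        assert by_end[5037].calc_kda == 64
        assert by_end[5037].mass_error_fraction == pytest.approx(0.086, abs=0.01)
        ranked15 = assign_c_terminus(scaffold, 2402, 45.0, cmap, fragment_id="15")
        assert any(a.end == 2795 and a.calc_kda == 45 for a in ranked15)

    def test_ranking_deterministic(self, scaffold):
        cmap = cleavage_sites(scaffold)
        a = assign_c_terminus(scaffold, 4476, 70.0, cmap)
        b = assign_c_terminus(scaffold, 4476, 70.0, cmap)
        assert a == b
        assert [x.candidate_rank for x in a] == list(range(1, len(a) + 1))
        errors = [x.mass_error_fraction for x in a]
        assert errors == sorted(errors)

    def test_unassignable_reports_nearest_miss(self):
        seq = ProteinSequence(id="s", residues="AAKAA")
        cmap = cleavage_sites(seq)
        with pytest.raises(UnassignableError, match="nearest miss"):
            assign_c_terminus(seq, 1, 500.0, cmap)

    def test_tolerance_bounds(self, scaffold):
        cmap = cleavage_sites(scaffold)
        with pytest.raises(ValueError):
            assign_c_terminus(scaffold, 1, 50.0, cmap, tolerance=0.9)


def test_true_end_recovered_under_mass_noise():
    """With 5% multiplicative mass noise the true C-terminus is (essentially)
    always in the tolerance-0.15 candidate list and ranks first in >= 90% of
    replicates.

    Limited proteolysis is the regime this contract targets: only a dozen or
    so major cleavage sites produce observable bands, so neighboring
    C-terminal candidates differ by tens of kDa and gel-level mass noise
    rarely reorders them. The test protein therefore carries rare K/R
    (about one major site per 400 residues, matching the study-scale
    fragment map) and observed spans cover one to four inter-site segments.
    """
    rng = np.random.default_rng(42)
    other = [r for r in "ACDEFGHILMNPQSTVWY"]
    freqs = {r: 0.996 / len(other) for r in other}
    freqs["K"] = freqs["R"] = 0.002
    letters = sorted(freqs)
    probs = np.array([freqs[r] for r in letters])
    residues = "".join(rng.choice(letters, size=5000, p=probs / probs.sum()))
    seq = ProteinSequence(id="s", residues=residues)
    cmap = cleavage_sites(seq)
    boundaries = [0, *cmap.sites, seq.length]
    n_in_list = n_first = 0
    n_rep = 500
    for _ in range(n_rep):
        a = int(rng.integers(0, len(boundaries) - 1))
        b = min(a + int(rng.integers(1, 5)), len(boundaries) - 1)
        start, end = boundaries[a] + 1, boundaries[b]
        true_kda = segment_mass(seq, start, end) / 1000.0
        apparent = true_kda * float(np.exp(rng.normal(0.0, 0.05)))
        ranked = assign_c_terminus(seq, start, apparent, cmap, tolerance=0.15)
        ends = [x.end for x in ranked]
        n_in_list += end in ends
        n_first += ends[0] == end
    # a 5%-sigma lognormal factor exceeds the 15% tolerance with probability
    # ~0.3% per draw, so a handful of misses in 500 is expected
    assert n_in_list / n_rep >= 0.99
    assert n_first / n_rep >= 0.90
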