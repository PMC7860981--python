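"""Variable-segment delimitation, global alignment vs exhaustive enumeration,
identity/proline statistics and peptide masses."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st

from ureasurf.synthetic import make_nags_set, _random_seq
from ureasurf.vs import (GAP_EXTEND, GAP_OPEN, NagsRecord, align_global,
                         find_vs, group_stats, pairwise_identity,
                         peptide_mass, proline_content)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _score_columns(cols):
    """Affine score of an explicit alignment: gap of length L costs
    GAP_OPEN + (L-1)*GAP_EXTEND."""
    score = 0.0
    run_a = run_b = 0
    for ca, cb in cols:
        if ca == "-":
            run_a += 1
            run_b = 0
            score += GAP_OPEN if run_a == 1 else GAP_EXTEND
        elif cb == "-":
            run_b += 1
            run_a = 0
            score += GAP_OPEN if run_b == 1 else GAP_EXTEND
        else:
            run_a = run_b = 0
            score += BLOSUM62[ca, cb]
    return score


def brute_force_best_score(a, b):
    """Exhaustive enumeration over all global alignments (tiny inputs only)."""
    best = [-math.inf]

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], _score_columns(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


class TestAlignGlobal:
    def test_identical_sequences_score_is_diagonal_sum(self):
        a, b, score = align_global("ACDE", "ACDE")
        assert (a, b) == ("ACDE", "ACDE")
        assert score == 4 + 9 + 6 + 5  # BLOSUM62 diagonal for A,C,D,E

    def test_single_mismatch_column(self):
        a, b, score = align_global("A", "G")
        assert (a, b) == ("A", "G")
        assert score == BLOSUM62["A", "G"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "ACD")

    @pytest.mark.parametrize("a, b", [
        ("ACDE", "ACE"),
        ("KRED", "KED"),
        ("WWP", "WP"),
        ("ACDEFG", "ADFG"),
    ])
    def test_equals_exhaustive_enumeration(self, a, b):
        _, _, score = align_global(a, b)
        assert score == brute_force_best_score(a, b)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEGKLW", min_size=1, max_size=5),
           st.text(alphabet="ACDEGKLW", min_size=1, max_size=5))
    def test_optimality_property_short_inputs(self, a, b):
        _, _, score = align_global(a, b)
        assert score == brute_force_best_score(a, b)


class TestFindVs:
    def test_constructed_concatenation(self):
        ref = "W" + _random_seq(np.random.default_rng(0), 80)
        mts = "MLSTARAHLL"  # 10 residues
        vs_seq = "PAPPSAPLP"  # 9 residues
        rec = NagsRecord(id="x", group="mammal", sequence=mts + vs_seq + ref,
                         mpp_site=11)
        vseg = find_vs(rec, ref)
        assert (vseg.start, vseg.end) == (11, 19)
        assert vseg.sequence == vs_seq

    def test_post_mpp_equals_reference_gives_empty_vs(self):
        ref = "W" + _random_seq(np.random.default_rng(1), 60)
        rec = NagsRecord(id="x", group="mammal", sequence="MMM" + ref,
                         mpp_site=4)
        vseg = find_vs(rec, ref)
        assert vseg.length == 0 and vseg.end < vseg.start

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(vs_len=st.integers(1, 200), mts_len=st.integers(0, 60),
           seed=st.integers(0, 10_000))
    def test_recovers_generator_truth_spans(self, vs_len, mts_len, seed):
        rng = np.random.default_rng(seed)
        ref = "W" + _random_seq(rng, 100)
        mts = _random_seq(rng, mts_len)
        vs_seq = _random_seq(rng, vs_len, proline_fraction=0.2)
        rec = NagsRecord(id="r", group="mammal", sequence=mts + vs_seq + ref,
                         mpp_site=mts_len + 1)
        vseg = find_vs(rec, ref)
        assert (vseg.start, vseg.end) == (mts_len + 1, mts_len + vs_len)
        assert vseg.sequence == vs_seq


class TestProlineContent:
    @pytest.mark.parametrize("seq, pct", [("PPPP", 100.0), ("APGA", 25.0),
                                          ("ACDE", 0.0)])
    def test_definition(self, seq, pct):
        assert proline_content(seq) == pytest.approx(pct)

    def test_empty_sequence_undefined(self):
        with pytest.raises(ValueError):
            proline_content("")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80))
    def test_bounded_and_reversal_invariant(self, seq):
        pct = proline_content(seq)
        assert 0.0 <= pct <= 100.0
        assert pct == proline_content(seq[::-1])


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEF", "ACDEF") == 100.0

    def test_half_identity(self):
        assert pairwise_identity("AAAA", "AATT") == pytest.approx(50.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 500))
    def test_symmetry_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_seq(rng, int(rng.integers(5, 40)))
        b = _random_seq(rng, int(rng.integers(5, 40)))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_100_iff_identical_when_gapless(self):
        assert pairwise_identity("ACD", "ACD") == 100.0
        assert pairwise_identity("ACD", "ACE") < 100.0


class TestGroupStats:
    def test_generated_ranges_within_prescription(self):
        records, ref, _ = make_nags_set(n_mammal=8, n_other=8, seed=4)
        stats = group_stats(records, ref).set_index("group")
        m = stats.loc["mammal"]
        assert 37 <= m["length_min"] <= m["length_max"] <= 64
        # one-residue quantisation slack on the percent bounds
        assert m["proline_min_pct"] >= 100 * 0.174 - 100 / 37
        assert m["proline_max_pct"] <= 100 * 0.323 + 100 / 37
        o = stats.loc["non_mammal"]
        assert 31 <= o["length_min"] <= o["length_max"] <= 40

    def test_single_record_group_omits_identity(self):
        rng = np.random.default_rng(9)
        ref = "W" + _random_seq(rng, 60)
        rec = NagsRecord(id="only", group="mammal",
                         sequence=_random_seq(rng, 10) + _random_seq(rng, 20)
                         + ref, mpp_site=11)
        stats = group_stats([rec], ref).set_index("group")
        assert math.isnan(stats.loc["mammal", "identity_min_pct"])
        assert stats.loc["mammal", "length_min"] == 20

    def test_identical_records_have_identity_100(self):
        rng = np.random.default_rng(10)
        ref = "W" + _random_seq(rng, 60)
        seq = _random_seq(rng, 10) + _random_seq(rng, 25) + ref
        recs = [NagsRecord(id=f"r{i}", group="mammal", sequence=seq,
                           mpp_site=11) for i in range(2)]
        stats = group_stats(recs, ref).set_index("group")
        assert stats.loc["mammal", "identity_min_pct"] == 100.0
        assert stats.loc["mammal", "identity_max_pct"] == 100.0


class TestPeptideMass:
    def test_glycine(self):
        assert peptide_mass("G") == pytest.approx(0.075, abs=5e-4)

    def test_diglycine_loses_one_water(self):
        assert peptide_mass("GG") == pytest.approx(0.132, abs=5e-4)

    def test_concatenation_additivity(self):
        a, b = "ADKLF", "GGWPT"
        joint = peptide_mass(a + b)
        assert joint == pytest.approx(peptide_mass(a) + peptide_mass(b)
                                      - 0.018, abs=2e-3)

    def test_tag_is_fused_n_terminally(self):
        assert peptide_mass("ACD", tag="MGH") == peptide_mass("MGHACD")

    def test_non_standard_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("ACB")
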