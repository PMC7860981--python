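"""Fixture generators: reproducibility, truth-file fidelity, oracle quality."""

import numpy as np
import pytest

from ureasurf.synthetic import (DegenerateGeometryError, FixtureSpec,
                                generate_fixture, make_nags_set,
                                make_sphere_system, make_toy_peptide,
                                make_variant_table, mc_sasa, simulate_msa,
                                two_sphere_exposed_areas)


class TestSphereSystems:
    def test_single_sphere_truth(self):
        _, truth, se = make_sphere_system([1.7], [[0, 0, 0]])
        assert truth[0] == pytest.approx(4 * np.pi * 3.1**2)
        assert se is None

    def test_two_sphere_cap_formula_against_mc(self):
        """The closed form agrees with independent Monte-Carlo integration."""
        r1, r2, d, probe = 1.7, 1.5, 2.4, 1.4
        analytic = two_sphere_exposed_areas(r1, r2, d, probe)
        coords = np.array([[0, 0, 0], [d, 0, 0]])
        mc, ses = mc_sasa(coords, np.array([r1, r2]), probe,
                          n_samples=400_000, seed=1)
        for a, m, s in zip(analytic, mc, ses):
            assert abs(a - m) < 4 * s + 1e-6

    def test_disjoint_and_engulfed_limits(self):
        full = 4 * np.pi * 3.1**2
        a, b = two_sphere_exposed_areas(1.7, 1.7, 100.0, 1.4)
        assert a == pytest.approx(full) and b == pytest.approx(full)
        a, b = two_sphere_exposed_areas(5.0, 0.5, 0.1, 0.0)
        assert b == 0.0

    def test_coincident_centers_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            make_sphere_system([1.7, 1.7], [[0, 0, 0], [0, 0, 0]])

    def test_mc_standard_error_below_half_percent_at_1e6(self):
        coords = [[0, 0, 0], [2.5, 0, 0], [1.2, 2.0, 0.5]]
        _, areas, ses = make_sphere_system([1.7, 1.55, 1.52], coords,
                                           mc_samples=1_000_000, seed=2)
        assert np.all(ses / areas < 0.005)

    def test_seeded_reproducibility(self):
        a = make_sphere_system([1.7] * 3, [[0, 0, 0], [3, 0, 0], [0, 3, 0]],
                               mc_samples=50_000, seed=9)[1]
        b = make_sphere_system([1.7] * 3, [[0, 0, 0], [3, 0, 0], [0, 3, 0]],
                               mc_samples=50_000, seed=9)[1]
        np.testing.assert_array_equal(a, b)


class TestToyPeptides:
    def test_extended_all_surface(self):
        _, labels = make_toy_peptide("AAAAA", "extended")
        assert labels == {i: True for i in range(1, 6)}

    def test_collapsed_cluster_has_buried_core(self):
        structure, labels = make_toy_peptide("A" * 27, "collapsed", seed=0)
        assert len(labels) == 27
        assert any(not v for v in labels.values()), "no buried residue"
        assert any(v for v in labels.values()), "no exposed residue"

    def test_labels_match_engine_classification(self, study_params):
        """The dot-method classifier reproduces the MC-verified labels."""
        from ureasurf.sasa import accessibility_table

        structure, labels = make_toy_peptide("A" * 27, "collapsed", seed=1)
        accs = accessibility_table(structure, study_params)
        got = {a.seq_num: a.is_surface for a in accs}
        assert got == labels

    def test_oversized_sequence_rejected(self):
        with pytest.raises(ValueError):
            make_toy_peptide("A" * 51, "extended")


class TestSimulateMsa:
    def test_full_conservation(self):
        alignment, truth = simulate_msa(n_seqs=10, length=8, conservation=1.0,
                                        seed=0)
        assert all(seq == alignment.query for _, seq in alignment.homologs)
        assert np.all(truth == 1.0)

    def test_seeded_bytes_identical(self):
        a, _ = simulate_msa(n_seqs=20, length=15, conservation=0.7, seed=42)
        b, _ = simulate_msa(n_seqs=20, length=15, conservation=0.7, seed=42)
        assert a.records == b.records

    def test_group_round_robin(self):
        alignment, _ = simulate_msa(n_seqs=6, length=5, conservation=0.9,
                                    groups=["m", "f"], seed=1)
        counts = {}
        for g in alignment.taxonomy.values():
            counts[g] = counts.get(g, 0) + 1
        assert counts == {"m": 3, "f": 3}

    def test_invalid_conservation_rejected(self):
        with pytest.raises(ValueError):
            simulate_msa(n_seqs=5, length=3, conservation=1.5)


class TestVariantTables:
    def test_all_similar_ddg_candidates_are_surface_unannotated(self):
        labels = {i: ("A", i <= 5) for i in range(1, 11)}
        table, expected = make_variant_table(labels, n_variants=10,
                                             fraction_surface=0.5,
                                             ddg_spec=1.0,
                                             annotated_fraction=0.0, seed=0)
        surface_tokens = {
            row["variant"] for _, row in table.iterrows()
            if labels[int(row["variant"][3:-1])][1]
        }
        assert expected == surface_tokens

    def test_all_destabilising_gives_no_candidates(self):
        labels = {i: ("A", True) for i in range(1, 11)}
        _, expected = make_variant_table(labels, n_variants=5,
                                         fraction_surface=1.0, ddg_spec=5.0,
                                         seed=0)
        assert expected == set()

    def test_unachievable_fraction_rejected(self):
        labels = {1: ("A", True), 2: ("C", False)}
        with pytest.raises(ValueError):
            make_variant_table(labels, n_variants=4, fraction_surface=1.0)

    def test_seeded_regeneration_identical(self):
        labels = {i: ("A", i % 2 == 0) for i in range(1, 21)}
        t1, e1 = make_variant_table(labels, seed=5)
        t2, e2 = make_variant_table(labels, seed=5)
        assert t1.equals(t2) and e1 == e2


class TestNagsSets:
    def test_truth_spans_recovered_exactly(self):
        from ureasurf.vs import find_vs

        records, ref, truth = make_nags_set(n_mammal=10, n_other=10, seed=6)
        for rec in records:
            vseg = find_vs(rec, ref)
            assert (vseg.start, vseg.end) == truth[rec.id]

    def test_group_sizes_and_absence(self):
        records, _, _ = make_nags_set(n_mammal=3, n_other=0, seed=0)
        groups = {r.group for r in records}
        assert groups == {"mammal"}

    def test_proline_within_range_up_to_quantisation(self):
        records, _, truth = make_nags_set(n_mammal=20, n_other=0, seed=7)
        for rec in records:
            start, end = truth[rec.id]
            vs_seq = rec.sequence[start - 1:end]
            pct = 100 * vs_seq.count("P") / len(vs_seq)
            assert 17.4 - 100 / len(vs_seq) <= pct <= 32.3 + 100 / len(vs_seq)


class TestFixtureFiles:
    @pytest.mark.parametrize("kind, params", [
        ("sphere_system", {"radii": [1.7, 1.7], "positions": [[0, 0, 0], [3, 0, 0]]}),
        ("msa", {"n_seqs": 5, "length": 10, "conservation": 0.8}),
        ("nags_set", {"n_mammal": 2, "n_other": 2}),
        ("variant_table", {"residue_labels": {1: ["A", True], 2: ["C", False]},
                           "n_variants": 2, "fraction_surface": 0.5}),
    ])
    def test_generation_is_reproducible_bytes(self, tmp_path, kind, params):
        spec = FixtureSpec(kind=kind, params=params, seed=3)
        first = generate_fixture(spec, tmp_path / "a")
        second = generate_fixture(spec, tmp_path / "b")
        for fa, fb in zip(first, second):
            assert fa.read_bytes() == fb.read_bytes()

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_fixture(FixtureSpec(kind="nope"), tmp_path)
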