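"""HGVS parsing, ddG stability classes and the candidate-residue ledger."""

import pytest

from ureasurf.sasa import ResidueAccessibility
from ureasurf.variants import (MissenseVariant, StabilityClass,
                               UnsupportedVariantError, accessibility_index,
                               build_ledger, locate_variant, parse_variant,
                               stability_class, summarize_counts)


class TestParseVariant:
    @pytest.mark.parametrize("token, expected", [
        ("p.R40H", ("R", 40, "H")),
        ("p.Arg721Gln", ("R", 721, "Q")),
        ("R1262P", ("R", 1262, "P")),
        ("p.Tyr389Cys", ("Y", 389, "C")),
    ])
    def test_accepted_tokens(self, token, expected):
        v = parse_variant(token)
        assert (v.ref_aa, v.position, v.alt_aa) == expected

    @pytest.mark.parametrize("token", [
        "p.K289fs", "p.R40*", "p.Glu52Ter", "p.K221del", "p.A102_G103insV",
    ])
    def test_non_missense_rejected(self, token):
        with pytest.raises(UnsupportedVariantError):
            parse_variant(token)

    def test_identity_substitution_rejected(self):
        with pytest.raises(ValueError):
            parse_variant("p.R40R")

    def test_normalised_token_round_trip(self):
        assert parse_variant("p.Arg721Gln").token == "p.R721Q"


class TestStabilityClass:
    @pytest.mark.parametrize("ddg, expected", [
        (1.0, StabilityClass.SIMILAR),
        (0.0, StabilityClass.SIMILAR),   # boundary inclusive
        (2.0, StabilityClass.SIMILAR),   # boundary inclusive
        (-0.5, StabilityClass.MORE_STABLE),
        (2.01, StabilityClass.DESTABILIZING),
        (None, StabilityClass.UNKNOWN),
    ])
    def test_threshold_rule(self, ddg, expected):
        assert stability_class(ddg) is expected


def _acc(chain, seq, aa, rel):
    return ResidueAccessibility(chain_id=chain, seq_num=seq, insertion_code="",
                                aa=aa, sasa=0.0, max_sasa=100.0, rel_sasa=rel,
                                is_surface=rel > 25.0)


@pytest.fixture
def state_indexes():
    apo = accessibility_index([_acc("A", 10, "R", 50.0), _acc("A", 11, "K", 10.0),
                               _acc("A", 12, "D", 30.0)])
    lig = accessibility_index([_acc("A", 10, "R", 40.0), _acc("A", 11, "K", 30.0)])
    return {"apo": apo, "liganded": lig}


class TestLocateVariant:
    def test_surface_in_both_states(self, state_indexes):
        row = locate_variant(parse_variant("p.R10H"), state_indexes)
        assert row.surface == {"apo": True, "liganded": True}
        assert not row.discordant

    def test_unresolved_in_one_state(self, state_indexes):
        row = locate_variant(parse_variant("p.D12N"), state_indexes)
        assert row.surface["apo"] is True
        assert row.surface["liganded"] is None

    def test_reference_mismatch_recorded(self, state_indexes):
        row = locate_variant(parse_variant("p.Q10H"), state_indexes)
        assert row.discordant == {"apo": "R", "liganded": "R"}
        assert row.surface["apo"] is True  # row still emitted

    def test_numbering_offset_applied(self):
        # mature-protein structure numbering shifted by -32 vs pre-protein
        idx = accessibility_index([_acc("A", 8, "K", 60.0)], numbering_offset=32)
        row = locate_variant(parse_variant("p.K40E"), {"apo": idx})
        assert row.surface["apo"] is True

    def test_multichain_keeps_most_exposed_copy(self):
        idx = accessibility_index([_acc("A", 5, "E", 10.0),
                                   _acc("B", 5, "E", 40.0),
                                   _acc("C", 5, "E", 20.0)])
        assert idx[5].rel_sasa == 40.0


class TestBuildLedger:
    def test_candidate_filter_definition(self, state_indexes):
        variants = [
            MissenseVariant("R", 10, "H", ddg=1.5),   # surface both, similar
            MissenseVariant("K", 11, "E", ddg=1.0),   # surface liganded only
            MissenseVariant("D", 12, "N", ddg=5.0),   # destabilising
            MissenseVariant("R", 10, "C", ddg=-1.0),  # more stable
        ]
        rows = build_ledger(variants, state_indexes)
        by_token = {r.variant.token: r for r in rows}
        assert by_token["p.R10H"].candidate
        assert by_token["p.K11E"].candidate  # surface in >=1 state suffices
        assert not by_token["p.D12N"].candidate
        assert by_token["p.R10C"].candidate

    def test_experimental_annotation_excludes(self, state_indexes):
        variants = [MissenseVariant("R", 10, "H", ddg=1.0)]
        rows = build_ledger(variants, state_indexes,
                            annotations={"p.R10H": "decreased enzymatic activity"})
        assert not rows[0].candidate

    def test_unknown_ddg_needs_explicit_allowance(self, state_indexes):
        variants = [MissenseVariant("R", 10, "H")]
        assert not build_ledger(variants, state_indexes)[0].candidate
        assert build_ledger(variants, state_indexes,
                            allow_unknown_ddg=True)[0].candidate

    def test_duplicates_deduplicated(self, state_indexes):
        variants = [MissenseVariant("R", 10, "H", ddg=1.0)] * 2
        assert len(build_ledger(variants, state_indexes)) == 1

    def test_site_distance_filter(self, state_indexes):
        variants = [MissenseVariant("R", 10, "H", ddg=1.0)]
        near = build_ledger(variants, state_indexes,
                            site_distances={10: 4.0}, site_distance_cutoff=8.0)
        far = build_ledger(variants, state_indexes,
                           site_distances={10: 12.0}, site_distance_cutoff=8.0)
        assert not near[0].candidate
        assert far[0].candidate

    def test_agrees_with_brute_force_over_seeded_fixtures(self):
        """Ledger output equals direct rule enumeration on 100 seeded tables."""
        from ureasurf.synthetic import make_variant_table

        rng_labels = {}
        aas = "ARNDCQEGHILKMFPSTWYV"
        for pos in range(1, 41):
            rng_labels[pos] = (aas[pos % 20], pos % 2 == 0)
        indexes = {"apo": accessibility_index([
            _acc("A", pos, aa, 60.0 if surf else 5.0)
            for pos, (aa, surf) in rng_labels.items()
        ])}
        for seed in range(100):
            table, expected = make_variant_table(
                rng_labels, n_variants=12, fraction_surface=0.5,
                ddg_spec=("normal", 1.0, 2.0), seed=seed)
            variants, annotations = [], {}
            for _, row in table.iterrows():
                v = parse_variant(row["variant"],
                                  ddg=None if row["ddg_kcal_mol"] is None
                                  else float(row["ddg_kcal_mol"]))
                variants.append(v)
                if row["annotation"]:
                    annotations[v.token] = row["annotation"]
            rows = build_ledger(variants, indexes, annotations=annotations)
            got = {r.variant.token for r in rows if r.candidate}
            assert got == expected, f"seed {seed}"

    def test_order_invariance_of_counts(self, state_indexes):
        variants = [
            MissenseVariant("R", 10, "H", ddg=1.0),
            MissenseVariant("K", 11, "E", ddg=3.0),
            MissenseVariant("D", 12, "N", ddg=0.5),
        ]
        a = summarize_counts(build_ledger(variants, state_indexes))
        b = summarize_counts(build_ledger(list(reversed(variants)),
                                          state_indexes))
        assert a == b


class TestSummarizeCounts:
    def test_distinct_residue_counting(self, state_indexes):
        variants = [
            MissenseVariant("R", 10, "H", ddg=1.0),
            MissenseVariant("R", 10, "C", ddg=1.0),
            MissenseVariant("K", 11, "E", ddg=1.0),
        ]
        counts = summarize_counts(build_ledger(variants, state_indexes))
        assert counts["surface_variants"] == 3
        assert counts["surface_residues"] == 2
        assert counts["surface_in_both"] == 2
        assert counts["surface_liganded_only"] == 1

    def test_empty_ledger_all_zero(self):
        counts = summarize_counts([])
        assert all(v == 0 for v in counts.values())

    def test_threshold_monotonicity_of_surface_set(self):
        """Raising the cutoff never increases the surface-variant count."""
        accs = [_acc("A", i, "A", rel) for i, rel in
                enumerate([10.0, 26.0, 40.0, 80.0], start=1)]
        variants = [MissenseVariant("A", i, "G", ddg=1.0) for i in range(1, 5)]

        def count_at(threshold):
            for a in accs:
                a.is_surface = a.rel_sasa > threshold
            idx = accessibility_index(accs)
            rows = build_ledger(variants, {"apo": idx})
            return summarize_counts(rows)["surface_variants"]

        assert count_at(50.0) <= count_at(25.0)
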