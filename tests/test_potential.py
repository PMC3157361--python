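"""Decoy construction, pair counting, potential derivation (with the
glycine split), contact matrices and interaction scoring."""

import numpy as np
import pytest

from pepvax._alphabet import AA_INDEX, AMINO_ACIDS
from pepvax.potential import (
    ContactMatrix,
    DerivationError,
    InteractionPotential,
    SurfaceComposition,
    build_contact_matrix,
    count_pairs,
    derive_potential,
    glycine_fraction,
    load_general_potential,
    make_decoy,
    map_mhc_to_template,
    score_complex,
    score_interaction,
    score_to_probability,
    split_by_glycine,
)
from pepvax.structure_io import extract_interface, make_fixture_complex, make_fixture_set

from conftest import brute_force_interface


def brute_force_counts(structures, cutoff=8.0):
    counts = np.zeros((20, 20))
    for c in structures:
        for r, l, _ in brute_force_interface(c, cutoff):
            counts[AA_INDEX[r.aa], AA_INDEX[l.aa]] += 1
    return counts


class TestSurfaceComposition:
    def test_default_sums_to_one_with_glycine_at_surface_frequency(self, comp):
        assert sum(comp.freq.values()) == pytest.approx(1.0, abs=1e-9)
        assert comp.freq["G"] == pytest.approx(0.069)

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            SurfaceComposition({a: 0.1 for a in AMINO_ACIDS})


class TestMakeDecoy:
    def test_degenerate_composition_gives_all_alanine_ligand(self, rng):
        c, _ = make_fixture_complex(3, 5, "ACD", "GGGGG", 1.0, seed=0)
        point = SurfaceComposition({a: (1.0 if a == "A" else 0.0) for a in AMINO_ACIDS})
        d = make_decoy(c, point, rng)
        assert d.sequence("ligand") == "AAAAA"
        assert d.sequence("receptor") == "ACD"
        for a, b in zip(c.ligand_residues, d.ligand_residues):
            assert a.ca_xyz == b.ca_xyz

    def test_decoy_frequencies_match_composition(self, comp, rng):
        c, _ = make_fixture_complex(2, 10, "AA", "G" * 10, 1.0, seed=1)
        n_decoys = 3000
        counts = np.zeros(20)
        for _ in range(n_decoys):
            d = make_decoy(c, comp, rng)
            for aa in d.sequence("ligand"):
                counts[AA_INDEX[aa]] += 1
        n = n_decoys * 10
        p = comp.as_array()
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(counts / n - p) <= 3 * se + 1e-12)


class TestCountPairs:
    def test_hand_enumerated_fixture(self):
        # receptor A,G; ligand G,L all in contact: pairs (A,G),(A,L),(G,G),(G,L)
        c, _ = make_fixture_complex(2, 2, "AG", "GL", 1.0, seed=3)
        pcm = count_pairs([c])
        assert pcm.counts[AA_INDEX["A"], AA_INDEX["G"]] == 1
        assert pcm.counts[AA_INDEX["A"], AA_INDEX["L"]] == 1
        assert pcm.counts[AA_INDEX["G"], AA_INDEX["G"]] == 1
        assert pcm.counts.sum() == len(extract_interface(c))

    def test_empty_interfaces_give_zero_matrix(self):
        c, _ = make_fixture_complex(3, 3, "AAA", "GGG", 0.0, seed=0)
        assert count_pairs([c]).counts.sum() == 0

    def test_order_invariance_and_brute_force(self):
        structures = make_fixture_set(6, seed=9, preset="null")
        a = count_pairs(structures).counts
        b = count_pairs(structures[::-1]).counts
        assert np.array_equal(a, b)
        assert np.array_equal(a, brute_force_counts(structures))


class TestDerivePotential:
    def test_planted_pair_recovered_as_unique_maximum(self, comp):
        structures = make_fixture_set(60, seed=4, preset="planted", planted_pair=("A", "G"))
        ip = derive_potential(structures, "IP_T", comp, rng=0)
        m = ip.matrix
        assert m.max() == 1.0  # bit-exact normalization
        assert np.unravel_index(m.argmax(), m.shape) == (AA_INDEX["A"], AA_INDEX["G"])
        assert (m == 1.0).sum() == 1

    def test_null_composition_entries_near_zero(self, comp):
        structures = make_fixture_set(200, seed=5, preset="null")
        c_crystal = count_pairs(structures).counts / len(structures)
        rng = np.random.default_rng(6)
        decoys = [make_decoy(c, comp, rng) for c in structures]
        c_random = count_pairs(decoys).counts / len(decoys)
        diff = c_crystal - c_random
        # each entry is a difference of two mean counts with the same
        # expectation; bound fluctuations by 5 Monte-Carlo SEs
        pooled = (c_crystal + c_random) / len(structures)
        se = np.sqrt(np.maximum(pooled, 1e-3))
        assert np.all(np.abs(diff) < 5 * se)

    def test_decoy_count_stability_of_argmax(self, comp):
        structures = make_fixture_set(40, seed=7, preset="planted")
        one = derive_potential(structures, "IP_T", comp, decoys_per_structure=1, rng=1)
        ten = derive_potential(structures, "IP_T", comp, decoys_per_structure=10, rng=1)
        assert one.matrix.argmax() == ten.matrix.argmax()

    def test_degenerate_input_raises(self, comp):
        # all interfaces empty: nothing can be enriched
        c, _ = make_fixture_complex(3, 3, "AAA", "GGG", 0.0, seed=0)
        with pytest.raises((DerivationError, ValueError)):
            derive_potential([c], "IP_T", comp, rng=0)


class TestGlycineSplit:
    def test_fraction_counts_distinct_ligand_interface_residues(self):
        c, _ = make_fixture_complex(4, 4, "AAAA", "GGAL", 1.0, seed=0)
        assert glycine_fraction(c) == pytest.approx(0.5)

    def test_no_glycine_gives_zero(self):
        c, _ = make_fixture_complex(3, 3, "AAA", "ALK", 1.0, seed=0)
        assert glycine_fraction(c) == 0.0

    def test_seven_percent_classified_high(self):
        # 7 of 100 ligand interface residues are glycine: 0.07 > 0.069
        seq = "G" * 7 + "A" * 93
        c, _ = make_fixture_complex(50, 100, "A" * 50, seq, 1.0, seed=0,
                                    complex_kind="antibody_antigen")
        frac = glycine_fraction(c)
        assert frac == pytest.approx(0.07)
        high, low = split_by_glycine([c])
        assert [s.id for s in high] == [c.id]

    def test_boundary_tie_goes_low_and_partition_is_exact(self):
        def with_fraction(n_g, n_total, ident):
            seq = "G" * n_g + "A" * (n_total - n_g)
            c, _ = make_fixture_complex(n_total, n_total, "A" * n_total, seq, 1.0,
                                        seed=0, complex_kind="antibody_antigen",
                                        structure_id=ident)
            return c

        cs = [with_fraction(50, 1000, "f050"),   # 0.05
              with_fraction(69, 1000, "f069"),   # 0.069 exactly: tie -> low
              with_fraction(70, 1000, "f070")]   # 0.07
        high, low = split_by_glycine(cs)
        assert {c.id for c in low} == {"f050", "f069"}
        assert {c.id for c in high} == {"f070"}
        assert sorted(c.id for c in high + low) == sorted(c.id for c in cs)

    def test_zero_threshold_sends_any_glycine_high(self):
        c, _ = make_fixture_complex(4, 4, "AAAA", "GAAA", 1.0, seed=0,
                                    complex_kind="antibody_antigen")
        high, low = split_by_glycine([c], threshold=0.0)
        assert high and not low


class TestContactMatrixAndScoring:
    def test_identity_patterned_contacts(self):
        # two receptor/ligand pairs placed far apart: contacts (0,0), (1,1)
        from pepvax.structure_io import Chain, ComplexStructure, Residue

        rec = [Residue("A", "R", 0, (0.0, 0.0, 0.0)), Residue("G", "R", 1, (100.0, 0.0, 0.0))]
        lig = [Residue("G", "L", 0, (5.0, 0.0, 0.0)), Residue("L", "L", 1, (105.0, 0.0, 0.0))]
        c = ComplexStructure("ident", [Chain("R", "receptor", rec), Chain("L", "ligand", lig)], "tcr_pmhc")
        cm = build_contact_matrix(c)
        assert np.array_equal(cm.m, np.eye(2, dtype=bool))

    def test_all_contact_fixture_and_count_consistency(self):
        c, _ = make_fixture_complex(3, 3, "AAA", "GGG", 1.0, seed=1)
        cm = build_contact_matrix(c)
        assert cm.n_contacts == len(extract_interface(c))

    def test_hand_computed_score(self):
        ip = InteractionPotential(np.zeros((20, 20)), "IP_T")
        ip.matrix[AA_INDEX["A"], AA_INDEX["G"]] = 1.0
        ip.matrix[AA_INDEX["A"], AA_INDEX["L"]] = 0.5
        ip.matrix[AA_INDEX["G"], AA_INDEX["G"]] = -0.2
        ip.matrix[AA_INDEX["G"], AA_INDEX["L"]] = 0.1
        cm = ContactMatrix("t", np.ones((2, 2), dtype=int))
        assert score_interaction("AG", "GL", cm, ip) == pytest.approx(0.35)

    def test_zero_potential_scores_zero(self):
        ip = InteractionPotential(np.zeros((20, 20)), "IP_T")
        cm = ContactMatrix("t", np.ones((3, 4), dtype=int))
        assert score_interaction("ACD", "GGLK", cm, ip) == 0.0

    def test_single_repeated_pair_is_that_entry(self):
        ip = InteractionPotential(np.zeros((20, 20)), "IP_T")
        ip.matrix[AA_INDEX["C"], AA_INDEX["W"]] = 0.42
        cm = ContactMatrix("t", np.ones((2, 2), dtype=int))
        assert score_interaction("CC", "WW", cm, ip) == pytest.approx(0.42)

    def test_all_zero_rows_and_columns_ignored(self, rng):
        m = np.zeros((4, 4), dtype=int)
        m[0, 0] = m[1, 2] = 1
        cm_small = ContactMatrix("t", m[:2, :3])
        cm_padded = ContactMatrix("t", m)
        ip = InteractionPotential(rng.normal(size=(20, 20)), "IP_T")
        # padding with non-contacting rows/cols must not change the score
        assert score_interaction("AC", "DEF", cm_small, ip) == pytest.approx(
            score_interaction("ACKK", "DEFK", cm_padded, ip)
        )

    def test_longer_sequences_use_best_window(self):
        ip = InteractionPotential(np.zeros((20, 20)), "IP_T")
        ip.matrix[AA_INDEX["A"], AA_INDEX["G"]] = 1.0
        cm = ContactMatrix("t", np.ones((1, 1), dtype=int))
        assert score_interaction("KA", "LGL", cm, ip) == pytest.approx(1.0)

    def test_nonstandard_letter_rejected(self):
        ip = InteractionPotential(np.zeros((20, 20)), "IP_T")
        cm = ContactMatrix("t", np.ones((1, 1), dtype=int))
        with pytest.raises(ValueError):
            score_interaction("X", "G", cm, ip)

    def test_score_never_exceeds_one_for_derived_potential(self, env):
        cm = env.templates_I[0][2]
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = "".join(rng.choice(list(AMINO_ACIDS), cm.m.shape[0]))
            l = "".join(rng.choice(list(AMINO_ACIDS), cm.m.shape[1]))
            assert score_interaction(r, l, cm, env.ip_t) <= 1.0


class TestScoreToProbability:
    @pytest.mark.parametrize("score,expected", [(0.35, 0.35), (-0.4, 0.0), (1.0, 1.0)])
    def test_clamp(self, score, expected):
        assert score_to_probability(score) == pytest.approx(expected)

    def test_logistic_is_monotone(self):
        grid = np.linspace(-1, 1, 21)
        vals = [score_to_probability(s, "logistic") for s in grid]
        assert np.all(np.diff(vals) > 0)


class TestSerialization:
    def test_potential_tsv_round_trip(self, env):
        back = InteractionPotential.from_tsv(env.ip_t.to_tsv())
        assert np.array_equal(back.matrix, env.ip_t.matrix)
        assert back.variant == "IP_T"

    def test_contact_matrix_tsv_round_trip(self, env):
        cm = env.templates_I[0][2]
        back = ContactMatrix.from_tsv(cm.to_tsv())
        assert np.array_equal(back.m, cm.m)

    def test_general_table_loads(self):
        g = load_general_potential()
        assert g.matrix.shape == (20, 20)
        assert np.allclose(g.matrix, g.matrix.T)


class TestTemplateMapping:
    def _cm(self, n=2):
        return ContactMatrix("t", np.ones((n, n), dtype=int))

    def test_identical_query_picks_that_template(self):
        lib = [("X", "ACDEFGHIKL", self._cm()), ("Y", "WWWWWWWWWW", self._cm())]
        assert map_mhc_to_template("ACDEFGHIKL", lib) is lib[0][2]

    def test_single_template_always_used(self):
        lib = [("only", "WWWW", self._cm())]
        assert map_mhc_to_template("ACDE", lib) is lib[0][2]

    def test_higher_identity_wins(self):
        # 90% identical to A, 60% to B
        base = "ACDEFGHIKL"
        a = base[:9] + "W"
        b = base[:6] + "WWWW"
        lib = [("A", a, self._cm()), ("B", b, self._cm(3))]
        assert map_mhc_to_template(base, lib) is lib[0][2]

    def test_empty_library_is_error(self):
        with pytest.raises(ValueError):
            map_mhc_to_template("ACDE", [])
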