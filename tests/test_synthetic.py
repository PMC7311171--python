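import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ciliageom import PlaneModel
from ciliageom.motifs import BBSOME_RELAXED, BBSOME_STRICT, cohort_motif_census, scan_motif
from ciliageom.synthetic import (
    CohortSpec,
    HelixSpec,
    make_census_cohort,
    make_extended_chain,
    make_gpcr_cohort,
    make_ideal_helix,
    make_membrane_complex_fixture,
    make_ph_site_fixture,
)


class TestIdealHelix:
    def test_single_residue_sits_at_radius(self):
        model = make_ideal_helix(HelixSpec(1))
        np.testing.assert_allclose(model.ca_coords()[0], [2.3, 0.0, 0.0], atol=1e-12)

    def test_seven_residue_axial_extent_is_nine_angstrom(self):
        xyz = make_ideal_helix(HelixSpec(7)).ca_coords()
        assert xyz[-1, 2] - xyz[0, 2] == pytest.approx(9.0)

    def test_consecutive_ca_distance_matches_closed_form(self):
        spec = HelixSpec(20)
        xyz = make_ideal_helix(spec).ca_coords()
        chord = 2 * spec.helix_radius * np.sin(np.radians(spec.twist_per_residue) / 2)
        expected = np.sqrt(spec.rise_per_residue**2 + chord**2)
        d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        np.testing.assert_allclose(d, expected, atol=1e-6)
        assert expected == pytest.approx(3.8, abs=0.1)  # the canonical Cα–Cα step

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            HelixSpec(0)
        with pytest.raises(ValueError):
            HelixSpec(5, rise_per_residue=-1.0)


class TestExtendedChain:
    def test_six_steps_reach_21_angstrom(self):
        xyz = make_extended_chain(7, rise=3.5).ca_coords()
        assert np.linalg.norm(xyz[-1] - xyz[0]) == pytest.approx(21.0)

    def test_single_residue_has_zero_extent(self):
        assert len(make_extended_chain(1).ca_coords()) == 1

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(1, 100))
    def test_end_to_end_is_steps_times_rise(self, n):
        xyz = make_extended_chain(n).ca_coords()
        assert np.linalg.norm(xyz[-1] - xyz[0]) == pytest.approx((n - 1) * 3.5, abs=1e-9)


class TestMembraneFixture:
    def test_anchor_axis_parallel_to_planted_plane(self, planted_plane):
        _, truth = make_membrane_complex_fixture(planted_plane, seed=3)
        axis = np.array(truth["anchor_axis"])
        assert abs(np.dot(axis, planted_plane.normal)) < 1e-6

    def test_body_entirely_cytoplasmic(self, planted_plane):
        model, _ = make_membrane_complex_fixture(planted_plane, seed=3)
        body = model.subset(lambda a: a.chain_id == "B").coords()
        d = body @ planted_plane.normal - planted_plane.offset
        assert np.all(d < 0)

    def test_same_seed_reproduces_different_seed_differs(self, planted_plane):
        m1, _ = make_membrane_complex_fixture(planted_plane, seed=5)
        m2, _ = make_membrane_complex_fixture(planted_plane, seed=5)
        m3, _ = make_membrane_complex_fixture(planted_plane, seed=6)
        np.testing.assert_array_equal(m1.coords(), m2.coords())
        assert not np.allclose(m1.coords(), m3.coords())

    def test_planted_charges_sit_in_slab(self, planted_plane):
        model, truth = make_membrane_complex_fixture(
            planted_plane, seed=9, n_positive_in_slab=4, n_negative_in_slab=3
        )
        charged = model.subset(lambda a: a.chain_id in ("P", "N")).coords()
        d = charged @ planted_plane.normal - planted_plane.offset
        assert np.all((d < 0) & (d > -truth["charge_slab_depth"]))


class TestGpcrCohort:
    @pytest.mark.parametrize("fraction, expected", [(0.0, 0), (1.0, 26), (23 / 26, 23)])
    def test_planted_motif_fraction_is_exact(self, fraction, expected):
        cohort = make_gpcr_cohort(CohortSpec(n_sequences=26, motif_fraction=fraction, seed=11))
        n_with = sum(
            bool(scan_motif(rec, BBSOME_RELAXED, cohort.windows[rec.id]))
            for rec in cohort.records
        )
        assert n_with == expected

    def test_labels_match_scan(self):
        cohort = make_gpcr_cohort(CohortSpec(n_sequences=30, motif_fraction=0.5, seed=12))
        for rec in cohort.records:
            hit = bool(scan_motif(rec, BBSOME_RELAXED, cohort.windows[rec.id]))
            assert hit == cohort.labels[rec.id]["has_motif"]

    def test_census_cohort_strict_and_relaxed_counts(self):
        cohort = make_census_cohort(n_total=26, n_strict=20, n_relaxed_only=3, seed=13)
        windows = {
            sid: _ann(sid, w) for sid, w in cohort.windows.items()
        }
        strict, n, _ = cohort_motif_census(cohort.records, BBSOME_STRICT, windows)
        relaxed, _, _ = cohort_motif_census(cohort.records, BBSOME_RELAXED, windows)
        assert (strict, relaxed, n) == (20, 23, 26)

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_sequences=5, alphabet_background={"A": 0.5, "C": 0.4})


class TestPhSiteFixture:
    def test_zero_clash_site_is_open(self):
        from ciliageom import assess_site

        query, template, env, truth = make_ph_site_fixture(0, seed=21)
        result = assess_site(query, "canonical", [template], env)
        assert result.verdict == "open"
        assert result.clash_count == 0

    def test_planted_clash_count_exact(self):
        from ciliageom import count_clashes, place_template_ligand

        query, template, env, truth = make_ph_site_fixture(12, seed=22)
        lig, rmsd = place_template_ligand(query, template)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        n, _ = count_clashes(lig, env, cutoff=truth["cutoff"])
        assert n == 12

    def test_tighter_cutoff_counts_no_more(self):
        from ciliageom import count_clashes, place_template_ligand

        query, template, env, truth = make_ph_site_fixture(3, seed=23)
        lig, _ = place_template_ligand(query, template)
        n_tight, _ = count_clashes(lig, env, cutoff=truth["cutoff"] - 0.5)
        assert n_tight <= 3


def _ann(sid, window):
    from ciliageom import Helix8Annotation

    return Helix8Annotation(sid, window[0], window[1])
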