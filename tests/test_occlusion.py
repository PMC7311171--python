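import numpy as np
import pytest

from ciliageom import (
    DomainSelection,
    GeometryError,
    PlaneModel,
    assess_site,
    count_clashes,
    place_template_ligand,
)
from ciliageom.geometry import RigidTransform
from ciliageom.occlusion import TemplateComplex
from ciliageom.structure import AtomRecord, StructureModel
from ciliageom.synthetic import make_ph_site_fixture


class TestPlaceTemplateLigand:
    def test_template_onto_itself_leaves_ligand_fixed(self):
        _, template, _, _ = make_ph_site_fixture(0, seed=1)
        lig, rmsd = place_template_ligand(template.ph_coords, template)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(lig, template.ligand_coords, atol=1e-9)

    def test_planted_transform_recovered(self):
        query, template, _, truth = make_ph_site_fixture(0, seed=2)
        lig, rmsd = place_template_ligand(query, template)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(lig, np.asarray(truth["ligand_true"]), atol=1e-6)

    def test_too_few_pairs_raise(self):
        _, template, _, _ = make_ph_site_fixture(0, seed=3)
        with pytest.raises(GeometryError):
            place_template_ligand(template.ph_coords[:10], template)

    def test_consistent_ligand_position_across_template_ensemble(self):
        # several templates of the same site, each jittered, place their
        # ligands within a tight cluster relative to the domain size
        query, base, _, _ = make_ph_site_fixture(0, seed=4)
        rng = np.random.default_rng(4)
        centroids = []
        for k in range(9):
            g = RigidTransform.about_axis(rng.normal(size=3), rng.uniform(5, 175),
                                          translation=rng.uniform(-15, 15, 3))
            jitter = rng.normal(scale=0.6, size=base.ligand_coords.shape)
            tpl = TemplateComplex(
                id=f"t{k}", site_label="canonical",
                ph_coords=g.apply(base.ph_coords),
                ligand_coords=g.apply(base.ligand_coords + jitter),
            )
            lig, _ = place_template_ligand(query, tpl)
            centroids.append(lig.mean(axis=0))
        spread = np.linalg.norm(np.asarray(centroids) - np.mean(centroids, axis=0), axis=1)
        domain_size = np.ptp(base.ph_coords, axis=0).max()
        assert spread.max() < 0.1 * domain_size


class TestCountClashes:
    def test_empty_environment_counts_zero(self):
        env = StructureModel([AtomRecord("C", "CA", (100.0, 100.0, 100.0), 1, "ALA", "E")])
        n, blocker = count_clashes(np.zeros((3, 3)), env, cutoff=3.0)
        assert (n, blocker) == (0, None)

    @pytest.mark.parametrize("planted", [0, 3, 12])
    def test_planted_counts_exact(self, planted):
        query, template, env, truth = make_ph_site_fixture(planted, seed=5 + planted)
        lig, _ = place_template_ligand(query, template)
        n, blocker = count_clashes(lig, env, cutoff=truth["cutoff"])
        assert n == planted
        assert (blocker is None) == (planted == 0)

    def test_monotone_in_cutoff(self):
        query, template, env, truth = make_ph_site_fixture(8, seed=6)
        lig, _ = place_template_ligand(query, template)
        counts = [count_clashes(lig, env, cutoff=c)[0] for c in (1.0, 2.0, 3.0, 5.0, 10.0)]
        assert counts == sorted(counts)

    def test_excluded_selection_not_counted(self):
        query, template, env, truth = make_ph_site_fixture(5, seed=7)
        lig, _ = place_template_ligand(query, template)
        n_all, _ = count_clashes(lig, env, cutoff=truth["cutoff"])
        n_excl, _ = count_clashes(
            lig, env, exclude=[DomainSelection("E", 1, 10**6)], cutoff=truth["cutoff"]
        )
        assert n_all == 5 and n_excl == 0


class TestAssessSite:
    def test_open_near_membrane(self):
        query, template, env, _ = make_ph_site_fixture(0, seed=8)
        lig, _ = place_template_ligand(query, template)
        centroid = lig.mean(axis=0)
        plane = PlaneModel([0, 0, 1], float(centroid[2] + 5.0), 3.0)
        result = assess_site(query, "canonical", [template], env, plane=plane)
        assert result.verdict == "open"
        assert result.membrane_distance == pytest.approx(5.0, abs=1e-6)

    def test_open_but_distant_beyond_threshold(self):
        query, template, env, _ = make_ph_site_fixture(0, seed=9)
        lig, _ = place_template_ligand(query, template)
        plane = PlaneModel([0, 0, 1], float(lig.mean(axis=0)[2] + 12.0), 3.0)
        result = assess_site(query, "canonical", [template], env, plane=plane,
                             distance_threshold=10.0)
        assert result.verdict == "distant"

    def test_any_clash_blocks_by_default(self):
        query, template, env, _ = make_ph_site_fixture(2, seed=10)
        result = assess_site(query, "canonical", [template], env)
        assert result.verdict == "blocked"
        assert result.clash_count >= 1
        assert result.nearest_blocker is not None

    def test_invariant_under_joint_rigid_motion(self):
        query, template, env, _ = make_ph_site_fixture(4, seed=11)
        g = RigidTransform.about_axis([2, -1, 1], 63.0, translation=[7, 8, -9])
        moved_query = query.transformed(g.rotation, g.translation)
        moved_env = env.transformed(g.rotation, g.translation)
        a = assess_site(query, "canonical", [template], env)
        b = assess_site(moved_query, "canonical", [template], moved_env)
        assert a.clash_count == b.clash_count
        assert a.verdict == b.verdict

    def test_median_insensitive_to_single_template_removal(self):
        query, base, env, truth = make_ph_site_fixture(6, seed=12)
        rng = np.random.default_rng(12)
        templates = []
        for k in range(9):
            g = RigidTransform.about_axis(rng.normal(size=3), rng.uniform(5, 175),
                                          translation=rng.uniform(-15, 15, 3))
            templates.append(TemplateComplex(
                id=f"t{k}", site_label="canonical",
                ph_coords=g.apply(base.ph_coords),
                ligand_coords=g.apply(base.ligand_coords),
            ))
        full = assess_site(query, "canonical", templates, env)
        spread = max(full.per_template_clashes) - min(full.per_template_clashes)
        for k in range(9):
            reduced = assess_site(query, "canonical", templates[:k] + templates[k + 1 :], env)
            assert abs(reduced.clash_count - full.clash_count) <= max(spread, 1)

    def test_missing_site_template_rejected(self):
        query, template, env, _ = make_ph_site_fixture(0, seed=13)
        with pytest.raises(ValueError):
            assess_site(query, "atypical", [template], env)
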