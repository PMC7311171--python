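import numpy as np
import pytest

from ciliageom import (
    AnchorSpec,
    CylinderModel,
    InfeasibilityReport,
    OrientationSearchConfig,
    PlaneModel,
    curvature_compatibility,
    membrane_facing_charge_census,
    min_patch_distance,
    place_membrane,
)
from ciliageom.structure import AtomRecord, SelectionError, StructureModel
from ciliageom.synthetic import HelixSpec, make_ideal_helix, make_membrane_complex_fixture


def _angle(u, v):
    return np.degrees(np.arccos(np.clip(abs(np.dot(u, v)), -1, 1)))


class TestPlaceMembrane:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_recovers_planted_plane(self, seed):
        rng = np.random.default_rng(seed + 500)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        plane = PlaneModel(n, float(rng.uniform(-20, 20)), 3.0)
        model, truth = make_membrane_complex_fixture(plane, seed=seed)
        anchor = AnchorSpec("A", 1, truth["anchor_range"][1])
        placed = place_membrane(model, anchor)
        assert not isinstance(placed, InfeasibilityReport)
        assert _angle(placed.normal, n) < 5.0
        assert abs(placed.offset - plane.offset) < 2.0

    def test_ideal_helix_own_anchor_plane_parallel_to_axis(self):
        helix = make_ideal_helix(HelixSpec(12))  # poly-Ala: no hydrophobic face
        anchor = AnchorSpec("A", 1, 12)
        placed = place_membrane(helix, anchor)
        assert not isinstance(placed, InfeasibilityReport)
        axis = np.array([0.0, 0.0, 1.0])
        assert abs(np.dot(placed.normal, axis)) < np.radians(1e-3)

    def test_unresolvable_anchor_raises(self):
        helix = make_ideal_helix(HelixSpec(12))
        with pytest.raises(SelectionError):
            place_membrane(helix, AnchorSpec("Z", 1, 12))

    def test_surrounded_helix_is_infeasible(self, rng):
        # a shell of atoms all around the anchor helix: every roll of the
        # plane leaves some atoms far beyond it
        helix = make_ideal_helix(HelixSpec(12))
        shell = []
        k = 0
        for _ in range(80):
            p = rng.normal(size=3)
            p = p / np.linalg.norm(p) * 25.0 + np.array([0, 0, 8.0])
            k += 1
            shell.append(AtomRecord("C", "CA", tuple(p), k, "ALA", "S"))
        model = StructureModel(list(helix.atoms) + shell)
        result = place_membrane(model, AnchorSpec("A", 1, 12))
        assert isinstance(result, InfeasibilityReport)
        assert result.min_max_penetration > result.penetration_tolerance

    def test_placement_invariant_under_rigid_motion(self, membrane_fixture):
        from ciliageom.geometry import RigidTransform

        model, truth, anchor = membrane_fixture
        placed = place_membrane(model, anchor)
        g = RigidTransform.about_axis([1, 2, 3], 55.0, translation=[10, -4, 6])
        moved = model.transformed(g.rotation, g.translation)
        placed_moved = place_membrane(moved, anchor)
        # the plane must co-move with the model (rigid equivalence)
        expected = placed.transformed(g)
        assert _angle(placed_moved.normal, expected.normal) < 0.5
        point = expected.offset * expected.normal
        assert abs(np.dot(placed_moved.normal, point) - placed_moved.offset) < 0.5


class TestMinPatchDistance:
    def test_anchor_patch_within_headgroup_depth(self, membrane_fixture):
        model, truth, anchor = membrane_fixture
        patch = model.subset(lambda a: a.chain_id == "A").coords()
        cfg = OrientationSearchConfig(patch_coords=patch)
        d, plane = min_patch_distance(model, anchor, cfg)
        assert d <= anchor.headgroup_depth + 2.3 + 1e-6  # depth + helix radius

    def test_grid_matches_dense_oracle(self, membrane_fixture):
        model, truth, anchor = membrane_fixture
        patch = model.subset(lambda a: a.chain_id == "B").coords()[:20]
        coarse_cfg = OrientationSearchConfig(angular_grid_step=2.0, patch_coords=patch)
        fine_cfg = OrientationSearchConfig(
            angular_grid_step=0.5, refinement="none", patch_coords=patch
        )
        d_coarse, _ = min_patch_distance(model, anchor, coarse_cfg)
        d_fine, _ = min_patch_distance(model, anchor, fine_cfg)
        assert abs(d_coarse - d_fine) <= 0.5

    def test_finer_grid_never_increases_minimum(self, membrane_fixture):
        model, truth, anchor = membrane_fixture
        patch = model.subset(lambda a: a.chain_id == "B").coords()[:20]
        results = []
        for step in (8.0, 4.0, 2.0):
            cfg = OrientationSearchConfig(angular_grid_step=step, refinement="none",
                                          patch_coords=patch)
            d, _ = min_patch_distance(model, anchor, cfg)
            results.append(d)
        # grids here are nested (8 ⊃ 4 ⊃ 2), so the minimum cannot rise
        assert results[1] <= results[0] + 1e-9
        assert results[2] <= results[1] + 1e-9

    def test_missing_patch_rejected(self, membrane_fixture):
        model, truth, anchor = membrane_fixture
        with pytest.raises(ValueError):
            min_patch_distance(model, anchor, OrientationSearchConfig())


class TestChargeCensus:
    def test_planted_counts_recovered(self, membrane_fixture):
        model, truth, anchor = membrane_fixture
        placed = place_membrane(model, anchor)
        census = membrane_facing_charge_census(model, placed, slab_depth=truth["charge_slab_depth"])
        assert (census.positive_count, census.negative_count) == (7, 2)
        assert census.net == 5

    def test_poly_lysine_helix_counts_all_positive(self):
        helix = make_ideal_helix(HelixSpec(10), residue_names="K" * 10)
        plane = PlaneModel([0, 0, 1], 30.0, 3.0)
        census = membrane_facing_charge_census(helix, plane, slab_depth=50.0)
        assert (census.positive_count, census.negative_count) == (10, 0)

    def test_slab_census_monotone_in_depth(self, membrane_fixture):
        model, truth, anchor = membrane_fixture
        placed = place_membrane(model, anchor)
        shallow = membrane_facing_charge_census(model, placed, slab_depth=3.0)
        deep = membrane_facing_charge_census(model, placed, slab_depth=12.0)
        assert shallow.positive_count <= deep.positive_count
        assert shallow.negative_count <= deep.negative_count

    def test_counts_bounded_by_residue_count(self, membrane_fixture):
        model, truth, anchor = membrane_fixture
        placed = place_membrane(model, anchor)
        census = membrane_facing_charge_census(model, placed, slab_depth=1e6)
        assert census.positive_count + census.negative_count <= model.n_residues()


class TestCurvature:
    def test_wide_cylinder_close_to_flat_plane(self, membrane_fixture):
        model, truth, anchor = membrane_fixture
        placed = place_membrane(model, anchor)
        heavy = model.coords()
        flat_count = int(np.sum(heavy @ placed.normal - placed.offset > 0))
        cyl = CylinderModel(np.zeros(3), np.array([1.0, 0, 0]), 1250.0)
        n_pen, frac, _ = curvature_compatibility(model, placed, cyl)
        assert abs(n_pen - flat_count) <= 1
        assert 0.0 <= frac <= 1.0

    def test_convex_surface_matching_radius_has_no_penetration(self):
        # points on a cylinder of the target radius, seen from inside
        R = 200.0
        ang = np.linspace(-0.3, 0.3, 25)
        pts = np.stack([np.zeros_like(ang), R * np.sin(ang), R * np.cos(ang) - R], axis=1)
        atoms = [AtomRecord("C", "CA", tuple(p), i + 1, "ALA", "A") for i, p in enumerate(pts)]
        model = StructureModel(atoms)
        plane = PlaneModel([0, 0, 1], 0.0)
        n_pen, _, _ = curvature_compatibility(
            model, plane, CylinderModel(np.zeros(3), np.array([1.0, 0, 0]), R),
            penetration_tolerance=1e-6,
        )
        assert n_pen == 0

    def test_concave_up_surface_penetrates(self):
        # surface curving away from the membrane interior pokes the wall
        R = 200.0
        y = np.linspace(-60, 60, 25)
        pts = np.stack([np.zeros_like(y), y, y**2 / (2 * 50.0)], axis=1)
        atoms = [AtomRecord("C", "CA", tuple(p), i + 1, "ALA", "A") for i, p in enumerate(pts)]
        model = StructureModel(atoms)
        plane = PlaneModel([0, 0, 1], 0.0)
        n_pen, _, _ = curvature_compatibility(
            model, plane, CylinderModel(np.zeros(3), np.array([1.0, 0, 0]), R)
        )
        assert n_pen > 0
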