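"""Elastic surface registration: correspondence rule, rigid SVD alignment,
stiffness-modulated elastic step and the full loop."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

import hippomorph as hm
from hippomorph.errors import ParameterError, RegistrationError
from hippomorph.registration import CorrespondenceSet, accept_correspondence


def _icosphere(radius, center=(0, 0, 0), sub=3):
    tm = trimesh.creation.icosphere(subdivisions=sub, radius=radius)
    return hm.SurfaceMesh(np.asarray(tm.vertices) + np.asarray(center, float),
                          np.asarray(tm.faces))


class TestCorrespondenceRule:
    def test_acceptance_predicate_dot_threshold(self):
        """The 60-degree tolerance is a strict dot-product > 0.5 test."""
        assert accept_correspondence(0.6, 0, 1.0)
        assert not accept_correspondence(0.5, 0, 1.0)  # boundary excluded
        assert not accept_correspondence(0.0, 0, 1.0)  # orthogonal normals
        assert not accept_correspondence(-1.0, 0, 1.0)

    def test_acceptance_predicate_blocking_intersections(self):
        """An earlier sheet of the target blocks the match."""
        assert not accept_correspondence(0.9, 1, 1.0)
        assert not accept_correspondence(0.9, 2, 1.0)

    def test_acceptance_predicate_max_ray_length(self):
        assert not accept_correspondence(0.9, 0, 5.0, max_ray_length=4.0)

    def test_self_correspondence(self, template_mesh):
        corr = hm.find_correspondences(template_mesh, template_mesh)
        assert corr.valid.all()
        assert np.allclose(corr.points, template_mesh.vertices, atol=1e-9)
        assert np.all(corr.weights == 1.0)

    def test_concentric_spheres_all_accepted_radial(self):
        src = _icosphere(4.0, center=(10, 10, 10))
        tgt = _icosphere(6.0, center=(10, 10, 10), sub=4)
        corr = hm.find_correspondences(src, tgt, hm.RegistrationConfig())
        assert corr.valid.mean() > 0.99
        d = np.linalg.norm(corr.points[corr.valid] - src.vertices[corr.valid], axis=1)
        assert np.allclose(d, 2.0, atol=0.05)

    def test_opposed_sheet_blocks_match(self):
        """A nearer sheet whose normal fails the dot test blocks the vertex:
        an inward-oriented inner sphere sits between the source and the
        well-aligned outer sphere."""
        src = _icosphere(4.0)
        outer = _icosphere(6.0, sub=4)
        inner = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        inner.invert()  # normals point toward the centre
        tgt = hm.SurfaceMesh(
            np.vstack([outer.vertices, np.asarray(inner.vertices)]),
            np.vstack([outer.faces, np.asarray(inner.faces) + outer.n_vertices]),
        )
        corr = hm.find_correspondences(src, tgt, hm.RegistrationConfig())
        assert corr.valid.mean() < 0.01
        assert np.all(corr.weights[~corr.valid] == 0.0)


class TestRigidAlign:
    def _corr(self, points):
        return CorrespondenceSet(points, np.ones(len(points), bool),
                                 np.ones(len(points)))

    def test_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        rig = hm.rigid_align(self._corr(pts), hm.SurfaceMesh(pts, np.zeros((0, 3), int)))
        assert np.allclose(rig.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(rig.translation, 0.0, atol=1e-9)

    def test_known_rotation_translation_recovery(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 3)) * 3
        r = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t = np.array([1.0, -2.0, 0.5])
        tgt = pts @ r.T + t
        rig = hm.rigid_align(self._corr(tgt), hm.SurfaceMesh(pts, np.zeros((0, 3), int)))
        assert np.abs(rig.rotation - r).max() < 1e-9
        assert np.abs(rig.translation - t).max() < 1e-9

    def test_mirrored_target_stays_proper(self):
        """Reflection is corrected to a proper rotation, with residual, and
        never beats the best proper rotation found by brute force."""
        from hippomorph.experiments import brute_force_rigid

        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rig = hm.rigid_align(self._corr(mirrored),
                             hm.SurfaceMesh(pts, np.zeros((0, 3), int)))
        assert np.linalg.det(rig.rotation) == pytest.approx(1.0, abs=1e-9)
        res = mirrored - rig.apply(pts)
        cost_svd = float((res**2).sum())
        assert cost_svd > 1e-6  # a reflection cannot be fit exactly
        _, _, cost_grid = brute_force_rigid(pts, mirrored)
        assert cost_svd <= cost_grid + 1e-9

    def test_degenerate_collinear_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.raises(RegistrationError, match="degenerate|collinear"):
            hm.rigid_align(self._corr(pts + np.array([0.5, 0, 0])),
                           hm.SurfaceMesh(pts, np.zeros((0, 3), int)))

    def test_oracle_equivalence_random_point_sets(self):
        """SVD solution matches the brute-force rotation-grid minimizer."""
        from hippomorph.experiments import rigid_align_oracle

        res = rigid_align_oracle(seed=3, n_configs=25)
        assert res["max_rotation_error"] < 1e-9
        assert res["max_translation_error"] < 1e-9
        assert res["max_cost_gap_vs_bruteforce"] <= 1e-9


class TestElasticStep:
    def test_all_weights_zero_is_identity(self, icosphere_pair):
        mesh = icosphere_pair[0]
        corr = CorrespondenceSet(
            np.full_like(mesh.vertices, np.nan),
            np.zeros(mesh.n_vertices, bool),
            np.zeros(mesh.n_vertices),
        )
        out = hm.elastic_step(mesh, corr, beta=2.0)
        assert np.allclose(out.vertices, mesh.vertices)

    @pytest.mark.parametrize("beta", [0.1, 1.0, 10.0])
    def test_uniform_translation_exact_for_any_beta(self, icosphere_pair, beta):
        mesh = icosphere_pair[0]
        v = np.array([0.3, -0.7, 1.1])
        corr = CorrespondenceSet(mesh.vertices + v,
                                 np.ones(mesh.n_vertices, bool),
                                 np.ones(mesh.n_vertices))
        out = hm.elastic_step(mesh, corr, beta=beta)
        assert np.allclose(out.vertices, mesh.vertices + v, atol=1e-9)

    def test_spread_increases_with_stiffness(self, icosphere_pair):
        mesh = icosphere_pair[0]
        pts = np.full_like(mesh.vertices, np.nan)
        valid = np.zeros(mesh.n_vertices, bool)
        valid[0] = True
        pts[0] = mesh.vertices[0] + mesh.vertex_normals()[0] * 1.0
        corr = CorrespondenceSet(pts, valid, valid.astype(float))

        def spread(beta):
            out = hm.elastic_step(mesh, corr, beta=beta)
            d = np.linalg.norm(out.vertices - mesh.vertices, axis=1)
            return int(np.sum(d > 0.1 * d.max()))

        assert spread(10.0) > spread(0.5)

    def test_nonpositive_beta_rejected(self, icosphere_pair):
        mesh = icosphere_pair[0]
        corr = CorrespondenceSet(mesh.vertices, np.ones(mesh.n_vertices, bool),
                                 np.ones(mesh.n_vertices))
        with pytest.raises(ParameterError):
            hm.elastic_step(mesh, corr, beta=0.0)


class TestRegister:
    def test_identity_converges_immediately(self, template_mesh):
        reg, err, rig = hm.register(template_mesh, template_mesh)
        assert err.mean < 1e-9
        assert np.allclose(rig.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(reg.vertices, template_mesh.vertices, atol=1e-9)

    def test_rigid_pair_recovery(self, bump_pair):
        source = bump_pair[0]
        r = Rotation.from_euler("zy", [8, -5], degrees=True).as_matrix()
        cen = source.centroid
        t_world = np.array([0.8, -0.5, 0.4])
        target = source.with_vertices((source.vertices - cen) @ r.T + cen + t_world)
        cfg = hm.RegistrationConfig(rigid_init_iterations=120)
        reg, err, rig = hm.register(source, target, cfg)
        # voxel diagonal / 10 for the desk grid is 0.061 mm
        assert err.mean < 0.061
        t_true = cen - r @ cen + t_world
        assert np.abs(rig.rotation - r).max() < 1e-3
        assert np.abs(rig.translation - t_true).max() < 1e-2

    def test_topology_preserved(self, bump_pair):
        source, target = bump_pair[0], bump_pair[1]
        reg, _, _ = hm.register(source, target)
        assert reg.n_vertices == source.n_vertices
        assert np.array_equal(reg.faces, source.faces)

    def test_error_history_non_increasing_late(self, bump_pair):
        source, target = bump_pair[0], bump_pair[1]
        _, err, _ = hm.register(source, target)
        tail = np.asarray(err.history[-10:])
        assert np.all(np.diff(tail) <= 1e-3)

    def test_rigid_motion_equivariance(self, bump_pair):
        source, target = bump_pair[0], bump_pair[1]
        cfg = hm.RegistrationConfig(n_iterations=15)
        _, err_a, _ = hm.register(source, target, cfg)
        g = Rotation.from_euler("x", 12, degrees=True).as_matrix()
        gs = source.with_vertices(source.vertices @ g.T + 1.5)
        gt = target.with_vertices(target.vertices @ g.T + 1.5)
        _, err_b, _ = hm.register(gs, gt, cfg)
        assert np.allclose(err_a.values, err_b.values, atol=1e-6)

    def test_planted_bump_recovery(self, bump_pair):
        source, target, effect, truth = bump_pair
        reg, err, _ = hm.register(source, target)
        recovered = np.einsum("vi,vi->v", reg.vertices - source.vertices,
                              source.vertex_normals())
        planted = truth.normal_displacement(source.vertices)
        assert np.corrcoef(recovered, planted)[0, 1] >= 0.9
        assert err.mean < 0.05


class TestAverageSurface:
    def test_identical_masks_average_equals_subjects(self, small_template):
        avg, registered = hm.build_average_surface(
            [small_template, small_template], reference_mask=small_template,
            decimate_to=500,
        )
        for reg in registered:
            assert np.abs(avg.vertices - reg.vertices).max() < 1e-6

    def test_concentric_spheres_average_radius(self):
        grid = hm.GridSpec((64, 64, 64), (0.25, 0.25, 0.25))
        masks = [hm.make_template_mask(grid, 0.0, 0.0, r) for r in (4.0, 6.0)]
        avg, _ = hm.build_average_surface(
            masks, reference_mask=masks[0], decimate_to=700,
            axial_spacing=0.25,
        )
        radii = np.linalg.norm(avg.vertices - grid.center, axis=1)
        assert np.mean(radii) == pytest.approx(5.0, rel=0.02)

    def test_order_invariance_with_designated_reference(self, small_grid):
        cohort = hm.make_cohort(
            small_grid, n_per_group=3, subject_noise=0.1, seed=2, groups=("A",),
            mesh_vertices=500,
            template_kwargs={"curvature": 0.08, "length": 9.0, "radius": 1.6},
        )
        masks = [s.mask for s in cohort.subjects]
        kw = dict(reference_mask=cohort.template_mask, decimate_to=500)
        avg1, _ = hm.build_average_surface(masks, **kw)
        avg2, _ = hm.build_average_surface(masks[::-1], **kw)
        assert np.linalg.norm(avg1.vertices - avg2.vertices, axis=1).max() < 0.05
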