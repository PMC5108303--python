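"""TBM arm: rigid template, demons registration, Jacobian maps, mask
propagation and voxel-wise statistics."""

import numpy as np
import pytest
from scipy import ndimage

import hippomorph as hm
from hippomorph.errors import ValidationError
from hippomorph.stats import StatsConfig
from hippomorph.synthetic import radial_expansion_field
from hippomorph.tbm import DeformationField, invert_field
from hippomorph.volume import GridSpec, ImageVolume


@pytest.fixture(scope="module")
def tbm_grid():
    return GridSpec((48, 48, 20), (0.4, 0.4, 0.8))


@pytest.fixture(scope="module")
def tbm_template(tbm_grid):
    return hm.make_template_mask(tbm_grid, curvature=0.08, length=8.0, radius=1.5)


@pytest.fixture(scope="module")
def textured_pair(tbm_grid, tbm_template):
    """Template texture and the same texture warped by a known smooth field."""
    rng = np.random.default_rng(0)
    tex = ndimage.gaussian_filter(rng.standard_normal(tbm_grid.shape), 1.5)
    tex = tex / tex.std() + 1.5 * ndimage.gaussian_filter(
        tbm_template.data.astype(float), 1.0
    )
    center = tuple(tbm_grid.center)
    true = radial_expansion_field(tbm_grid, center, 4.0, 0.12)
    inv = invert_field(true)
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in tbm_grid.shape],
                               indexing="ij"), axis=-1).astype(float)
    coords = idx + inv.displacement / np.asarray(tbm_grid.spacing)
    warped = ndimage.map_coordinates(tex, coords.reshape(-1, 3).T, order=1,
                                     mode="nearest").reshape(tbm_grid.shape)
    to_vol = lambda a: ImageVolume(a, tbm_grid.spacing, tbm_grid.origin)
    return to_vol(tex), to_vol(warped), true


class TestJacobian:
    def test_identity_field(self, tbm_grid):
        fld = DeformationField(np.zeros(tbm_grid.shape + (3,)), tbm_grid.spacing)
        jac = hm.jacobian_map(fld, None)
        assert np.allclose(jac.det, 1.0, atol=1e-12)
        assert np.allclose(jac.log_det, 0.0, atol=1e-12)

    def test_uniform_scaling_det_s_cubed(self, tbm_grid):
        s = 1.07
        xs, ys, zs = tbm_grid.world_axes()
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        u = (s - 1.0) * np.stack([gx, gy, gz], axis=-1)
        jac = hm.jacobian_map(DeformationField(u, tbm_grid.spacing), None)
        interior = jac.det[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, s**3, atol=1e-6)

    def test_matches_simpleitk_oracle(self, tbm_grid):
        """Central-difference determinant agrees with SimpleITK's
        displacement-field Jacobian filter on a smooth random field."""
        import SimpleITK as sitk

        rng = np.random.default_rng(3)
        u = np.stack(
            [ndimage.gaussian_filter(rng.standard_normal(tbm_grid.shape), 3.0)
             for _ in range(3)], axis=-1,
        ) * 1.5
        mine = hm.jacobian_map(DeformationField(u, tbm_grid.spacing), None).det
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(u.transpose(2, 1, 0, 3)), isVector=True
        )
        img.SetSpacing(tbm_grid.spacing)
        theirs = sitk.GetArrayFromImage(
            sitk.DisplacementFieldJacobianDeterminant(img)
        ).transpose(2, 1, 0)
        interior = (slice(2, -2),) * 3
        assert np.allclose(mine[interior], theirs[interior], atol=5e-3)

    def test_chain_rule_composition(self, tbm_grid):
        """Jacobian of a composed field approximates the product of the
        Jacobians where both fields are smooth."""
        c = tuple(tbm_grid.center)
        f1 = radial_expansion_field(tbm_grid, c, 5.0, 0.05)
        f2 = radial_expansion_field(tbm_grid, c, 5.0, 0.04)
        idx = np.stack(np.meshgrid(*[np.arange(s) for s in tbm_grid.shape],
                                   indexing="ij"), axis=-1).astype(float)
        sp = np.asarray(tbm_grid.spacing)
        coords = idx + f2.displacement / sp
        u1_at = np.stack(
            [ndimage.map_coordinates(f1.displacement[..., k],
                                     coords.reshape(-1, 3).T, order=1,
                                     mode="nearest").reshape(tbm_grid.shape)
             for k in range(3)], axis=-1)
        comp = DeformationField(f2.displacement + u1_at, tbm_grid.spacing)
        j_comp = hm.jacobian_map(comp, None).det
        j_prod = hm.jacobian_map(f1, None).det * hm.jacobian_map(f2, None).det
        interior = (slice(4, -4),) * 3
        ratio = j_comp[interior] / j_prod[interior]
        assert np.abs(ratio - 1.0).max() < 0.05


class TestFieldInversionAndPropagation:
    def test_identity_propagation(self, tbm_grid, tbm_template):
        fld = DeformationField.identity(
            ImageVolume(np.zeros(tbm_grid.shape), tbm_grid.spacing)
        )
        out = hm.propagate_mask(tbm_template, fld)
        assert np.array_equal(out.data, tbm_template.data)

    def test_translation_field(self, tbm_grid, tbm_template):
        shift = np.array([0.8, -0.4, 0.8])  # two voxels in x, one in y and z
        u = np.tile(shift, tbm_grid.shape + (1,))
        out = hm.propagate_mask(tbm_template, DeformationField(u, tbm_grid.spacing))
        # mask_subj(y) = mask_template(y - shift): shifted by +shift in world
        ivox = np.round(shift / np.asarray(tbm_grid.spacing)).astype(int)
        expected = np.roll(tbm_template.data, ivox, axis=(0, 1, 2))
        agree = (out.data == expected).mean()
        assert agree > 0.99  # nearest-neighbour edge voxels may differ

    def test_inverse_consistency(self, tbm_grid):
        fld = radial_expansion_field(tbm_grid, tuple(tbm_grid.center), 4.0, 0.08)
        from hippomorph.tbm import _inversion_residual

        resid = _inversion_residual(fld, invert_field(fld))
        assert resid < 0.25 * min(tbm_grid.spacing)


_DEMONS_KW = dict(smoothing_sigma=1.5, iterations_per_level=60,
                  presmooth_sigma_vox=0.5)


class TestDemons:
    def test_identical_images_zero_field(self, textured_pair, tbm_grid):
        tmpl = textured_pair[0]
        fld = hm.nonrigid_register(tmpl, tmpl, **_DEMONS_KW)
        assert np.abs(fld.displacement).max() < 0.05 * min(tbm_grid.spacing)

    def test_known_warp_recovery(self, textured_pair, tbm_template, tbm_grid):
        tmpl, warped, true = textured_pair
        fld = hm.nonrigid_register(tmpl, warped, **_DEMONS_KW)
        mask = tbm_template.data.astype(bool)
        err = np.linalg.norm(
            fld.displacement[mask] - true.displacement[mask], axis=-1
        )
        assert err.mean() < 0.5 * min(tbm_grid.spacing)

    def test_recovered_field_diffeomorphic(self, textured_pair):
        tmpl, warped, _ = textured_pair
        fld = hm.nonrigid_register(tmpl, warped, **_DEMONS_KW)
        jac = hm.jacobian_map(fld, None)
        assert (jac.det > 0).all()

    def test_residual_reduction_vs_rigid_only(self, textured_pair, tbm_template):
        tmpl, warped, _ = textured_pair
        fld = hm.nonrigid_register(tmpl, warped, **_DEMONS_KW)
        mask = tbm_template.data.astype(bool)
        idx = np.stack(np.meshgrid(*[np.arange(s) for s in tmpl.shape],
                                   indexing="ij"), axis=-1).astype(float)
        coords = idx + fld.displacement / np.asarray(tmpl.spacing)
        resampled = ndimage.map_coordinates(
            warped.data, coords.reshape(-1, 3).T, order=1, mode="nearest"
        ).reshape(tmpl.shape)
        before = ((tmpl.data - warped.data) ** 2)[mask].mean()
        after = ((tmpl.data - resampled) ** 2)[mask].mean()
        assert after < 0.5 * before


class TestRigidTemplate:
    def test_identical_inputs_reproduce_input(self, tbm_template):
        out = hm.build_rigid_template([tbm_template, tbm_template], n_iterations=1)
        assert np.allclose(out.data, tbm_template.data, atol=1e-6)

    def test_translated_pair_recovers_shift(self, tbm_template, tbm_grid):
        shifted = ImageVolume(np.roll(tbm_template.data, (2, 0, 0), axis=(0, 1, 2)),
                              tbm_grid.spacing)
        from hippomorph.tbm import _rigid_register_pair, _to_sitk

        tf = _rigid_register_pair(_to_sitk(tbm_template, 1.0), _to_sitk(shifted, 1.0))
        params = np.asarray(tf.GetParameters())
        # Euler3D: 3 rotations then 3 translations; moving-to-fixed maps the
        # shifted image back, so t_x should be ~ +2 voxels * 0.4 mm
        assert abs(params[3] - 0.8) < 0.5 * tbm_grid.spacing[0]

    def test_order_invariance(self, tbm_grid, tbm_template):
        rng = np.random.default_rng(0)
        vols = []
        for k in range(3):
            data = ndimage.gaussian_filter(
                tbm_template.data.astype(float), 1.0
            ) + 0.05 * rng.standard_normal(tbm_grid.shape)
            vols.append(ImageVolume(data, tbm_grid.spacing))
        a = hm.build_rigid_template(vols, n_iterations=1)
        b = hm.build_rigid_template(vols[::-1], n_iterations=1)
        rms = np.sqrt(np.mean((a.data - b.data) ** 2))
        rng_range = a.data.max() - a.data.min()
        assert rms < 0.01 * rng_range


class TestVoxelStats:
    def _jac(self, log_det, mask):
        from hippomorph.tbm import JacobianMap

        return JacobianMap(det=np.exp(log_det), log_det=log_det, mask=mask)

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        mask = np.ones((6, 6, 4), bool)
        base = rng.normal(size=(4,) + mask.shape) * 0.05
        jacobians = [self._jac(base[i % 4], mask) for i in range(8)]
        res = hm.voxelwise_group_stats(jacobians, ["A"] * 4 + ["B"] * 4,
                                       StatsConfig(seed=0))
        assert not res.pairwise[("A", "B")]["significant"].any()

    def test_null_calibration_uncorrected(self):
        """Uncorrected per-voxel rejection rate ~ alpha under the null."""
        rng = np.random.default_rng(1)
        mask = np.ones((8, 8, 4), bool)
        rejections, trials = 0, 0
        for _ in range(200):
            jacobians = [
                self._jac(0.05 * rng.standard_normal(mask.shape), mask)
                for _ in range(8)
            ]
            res = hm.voxelwise_group_stats(jacobians, ["A"] * 4 + ["B"] * 4,
                                           StatsConfig(seed=0))
            rejections += int(res.pairwise[("A", "B")]["uncorrected"].sum())
            trials += int(mask.sum())
        rate = rejections / trials
        half = 1.96 * np.sqrt(0.05 * 0.95 / trials)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_planted_expansion_detected_with_sign(self):
        rng = np.random.default_rng(2)
        mask = np.ones((10, 10, 4), bool)
        blob = np.zeros(mask.shape)
        blob[3:7, 3:7, 1:3] = 0.1
        jacobians, labels = [], []
        for g, offset in (("A", 0.0), ("B", 1.0)):
            for _ in range(8):
                ld = offset * blob + 0.02 * rng.standard_normal(mask.shape)
                jacobians.append(self._jac(ld, mask))
                labels.append(g)
        res = hm.voxelwise_group_stats(jacobians, labels, StatsConfig(seed=0))
        pair = res.pairwise[("A", "B")]
        sig = pair["significant"]
        truth = blob[mask] > 0
        dice = 2 * np.sum(sig & truth) / (sig.sum() + truth.sum())
        assert dice >= 0.5
        assert np.all(pair["t"][sig & truth] < 0)  # B larger -> negative t

    def test_mismatched_masks_rejected(self):
        m1 = np.ones((4, 4, 2), bool)
        m2 = m1.copy()
        m2[0, 0, 0] = False
        with pytest.raises(ValidationError):
            hm.voxelwise_group_stats(
                [self._jac(np.zeros(m1.shape), m1),
                 self._jac(np.zeros(m2.shape), m2)] * 2,
                ["A", "B", "A", "B"], StatsConfig(seed=0),
            )
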