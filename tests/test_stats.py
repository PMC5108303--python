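"""Vertex-wise statistics: displacements, unit-volume normalization,
Hotelling's T2, subject-level permutation testing and BH-FDR."""

import numpy as np
import pytest
import trimesh

import hippomorph as hm
from hippomorph.errors import ValidationError
from hippomorph.experiments import brute_force_bh
from hippomorph.stats import StatsConfig


@pytest.fixture(scope="module")
def unit_sphere():
    tm = trimesh.creation.icosphere(subdivisions=3, radius=3.0)
    return hm.SurfaceMesh(np.asarray(tm.vertices) + 5.0, np.asarray(tm.faces))


class TestDisplacements:
    def test_identical_subject_gives_zero_vectors(self, unit_sphere):
        disp = hm.displacement_vectors(unit_sphere, [unit_sphere, unit_sphere],
                                       ["A", "B"])
        assert np.all(disp.vectors == 0.0)

    def test_uniform_inflation_closed_form(self, unit_sphere):
        s = 1.17
        c = unit_sphere.centroid
        inflated = unit_sphere.with_vertices(c + s * (unit_sphere.vertices - c))
        disp = hm.displacement_vectors(unit_sphere, [inflated], ["A"])
        expected = (s - 1.0) * (unit_sphere.vertices - c)
        assert np.allclose(disp.vectors[0], expected, atol=1e-9)

    def test_topology_mismatch_rejected(self, unit_sphere):
        other = trimesh.creation.icosphere(subdivisions=2, radius=3.0)
        bad = hm.SurfaceMesh(np.asarray(other.vertices), np.asarray(other.faces))
        with pytest.raises(ValidationError):
            hm.displacement_vectors(unit_sphere, [bad], ["A"])

    def test_planted_vertex_effect_amplitude(self, unit_sphere):
        """Group-B mean vector at the bump centre recovers the planted
        amplitude within 10% (noise-free vertex cohort)."""
        v = unit_sphere.vertices
        center = tuple(v[np.argmax(v[:, 2])])
        eff = hm.EffectSpec(center, 2.0, 0.4, "B")
        meshes, labels, _ = hm.make_vertex_cohort(
            unit_sphere, (eff,), n_per_group=4, subject_noise=0.0, seed=0,
            isotropic_jitter=0.0,
        )
        disp = hm.displacement_vectors(unit_sphere, meshes, labels)
        xb = disp.vectors[np.array(labels) == "B"]
        i = int(np.argmax(v[:, 2]))
        length = np.linalg.norm(xb.mean(axis=0)[i])
        assert length == pytest.approx(0.4, rel=0.10)
        normal_comp = xb.mean(axis=0)[i] @ unit_sphere.vertex_normals()[i]
        assert normal_comp > 0


class TestNormalizeVolume:
    def test_unit_volume_mesh_unchanged(self, unit_sphere):
        once = hm.normalize_volume(unit_sphere)
        twice = hm.normalize_volume(once)
        assert np.allclose(once.vertices, twice.vertices, atol=1e-9)
        assert hm.mesh_volume(once) == pytest.approx(1.0, rel=1e-9)

    def test_cube_side_two(self):
        box = trimesh.creation.box(extents=(2.0, 2.0, 2.0))
        mesh = hm.SurfaceMesh(np.asarray(box.vertices), np.asarray(box.faces))
        out = hm.normalize_volume(mesh)
        assert hm.mesh_volume(out) == pytest.approx(1.0, rel=1e-9)
        extent = out.vertices.max(0) - out.vertices.min(0)
        assert np.allclose(extent, 1.0, atol=1e-12)

    def test_scale_invariance_after_centroid_alignment(self, unit_sphere):
        big = unit_sphere.with_vertices(
            unit_sphere.centroid + 2.7 * (unit_sphere.vertices - unit_sphere.centroid)
        )
        a = hm.normalize_volume(unit_sphere)
        b = hm.normalize_volume(big)
        da = a.vertices - a.centroid
        db = b.vertices - b.centroid
        assert np.abs(da - db).max() < 1e-9


class TestHotellingT2:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 3))
        assert hm.hotelling_t2(x, x.copy(), ridge=1e-9) == pytest.approx(0.0, abs=1e-9)

    def test_reduces_to_t_squared_in_1d(self):
        rng = np.random.default_rng(1)
        a1 = rng.normal(size=8)
        b1 = rng.normal(size=8) + 1.2
        a = np.column_stack([a1, np.zeros(8), np.zeros(8)])
        b = np.column_stack([b1, np.zeros(8), np.zeros(8)])
        t2 = hm.hotelling_t2(a, b, ridge=1e-12)
        from scipy import stats as sps

        t, _ = sps.ttest_ind(a1, b1)
        assert t2 == pytest.approx(t**2, rel=1e-6)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3)) + np.array([0.5, -0.2, 0.1])
        r = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        t2 = hm.hotelling_t2(a, b, ridge=0.0)
        t2r = hm.hotelling_t2(a @ r.T, b @ r.T, ridge=0.0)
        assert t2r == pytest.approx(t2, rel=1e-9)

    def test_singular_covariance_instructs_ridge(self):
        from hippomorph.errors import NumericalError

        a = np.zeros((4, 3))
        b = np.zeros((4, 3))
        b[:, 0] = 1.0
        with pytest.raises(NumericalError, match="ridge"):
            hm.hotelling_t2(a, b, ridge=0.0)


class TestPermutationTest:
    def _displacements(self, rng, n_per_group, n_vertices, effect=0.0):
        tm = trimesh.creation.icosphere(subdivisions=1)  # 42 vertices
        mesh = hm.SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
        n_vertices = mesh.n_vertices
        x = rng.normal(size=(2 * n_per_group, n_vertices, 3))
        x[n_per_group:, : n_vertices // 4, 0] += effect
        return hm.DisplacementSet(x, ["A"] * n_per_group + ["B"] * n_per_group, mesh)

    def test_exact_enumeration_for_tiny_n(self):
        rng = np.random.default_rng(0)
        disp = self._displacements(rng, 4, 42, effect=2.0)
        res = hm.permutation_test(disp, "A", "B", StatsConfig(n_permutations=100, seed=0))
        assert res.metadata["exact"]
        assert res.metadata["n_permutations"] == 70  # C(8,4)
        # p-values are multiples of 1/70
        assert np.allclose(np.round(res.p * 70) - res.p * 70, 0.0, atol=1e-9)
        assert res.p.min() >= 1.0 / 70

    def test_seed_reproducibility_and_stability(self):
        rng = np.random.default_rng(1)
        disp = self._displacements(rng, 8, 42, effect=3.0)
        r1 = hm.permutation_test(disp, "A", "B", StatsConfig(n_permutations=5000, seed=3))
        r2 = hm.permutation_test(disp, "A", "B", StatsConfig(n_permutations=5000, seed=3))
        r3 = hm.permutation_test(disp, "A", "B", StatsConfig(n_permutations=5000, seed=4))
        assert np.array_equal(r1.p, r2.p)
        assert not np.array_equal(r1.p, r3.p)
        inter = np.sum(r1.significant & r3.significant)
        union = r1.significant.sum() + r3.significant.sum()
        assert union > 0 and 2 * inter / union > 0.9

    def test_q_values_dominate_p_values(self):
        rng = np.random.default_rng(2)
        disp = self._displacements(rng, 6, 42, effect=1.0)
        res = hm.permutation_test(disp, "A", "B", StatsConfig(n_permutations=500, seed=0))
        assert np.all(res.q >= res.p - 1e-12)
        assert np.all(res.significant <= (res.q <= 0.05))


class TestFDR:
    def test_all_ones(self):
        q, sig = hm.fdr_correct(np.ones(10), 0.05)
        assert not sig.any()
        assert np.all(q == 1.0)

    def test_hand_worked_step_up(self):
        # p_(4) = 0.05 <= 4 * 0.05 / 4, so all four are significant
        q, sig = hm.fdr_correct(np.array([0.01, 0.02, 0.04, 0.05]), 0.05)
        assert sig.all()

    def test_brute_force_oracle_equivalence(self):
        from hippomorph.experiments import fdr_oracle_check

        out = fdr_oracle_check(seed=0, n_vectors=1000)
        assert out["mismatches"] == 0

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(1e-5, 1, size=int(rng.integers(3, 80)))
            q, sig = hm.fdr_correct(p, 0.05)
            sm_sig, sm_q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.allclose(q, sm_q, atol=1e-12)
            assert np.array_equal(sig, sm_sig)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            hm.fdr_correct(np.array([]), 0.05)


class TestSignedMap:
    def _disp(self, vectors, labels, mesh):
        return hm.DisplacementSet(vectors, labels, mesh)

    def test_identical_groups_zero_and_antisymmetry(self, unit_sphere):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, unit_sphere.n_vertices, 3))
        labels = ["A"] * 3 + ["B"] * 3
        disp = self._disp(x, labels, unit_sphere)
        ab = hm.signed_displacement_map(disp, "A", "B")
        ba = hm.signed_displacement_map(disp, "B", "A")
        assert np.allclose(ab, -ba, atol=1e-12)
        same = self._disp(np.concatenate([x[:3], x[:3]]), labels, unit_sphere)
        assert np.allclose(hm.signed_displacement_map(same, "A", "B"), 0.0)

    def test_outward_effect_positive_within_support(self, unit_sphere):
        v = unit_sphere.vertices
        center = tuple(v[np.argmax(v[:, 2])])
        eff = hm.EffectSpec(center, 2.0, 0.3, "B")
        meshes, labels, truth = hm.make_vertex_cohort(
            unit_sphere, (eff,), n_per_group=4, subject_noise=0.0, seed=0,
            isotropic_jitter=0.0,
        )
        disp = hm.displacement_vectors(unit_sphere, meshes, labels)
        signed = hm.signed_displacement_map(disp, "A", "B")
        sup = np.abs(truth["B"]) > 0.05
        assert np.all(signed[sup] > 0)
        assert np.max(np.abs(signed)) <= 0.3 + 1e-6


class TestNullCalibrationAndMonotonicity:
    def test_null_fdr_control(self):
        """Empirical FDP over null simulations stays within q + 2 MC s.e."""
        from hippomorph.stats import _t2_batch, _relabelings

        rng = np.random.default_rng(7)
        n_sims, fdp = 200, []
        for _ in range(n_sims):
            x = rng.standard_normal((12, 30, 3))
            obs = _t2_batch(x[:6], x[6:], None)
            labelings, exact = _relabelings(6, 6, 400, rng)
            exceed = np.zeros(30)
            for la in labelings:
                m = np.zeros(12, bool)
                m[la] = True
                exceed += _t2_batch(x[m], x[~m], None) >= obs - 1e-12
            p = exceed / len(labelings) if exact else (1 + exceed) / (len(labelings) + 1)
            _, sig = hm.fdr_correct(np.clip(p, 1e-12, 1), 0.05)
            fdp.append(1.0 if sig.any() else 0.0)
        mc_se = np.sqrt(0.05 * 0.95 / n_sims)
        assert np.mean(fdp) <= 0.05 + 2 * mc_se

    def test_significant_count_monotone_in_amplitude(self, unit_sphere):
        v = unit_sphere.vertices
        center = tuple(v[np.argmax(v[:, 2])])
        counts = []
        for amp in (0.1, 0.25, 0.5):
            eff = hm.EffectSpec(center, 2.0, amp, "B")
            meshes, labels, _ = hm.make_vertex_cohort(
                unit_sphere, (eff,), n_per_group=8, subject_noise=0.05, seed=11,
            )
            disp = hm.displacement_vectors(
                unit_sphere.with_vertices(
                    np.mean([m.vertices for m in meshes], axis=0)
                ),
                meshes, labels,
            )
            res = hm.permutation_test(disp, "A", "B",
                                      StatsConfig(n_permutations=2000, seed=1))
            counts.append(int(res.significant.sum()))
        assert counts[0] <= counts[1] <= counts[2]
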