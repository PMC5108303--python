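import numpy as np
import pytest

import hippomorph as hm


@pytest.fixture(scope="session")
def desk_grid():
    return hm.desk_grid()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse grid for fast end-to-end tests."""
    return hm.GridSpec((64, 64, 24), (0.35, 0.35, 0.7))


@pytest.fixture(scope="session")
def template_mask(desk_grid):
    return hm.make_template_mask(desk_grid)


@pytest.fixture(scope="session")
def small_template(small_grid):
    return hm.make_template_mask(small_grid, curvature=0.08, length=9.0, radius=1.6)


@pytest.fixture(scope="session")
def template_mesh(template_mask):
    sdf = hm.interslice_distance_interpolation(template_mask, 0.25)
    return hm.extract_surface(sdf, decimate_to=1300)


@pytest.fixture(scope="session")
def sphere_mask():
    grid = hm.GridSpec((56, 56, 56), (0.25, 0.25, 0.25))
    return hm.make_template_mask(grid, curvature=0.0, length=0.0, radius=5.0)


@pytest.fixture(scope="session")
def icosphere_pair():
    """Two concentric sphere meshes (radii 4 and 6 mm) sharing a centre."""
    import trimesh

    center = np.array([10.0, 10.0, 10.0])
    meshes = []
    for r in (4.0, 6.0):
        tm = trimesh.creation.icosphere(subdivisions=3, radius=r)
        meshes.append(hm.SurfaceMesh(np.asarray(tm.vertices) + center,
                                     np.asarray(tm.faces)))
    return meshes


@pytest.fixture(scope="session")
def bump_pair(template_mask):
    """Template surface plus an exactly known 0.4 mm outward bump target."""
    from hippomorph.synthetic import deformed_level_set

    source = hm.extract_surface(deformed_level_set(template_mask, []),
                                decimate_to=1300)
    v = source.vertices
    center = tuple(v[np.argmax(v[:, 1])])
    effect = hm.EffectSpec(center, 2.5, 0.4, "")
    _, truth = hm.apply_local_deformation(template_mask, effect)
    target = hm.extract_surface(deformed_level_set(template_mask, [effect]),
                                decimate_to=2600)
    return source, target, effect, truth
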