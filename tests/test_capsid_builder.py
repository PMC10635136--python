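"""The 3-D Caspar-Klug construction: icosahedron scaffold, symmetry
axes, site counts, icosahedral-group invariance, and the facet mesh."""

import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from capsidlattice import (
    InvalidStepError,
    build_capsid,
    build_icosahedron,
    enumerate_t_numbers,
    facet_mesh,
    symmetry_axes,
)


class TestIcosahedron:
    def test_euler_characteristic(self, ico):
        assert len(ico.vertices) == 12
        assert len(ico.faces) == 20
        assert len(ico.edges) == 30
        assert 12 - 30 + 20 == 2

    def test_vertices_unit_norm_and_edges_equal(self, ico):
        assert np.allclose(np.linalg.norm(ico.vertices, axis=1), 1.0, atol=1e-12)
        lengths = np.linalg.norm(
            ico.vertices[ico.edges[:, 0]] - ico.vertices[ico.edges[:, 1]], axis=1
        )
        assert np.allclose(lengths, lengths[0], rtol=1e-9)

    def test_faces_wound_outward(self, ico):
        for a, b, c in ico.faces:
            n = np.cross(ico.vertices[b] - ico.vertices[a],
                         ico.vertices[c] - ico.vertices[a])
            assert np.dot(n, ico.vertices[[a, b, c]].mean(axis=0)) > 0

    def test_vertex_set_closed_under_coordinate_rotations(self, ico):
        tree = cKDTree(ico.vertices)
        for axis in np.eye(3):
            rot = Rotation.from_rotvec(np.pi * axis).as_matrix()
            d, _ = tree.query(ico.vertices @ rot.T)
            assert np.max(d) < 1e-9


class TestSymmetryAxes:
    def test_axis_counts(self, ico):
        axes = symmetry_axes(ico)
        counts = {o: sum(1 for a in axes if a.order == o) for o in (5, 3, 2)}
        assert counts == {5: 6, 3: 10, 2: 15}
        for a in axes:
            assert np.isclose(np.linalg.norm(a.direction), 1.0, atol=1e-12)

    def test_threefold_axes_parallel_to_face_centroids(self, ico):
        centroids = ico.vertices[ico.faces].mean(axis=1)
        centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
        for a in symmetry_axes(ico):
            if a.order == 3:
                cosangles = np.abs(centroids @ a.direction)
                assert np.max(cosangles) > 1 - 1e-12

    def test_fivefold_rotation_maps_vertices_to_vertices(self, ico):
        tree = cKDTree(ico.vertices)
        axis = next(a for a in symmetry_axes(ico) if a.order == 5)
        rot = Rotation.from_rotvec(2 * np.pi / 5 * axis.direction).as_matrix()
        d, _ = tree.query(ico.vertices @ rot.T)
        assert np.max(d) < 1e-9


class TestBuildCapsid:
    @pytest.mark.parametrize("step, n_total", [
        ((2, 1), 72),   # T=7
        ((1, 0), 12),   # T=1
        ((2, 2), 122),  # T=12
    ])
    def test_site_counts_examples(self, capsid, step, n_total):
        c = capsid(*step)
        assert len(c.sites) == n_total == 10 * c.T + 2
        assert len(c.pentamers) == 12
        assert len(c.hexamers) == 10 * (c.T - 1)

    @pytest.mark.parametrize(
        "step", [r.representations[0] for r in enumerate_t_numbers(52)]
    )
    def test_site_counts_all_t_up_to_52(self, capsid, step):
        c = capsid(*step)
        assert len(c.pentamers) == 12
        assert len(c.hexamers) == 10 * (c.T - 1)

    def test_pentamers_at_vertices_only(self, capsid):
        c = capsid(3, 1)
        vert_tree = cKDTree(c.icosahedron.vertices * c.radius)
        for s in c.sites:
            d, _ = vert_tree.query(s.position)
            assert (d < 1e-6 * c.radius) == (s.kind == "pentamer")

    @pytest.mark.parametrize("step", [(2, 1), (2, 2), (3, 1)])
    def test_icosahedral_group_invariance(self, capsid, step):
        c = capsid(*step)
        pos = c.positions
        tree = cKDTree(pos)
        rotations = _icosahedral_rotations(c.icosahedron)
        assert len(rotations) == 60
        for rot in rotations:
            d, _ = tree.query(pos @ rot.T)
            assert np.max(d) < 1e-6 * c.radius

    def test_handedness_mirror(self, capsid):
        laevo = capsid(3, 1)
        dextro = capsid(3, 1, "dextro")
        mirrored = laevo.positions * np.array([-1.0, 1.0, 1.0])
        d, _ = cKDTree(dextro.positions).query(mirrored)
        assert np.max(d) < 1e-9 * laevo.radius
        assert len(dextro.pentamers) == 12
        assert len(dextro.hexamers) == len(laevo.hexamers)
        # a chiral capsid is not superimposable on its mirror image
        d, _ = cKDTree(dextro.positions).query(laevo.positions)
        assert np.max(d) > 1e-2 * laevo.radius

    def test_min_site_distance_scales_as_radius_over_sqrt_t(self, capsid):
        for step in [(1, 1), (2, 1), (4, 2), (5, 3)]:
            c = capsid(*step)
            d, _ = cKDTree(c.positions).query(c.positions, k=2)
            dmin = d[:, 1].min()
            assert dmin > 0
            # nearest capsomers are ~ one lattice spacing apart
            assert 0.3 < dmin * np.sqrt(c.T) / c.radius < 1.2

    def test_invalid_inputs(self):
        with pytest.raises(InvalidStepError):
            build_capsid((0, 0))
        with pytest.raises(InvalidStepError):
            build_capsid((2, 1), radius=-1.0)
        with pytest.raises(InvalidStepError):
            build_capsid((2, 1), handedness="left")


def _icosahedral_rotations(ico):
    """The 60 proper rotations, generated from the symmetry axes."""
    rots = [np.eye(3)]
    for axis in symmetry_axes(ico):
        for m in range(1, axis.order):
            angle = 2 * np.pi * m / axis.order
            rots.append(Rotation.from_rotvec(angle * axis.direction).as_matrix())
    unique = []
    for r in rots:
        if not any(np.allclose(r, u, atol=1e-9) for u in unique):
            unique.append(r)
    return unique


class TestFacetMesh:
    @pytest.mark.parametrize("step", [(1, 0), (2, 1), (2, 2), (5, 3)])
    def test_mesh_closed_euler_two(self, capsid, step):
        c = capsid(*step)
        mesh = facet_mesh(c)
        assert mesh.euler_characteristic == 2
        assert len(mesh.vertices) == len(c.sites)
        # independent route: trimesh watertightness and winding
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                             process=False)
        assert tm.is_watertight
        assert tm.is_winding_consistent
        assert tm.volume > 0  # outward-wound

    def test_t1_mesh_is_the_icosahedron(self, capsid):
        mesh = facet_mesh(capsid(1, 0))
        assert len(mesh.vertices) == 12
        assert len(mesh.triangles) == 20
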