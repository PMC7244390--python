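"""Mesh primitives: icospheres, folded sheets, normals, areas, I/O."""

import numpy as np
import pytest

from cerebsim.anatomy import (
    SurfaceRecipe,
    cerebellum_like,
    cortex_like,
    generate_folded_sheet,
    smoothed_shell,
)
from cerebsim.meshes import (
    TriangleMesh,
    generate_sphere_shell,
    load_mesh,
    save_mesh,
    vertex_areas,
    vertex_normals,
)


def planar_grid(nx=8, ny=8, h=1e-3):
    """Regular right-triangle grid in the z=0 plane."""
    xs, ys = np.meshgrid(np.arange(nx) * h, np.arange(ny) * h, indexing="ij")
    verts = np.stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)], axis=1)
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return TriangleMesh(verts, np.array(faces))


class TestSphereShell:
    def test_icosahedron_counts_and_euler(self):
        m = generate_sphere_shell(80.0, subdivisions=0)
        assert m.n_vertices == 12
        assert m.n_faces == 20
        assert m.euler_characteristic() == 2

    @pytest.mark.parametrize("sub", [0, 2, 4])
    def test_vertices_on_sphere(self, sub):
        m = generate_sphere_shell(80.0, sub)
        r = np.linalg.norm(m.vertices, axis=1)
        assert np.abs(r - 0.080).max() < 1e-12 * 0.080

    def test_area_approaches_closed_form(self):
        m = generate_sphere_shell(80.0, 4)
        exact = 4 * np.pi * 0.080 ** 2
        assert abs(m.area() - exact) / exact < 0.005

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            generate_sphere_shell(-1.0)
        with pytest.raises(ValueError):
            generate_sphere_shell(10.0, subdivisions=-1)


class TestVertexNormals:
    def test_planar_grid_normals(self):
        m = planar_grid()
        n = vertex_normals(m)
        assert np.allclose(np.abs(n[:, 2]), 1.0, atol=1e-12)
        assert np.allclose(n[:, :2], 0.0, atol=1e-12)

    def test_icosphere_normals_radial(self):
        m = generate_sphere_shell(80.0, 3)
        n = vertex_normals(m)
        r = m.vertices / np.linalg.norm(m.vertices, axis=1, keepdims=True)
        cosang = np.clip((n * r).sum(1), -1, 1)
        assert np.rad2deg(np.arccos(cosang)).max() < 1.0

    def test_unit_norm(self, tiny_sheet):
        n = vertex_normals(tiny_sheet)
        assert np.abs(np.linalg.norm(n, axis=1) - 1.0).max() < 1e-12

    def test_isolated_vertex_rejected(self):
        m = TriangleMesh(np.vstack([planar_grid(3, 3).vertices,
                                    [[9, 9, 9]]]),
                         planar_grid(3, 3).faces)
        with pytest.raises(ValueError, match="isolated"):
            vertex_normals(m)


class TestVertexAreas:
    def test_single_equilateral_triangle(self):
        side = 1e-3
        verts = np.array([[0, 0, 0], [side, 0, 0],
                          [side / 2, side * np.sqrt(3) / 2, 0]])
        m = TriangleMesh(verts, np.array([[0, 1, 2]]))
        a = vertex_areas(m)
        expected = (np.sqrt(3) / 4) * side ** 2 / 3
        assert np.allclose(a, expected, rtol=1e-12)

    def test_conservation(self, tiny_sheet):
        a = vertex_areas(tiny_sheet)
        total = tiny_sheet.face_areas().sum()
        assert abs(a.sum() - total) / total < 1e-9

    def test_uniform_grid_interior_equal(self):
        m = planar_grid(10, 10)
        a = vertex_areas(m)
        interior = a.reshape(10, 10)[2:-2, 2:-2].ravel()
        assert np.allclose(interior, interior[0], rtol=1e-12)


class TestFoldedSheet:
    def test_determinism(self):
        rec = cerebellum_like(base_radius=15.0, center=(0, 0, 0),
                              cap_angular_radius=20.0, edge_length=0.2)
        m1 = generate_folded_sheet(rec)
        m2 = generate_folded_sheet(rec)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.faces, m2.faces)

    def test_unfolded_cap_normals_radial(self):
        rec = SurfaceRecipe(kind="smoothed-shell", folia_amplitude=0.0,
                            lobule_amplitude=0.0, base_radius=40.0,
                            cap_angular_radius=30.0, edge_length=1.0)
        m = generate_folded_sheet(rec)
        n = m.face_normals()
        c = m.vertices[m.faces].mean(axis=1)
        r = c / np.linalg.norm(c, axis=1, keepdims=True)
        cosang = np.clip((n * r).sum(1), -1, 1)
        assert np.rad2deg(np.arccos(cosang)).max() < 2.0

    def test_area_matches_arclength_quadrature(self):
        """Folding a cap with a 1 mm / 2 mm sinusoid must inflate its area
        by the 1-D arc-length factor of the corrugation (flat-limit
        estimate, numerical quadrature oracle)."""
        from scipy.integrate import quad

        amp, lam = 1.0, 2.0  # mm
        rec = SurfaceRecipe(kind="cerebellum-like", folia_wavelength=lam,
                            folia_amplitude=amp, lobule_amplitude=0.0,
                            base_radius=40.0, cap_angular_radius=10.0,
                            edge_length=0.1)
        folded = generate_folded_sheet(rec)
        smooth = generate_folded_sheet(
            SurfaceRecipe(kind="smoothed-shell", folia_amplitude=0.0,
                          lobule_amplitude=0.0, base_radius=40.0,
                          cap_angular_radius=10.0, edge_length=0.1))
        k = 2 * np.pi / lam
        factor = quad(lambda s: np.sqrt(1 + (amp * k * np.cos(k * s)) ** 2),
                      0.0, lam)[0] / lam
        ratio = folded.area() / smooth.area()
        assert abs(ratio - factor) / factor < 0.02

    def test_folded_exceeds_smoothed_area(self):
        cb = generate_folded_sheet(cerebellum_like(base_radius=10.0,
                                                   center=(0, 0, 0),
                                                   cap_angular_radius=40.0))
        sm = generate_folded_sheet(smoothed_shell(base_radius=10.0,
                                                  center=(0, 0, 0),
                                                  cap_angular_radius=40.0))
        assert cb.area() > sm.area()

    def test_rejects_coarse_resolution(self):
        rec = cerebellum_like(edge_length=1.0)  # folia wavelength 2 mm
        with pytest.raises(ValueError, match="resolve"):
            generate_folded_sheet(rec)

    def test_rejects_recipe_outside_skull(self):
        rec = cerebellum_like(base_radius=60.0, center=(0.0, -30.0, 0.0))
        with pytest.raises(ValueError):
            generate_folded_sheet(rec, inner_skull_radius_mm=80.0)

    def test_cortex_fold_field_is_seeded(self):
        a = generate_folded_sheet(cortex_like(seed=1))
        b = generate_folded_sheet(cortex_like(seed=2))
        assert not np.array_equal(a.vertices, b.vertices)


class TestMeshIO:
    @pytest.mark.parametrize("ext", ["ply", "off"])
    def test_roundtrip(self, tmp_path, ext, tiny_sheet):
        path = tmp_path / f"mesh.{ext}"
        save_mesh(path, tiny_sheet)
        back = load_mesh(path)
        assert np.allclose(back.vertices, tiny_sheet.vertices, atol=1e-7)
        assert np.array_equal(back.faces, tiny_sheet.faces)

    def test_scalar_sidecar(self, tmp_path, tiny_sheet):
        import pandas as pd

        tiny_sheet.scalar = np.arange(tiny_sheet.n_vertices, dtype=float)
        path = tmp_path / "mesh.ply"
        save_mesh(path, tiny_sheet)
        side = pd.read_csv(str(path) + ".csv")
        assert np.allclose(side["value"], tiny_sheet.scalar)
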