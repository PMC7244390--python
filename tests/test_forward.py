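"""Analytic forward engines: Sarvas MEG field, three-shell EEG series,
gain assembly and its superposition/depth properties."""

import numpy as np
import pytest

from cerebsim.anatomy import build_source_space, decimate_source_space
from cerebsim.forward import (
    ForwardEngine,
    GainMatrix,
    average_reference,
    compute_gain,
    eeg_potential_spheres,
    meg_field_sphere,
)
from cerebsim.sensors import HeadModel, generate_electrode_array

from test_meshes import planar_grid


def random_exterior_points(n, radius, seed=0):
    rng = np.random.default_rng(seed)
    p = rng.normal(size=(n, 3))
    return p / np.linalg.norm(p, axis=1, keepdims=True) * radius


class TestSarvasField:
    def test_radial_dipole_silent(self):
        pos = np.array([[0.0, 0.0, 0.05]])
        mom = np.array([[0.0, 0.0, 1e-9]])  # parallel to position
        B = meg_field_sphere(pos, mom, random_exterior_points(20, 0.12))
        scale = 1e-7 * 1e-9 / 0.05 ** 2  # crude field scale of this moment
        assert np.abs(B).max() < 1e-15 * scale

    def test_center_dipole_silent(self):
        pos = np.zeros((1, 3))
        mom = np.array([[1e-9, 2e-9, -1e-9]])
        B = meg_field_sphere(pos, mom, random_exterior_points(10, 0.12))
        assert np.abs(B).max() == 0.0

    def test_linearity_in_moment(self):
        pos = np.array([[0.01, 0.02, 0.04]])
        mom = np.array([[1e-9, -2e-9, 0.5e-9]])
        pts = random_exterior_points(10, 0.12)
        B1 = meg_field_sphere(pos, mom, pts)
        B2 = meg_field_sphere(pos, 2 * mom, pts)
        assert np.allclose(B2, 2 * B1, rtol=0, atol=0)

    def test_matches_scalar_potential_gradient(self):
        """Tangential dipole against a central-difference oracle on the
        magnetic scalar potential U = -(mu0/4pi)(Q x r0 . r)/F."""
        pos = np.array([[0.0, 0.0, 0.05]])
        mom = np.array([[1e-9, 0.0, 0.0]])
        pts = random_exterior_points(5, 0.12, seed=3)
        B = meg_field_sphere(pos, mom, pts)[:, 0, :]

        def U(r):
            r0, q = pos[0], mom[0]
            a = r - r0
            an, rn = np.linalg.norm(a), np.linalg.norm(r)
            F = an * (rn * an + rn ** 2 - r0 @ r)
            return -1e-7 * (np.cross(q, r0) @ r) / F

        h = 1e-6
        for i, p in enumerate(pts):
            g = np.array([(U(p + h * e) - U(p - h * e)) / (2 * h)
                          for e in np.eye(3)])
            assert np.linalg.norm(B[i] + g) / np.linalg.norm(B[i]) < 1e-6

    def test_radial_component_is_primary_only(self):
        """Volume currents contribute nothing to the radial field outside a
        spherical conductor: B.r must equal the bare Biot-Savart term."""
        pos = np.array([[0.01, 0.02, 0.04]])
        mom = np.array([[3e-9, -1e-9, 2e-9]])
        pts = random_exterior_points(8, 0.12, seed=4)
        B = meg_field_sphere(pos, mom, pts)[:, 0, :]
        d = pts - pos[0]
        Bp = 1e-7 * np.cross(mom[0], d) / np.linalg.norm(d, axis=1)[:, None] ** 3
        rhat = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        assert np.allclose((B * rhat).sum(1), (Bp * rhat).sum(1), rtol=1e-12)

    def test_sensor_inside_source_radius_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            meg_field_sphere(np.array([[0, 0, 0.07]]),
                             np.array([[1e-9, 0, 0]]),
                             np.array([[0.0, 0.0, 0.05]]))


def homogeneous_sphere_potential(dip, q, electrodes, R, sigma):
    """Closed-form surface potential of a dipole in a homogeneous sphere
    (insulating exterior), via generating-function sums of the Legendre
    series -- the independent oracle for the layered solution."""
    b = np.linalg.norm(dip)
    bh = dip / b
    qr = q @ bh
    qt = q - qr * bh
    out = []
    for e in electrodes:
        eh = e / np.linalg.norm(e)
        u = eh @ bh
        t = b / R
        rho = np.sqrt(1 - 2 * t * u + t * t)
        s_rad = 2 * t * (u - t) / rho ** 3 + 1 / rho - 1
        s_tan = 2 * t / rho ** 3 + t * (1 + 1 / rho) / (1 - t * u + rho)
        out.append((qr * s_rad + (qt @ eh) * s_tan) / (4 * np.pi * sigma * b * R))
    return np.array(out)


class TestThreeShellEEG:
    head = HeadModel()

    def test_equal_conductivities_reduce_to_homogeneous(self):
        head_eq = HeadModel((80, 85, 92), (0.3, 0.3, 0.3))
        dip = np.array([[0.01, 0.02, 0.03]])
        q = np.array([[2e-9, -1e-9, 0.5e-9]])
        el = random_exterior_points(12, 0.092, seed=5)
        V = eeg_potential_spheres(dip, q, el, head_eq)[:, 0]
        Vh = homogeneous_sphere_potential(dip[0], q[0], el, 0.092, 0.3)
        assert np.abs(V - Vh).max() / np.abs(Vh).max() < 1e-6

    def test_orientation_flip_negates(self):
        dip = np.array([[0.0, 0.01, 0.04]])
        q = np.array([[1e-9, 2e-9, -0.5e-9]])
        el = random_exterior_points(10, 0.092, seed=6)
        V1 = eeg_potential_spheres(dip, q, el, self.head)
        V2 = eeg_potential_spheres(dip, -q, el, self.head)
        assert np.array_equal(V2, -V1)

    def test_rigid_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.3, -0.5, 0.7]).as_matrix()
        dip = np.array([[0.01, -0.02, 0.035]])
        q = np.array([[1e-9, 1e-9, 0.0]])
        el = random_exterior_points(10, 0.092, seed=7)
        V1 = eeg_potential_spheres(dip, q, el, self.head)
        V2 = eeg_potential_spheres(dip @ rot.T, q @ rot.T, el @ rot.T,
                                   self.head)
        assert np.abs(V1 - V2).max() < 1e-10 * np.abs(V1).max()

    def test_dipole_at_center_finite(self):
        V = eeg_potential_spheres(np.zeros((1, 3)),
                                  np.array([[0, 0, 1e-9]]),
                                  random_exterior_points(6, 0.092), self.head)
        assert np.all(np.isfinite(V))
        assert np.abs(V).max() > 0

    def test_electrode_off_sphere_rejected(self):
        with pytest.raises(ValueError, match="scalp"):
            eeg_potential_spheres(np.array([[0, 0, 0.03]]),
                                  np.array([[1e-9, 0, 0]]),
                                  np.array([[0.0, 0.0, 0.05]]), self.head)

    def test_superficial_dipole_nonconvergent_reported(self):
        with pytest.raises(ValueError, match="terms"):
            eeg_potential_spheres(np.array([[0, 0, 0.0799]]),
                                  np.array([[1e-9, 0, 0]]),
                                  random_exterior_points(4, 0.092),
                                  self.head, tol=1e-14, max_terms=50)


class TestGainAssembly:
    def _flat_src(self):
        mesh = planar_grid(6, 6, 2e-3)
        mesh.vertices[:, 2] += 0.04  # lift the sheet to 40 mm height
        return build_source_space(mesh, None, surface="flat")

    def test_single_source_matches_direct_call(self, sensors):
        src = self._flat_src()
        G = compute_gain(src, sensors, ForwardEngine())
        j = 17
        mag = sensors.subset("mag")
        B = meg_field_sphere(src.positions[[j]], src.orientations[[j]],
                             mag.positions)
        direct = np.einsum("mnk,mk->mn", B, mag.orientations)[:, 0]
        assert np.allclose(G.modality_values("mag")[:, j], direct, rtol=1e-12)

    def test_superposition_identity(self, sensors):
        """The signal of a dipole set equals the sum of per-dipole signals
        exactly -- the identity the cancelation statistics rely on."""
        src = self._flat_src()
        G = compute_gain(src, sensors, ForwardEngine()).values
        idx = [1, 5, 9, 20]
        assert np.allclose(G[:, idx].sum(axis=1),
                           sum(G[:, j] for j in idx), rtol=0, atol=0)

    def test_gain_on_decimated_grid_matches_column_subset(self, sensors):
        src = self._flat_src()
        G = compute_gain(src, sensors, ForwardEngine())
        dec = decimate_source_space(src, 12)
        Gd = compute_gain(dec, sensors, ForwardEngine())
        assert np.allclose(Gd.values, G.values[:, dec.parent_indices],
                           rtol=1e-12)

    def test_depth_monotonicity_magnetometer(self, sensors):
        """A tangential dipole's magnetometer norm decreases toward the
        sphere center."""
        mag = sensors.subset("mag")
        depths = np.array([0.07, 0.055, 0.04, 0.025, 0.01])
        norms = []
        for z in depths:
            B = meg_field_sphere(np.array([[0, 0, z]]),
                                 np.array([[1e-9, 0, 0]]), mag.positions)
            norms.append(np.linalg.norm(
                np.einsum("mnk,mk->mn", B, mag.orientations)))
        assert np.all(np.diff(norms) < 0)

    def test_gradiometer_matches_finite_difference(self, sensors):
        src = self._flat_src()
        G = compute_gain(src, sensors, ForwardEngine())
        gx = G.values[G.channel_types == "gradiometer_x"]
        assert gx.shape[0] == 102
        assert np.all(np.isfinite(gx))
        # gradient magnitudes should differ from the field magnitudes by
        # roughly 1/baseline in scale (T/m vs T)
        mags = G.modality_values("mag")
        ratio = np.linalg.norm(gx) / np.linalg.norm(mags)
        assert 1.0 < ratio < 1000.0

    def test_average_reference_removes_constant(self):
        x = np.arange(12.0).reshape(4, 3)
        assert np.allclose(average_reference(x + 7.5).mean(axis=0), 0.0)

    def test_mesh_refinement_converges(self):
        """Gain-column norms on successively refined folded meshes change
        less with each halving of the edge length."""
        from cerebsim.anatomy import cerebellum_like, generate_folded_sheet

        el = generate_electrode_array(32)
        means = []
        for edge in (0.4, 0.2, 0.1):
            rec = cerebellum_like(base_radius=15.0, center=(0, 0, 0),
                                  cap_angular_radius=15.0,
                                  folia_wavelength=4.0, folia_amplitude=0.5,
                                  lobule_amplitude=0.0, edge_length=edge)
            mesh = generate_folded_sheet(rec)
            src = build_source_space(mesh, None, surface="conv")
            G = compute_gain(src, el, ForwardEngine())
            means.append(np.linalg.norm(G.values, axis=0).mean())
        d1 = abs(means[1] - means[0])
        d2 = abs(means[2] - means[1])
        assert d2 < d1
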