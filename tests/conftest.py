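"""Shared fixtures: sensor arrays, surfaces and gain matrices.

The heavyweight bundles (default cerebellum shell, cortex cap, smoothed
shell, convergence-study grids) are session-scoped so the anatomy and
forward computations run once for the whole suite.
"""

import numpy as np
import pytest

from cerebsim.anatomy import (
    build_source_space,
    cerebellum_like,
    cortex_like,
    decimate_source_space,
    generate_folded_sheet,
    smoothed_shell,
)
from cerebsim.forward import ForwardEngine, compute_gain
from cerebsim.sensors import (
    HeadModel,
    SensorArray,
    generate_electrode_array,
    generate_helmet_array,
)

INNER_SKULL_MM = 80.0


def combined_array() -> SensorArray:
    helm = generate_helmet_array()
    cap = generate_electrode_array()
    return SensorArray(
        helm.names + cap.names,
        np.concatenate([helm.types, cap.types]),
        np.vstack([helm.positions, cap.positions]),
        np.vstack([helm.orientations, cap.orientations]),
        np.concatenate([helm.baselines_mm, cap.baselines_mm]),
    )


@pytest.fixture(scope="session")
def sensors():
    return combined_array()


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def cortex_bundle(sensors):
    """Default cortex-like surface on its uniform 20k source grid."""
    mesh = generate_folded_sheet(cortex_like(), INNER_SKULL_MM)
    src_raw = build_source_space(mesh, INNER_SKULL_MM * 1e-3, 5.0, "cortex")
    src = decimate_source_space(src_raw, 20000)
    gain = compute_gain(src, sensors, ForwardEngine())
    return {"mesh": mesh, "src": src, "gain": gain}


@pytest.fixture(scope="session")
def cerebellum_bundle(sensors):
    """Default cerebellum-like shell decimated to its 60k source grid."""
    mesh = generate_folded_sheet(cerebellum_like(), INNER_SKULL_MM)
    src_raw = build_source_space(mesh, INNER_SKULL_MM * 1e-3, 5.0,
                                 "cerebellum")
    src = decimate_source_space(src_raw, 60000)
    gain = compute_gain(src, sensors, ForwardEngine())
    return {"mesh": mesh, "src": src, "gain": gain}


@pytest.fixture(scope="session")
def smoothed_bundle(sensors):
    """Smoothed-shell surrogate on its uniform 20k source grid."""
    mesh = generate_folded_sheet(smoothed_shell(), INNER_SKULL_MM)
    src_raw = build_source_space(mesh, INNER_SKULL_MM * 1e-3, 5.0, "smoothed")
    src = decimate_source_space(src_raw, 20000)
    gain = compute_gain(src, sensors, ForwardEngine())
    return {"mesh": mesh, "src": src, "gain": gain}


@pytest.fixture(scope="session")
def convergence_bundle(sensors):
    """Scaled cerebellum shell with full (110k) and 55%-decimated grids.

    Geometrically scaled shell: 6 mm base radius with the lobular band
    scaled in proportion; folia stay at the anatomical 2 mm wavelength and
    the mesh resolves them at 0.065 mm edges (< wavelength/20).
    """
    rec = cerebellum_like(base_radius=6.0, center=(0.0, -42.0, -31.0),
                          edge_length=0.1, lobule_wavelength=4.8,
                          lobule_amplitude=0.72)
    mesh = generate_folded_sheet(rec, INNER_SKULL_MM)
    src_mesh = build_source_space(mesh, INNER_SKULL_MM * 1e-3, 5.0, "cb-fine")
    full = decimate_source_space(src_mesh, 110000)
    dec = decimate_source_space(full, int(0.55 * 110000))
    gain_full = compute_gain(full, sensors, ForwardEngine())
    gain_dec = compute_gain(dec, sensors, ForwardEngine())
    return {"mesh": mesh, "full": full, "dec": dec,
            "gain_full": gain_full, "gain_dec": gain_dec}


@pytest.fixture(scope="session")
def bem_model(head):
    from cerebsim.bem import BemModel

    return BemModel(head.boundary_meshes(3), list(head.conductivities))


@pytest.fixture()
def tiny_sheet():
    """A small, cheap folded cap for unit tests."""
    rec = cerebellum_like(base_radius=20.0, center=(0.0, 0.0, 0.0),
                          cap_angular_radius=25.0, folia_wavelength=4.0,
                          folia_amplitude=0.5, lobule_amplitude=0.0,
                          edge_length=0.4)
    return generate_folded_sheet(rec, INNER_SKULL_MM)
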