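"""Head model and synthetic M/EEG sensor arrays.

The conductor is the standard three-compartment piecewise-homogeneous head
(brain / skull / scalp at 0.3 / 0.006 / 0.3 S/m).  Sensor geometry emulates
a 306-channel MEG system (102 sites, each with one magnetometer and two
orthogonal planar gradiometers) and a 72-electrode EEG cap; real layouts are
measurement data, so quasi-uniform Fibonacci lattices stand in, with CSV
round-tripping as the hook for loading a measured layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meshes import TriangleMesh, generate_sphere_shell

MAGNETOMETER = "magnetometer"
GRADIOMETER_X = "gradiometer_x"
GRADIOMETER_Y = "gradiometer_y"
ELECTRODE = "electrode"

#: modality name -> channel types included in its norm computations
MODALITIES = {
    "mag": (MAGNETOMETER,),
    "grad": (GRADIOMETER_X, GRADIOMETER_Y),
    "eeg": (ELECTRODE,),
}

CHANNEL_UNITS = {
    MAGNETOMETER: "T",
    GRADIOMETER_X: "T/m",
    GRADIOMETER_Y: "T/m",
    ELECTRODE: "V",
}


@dataclass
class HeadModel:
    """Concentric three-shell conductor (radii in mm, conductivities S/m)."""

    shell_radii: tuple = (80.0, 85.0, 92.0)
    conductivities: tuple = (0.3, 0.006, 0.3)

    def __post_init__(self):
        r = np.asarray(self.shell_radii, float)
        if not (np.all(np.diff(r) > 0) and np.all(r > 0)):
            raise ValueError("shell radii must be positive and strictly increasing")
        if not np.all(np.asarray(self.conductivities, float) > 0):
            raise ValueError("conductivities must be positive")

    @property
    def inner_skull_radius_m(self) -> float:
        return self.shell_radii[0] * 1e-3

    @property
    def scalp_radius_m(self) -> float:
        return self.shell_radii[2] * 1e-3

    def radii_m(self) -> np.ndarray:
        return np.asarray(self.shell_radii, float) * 1e-3

    def boundary_meshes(self, subdivisions: int = 3) -> list[TriangleMesh]:
        """Icosphere boundary meshes (brain, skull, scalp) for the BEM."""
        return [generate_sphere_shell(r, subdivisions) for r in self.shell_radii]


@dataclass
class SensorArray:
    """Typed M/EEG channels.

    Channel ordering for MEG is site-major (magnetometer, gradiometer_x,
    gradiometer_y per site).  ``orientations`` hold the measured field
    component direction (radial for all MEG channels of a site); the
    finite-difference axis of a planar gradiometer is recomputed
    deterministically from the site position via :func:`tangent_axes`.
    """

    names: list
    types: np.ndarray
    positions: np.ndarray  # meters
    orientations: np.ndarray  # unit vectors
    baselines_mm: np.ndarray  # nan for non-gradiometers

    def __post_init__(self):
        self.types = np.asarray(self.types, dtype=object)
        self.positions = np.asarray(self.positions, float)
        self.orientations = np.asarray(self.orientations, float)
        self.baselines_mm = np.asarray(self.baselines_mm, float)
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("channel orientations must be unit vectors")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def mask(self, modality: str) -> np.ndarray:
        types = MODALITIES[modality]
        return np.isin(self.types.astype(str), types)

    def subset(self, modality: str) -> "SensorArray":
        m = self.mask(modality)
        return SensorArray(
            [n for n, k in zip(self.names, m) if k],
            self.types[m], self.positions[m], self.orientations[m],
            self.baselines_mm[m],
        )

    def units(self) -> np.ndarray:
        return np.array([CHANNEL_UNITS[t] for t in self.types], dtype=object)

    # -- CSV round trip ------------------------------------------------------

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "channel_name": self.names,
                "type": self.types.astype(str),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "ox": self.orientations[:, 0],
                "oy": self.orientations[:, 1],
                "oz": self.orientations[:, 2],
                "baseline_mm": self.baselines_mm,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorArray":
        df = pd.read_csv(path)
        return cls(
            df["channel_name"].tolist(),
            df["type"].to_numpy(dtype=object),
            df[["x", "y", "z"]].to_numpy(float),
            df[["ox", "oy", "oz"]].to_numpy(float),
            df["baseline_mm"].to_numpy(float),
        )


def fibonacci_cap(n: int, coverage_deg: float) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the cap of polar angle
    ``coverage_deg`` around +z (golden-angle spiral lattice)."""
    i = np.arange(n) + 0.5
    cos_lim = np.cos(np.deg2rad(coverage_deg))
    z = 1.0 - (i / n) * (1.0 - cos_lim)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def tangent_axes(unit_pos: np.ndarray):
    """Deterministic orthonormal tangential frame (t1, t2) at each unit
    position: t1 = normalize(z x r) (x fallback near the pole), t2 = r x t1."""
    unit_pos = np.atleast_2d(unit_pos)
    zaxis = np.array([0.0, 0.0, 1.0])
    t1 = np.cross(np.broadcast_to(zaxis, unit_pos.shape), unit_pos)
    nrm = np.linalg.norm(t1, axis=1)
    polar = nrm < 1e-8
    if np.any(polar):
        t1[polar] = np.cross([1.0, 0.0, 0.0], unit_pos[polar])
        nrm = np.linalg.norm(t1, axis=1)
    t1 /= nrm[:, None]
    t2 = np.cross(unit_pos, t1)
    t2 /= np.linalg.norm(t2, axis=1, keepdims=True)
    return t1, t2


def generate_helmet_array(n_sites: int = 102, helmet_radius_mm: float = 108.0,
                          coverage_deg: float = 115.0,
                          baseline_mm: float = 16.8,
                          scalp_radius_mm: float = 92.0) -> SensorArray:
    """Synthetic MEG helmet: ``n_sites`` Fibonacci-lattice sites, each with a
    radial magnetometer and two orthogonal tangential planar gradiometers.

    With the defaults this yields the 306-channel complement of a
    102-site MEG system (102 magnetometers + 204 planar gradiometers with
    a 16.8 mm baseline).
    """
    if n_sites < 4:
        raise ValueError("n_sites must be >= 4")
    if helmet_radius_mm <= scalp_radius_mm:
        raise ValueError("helmet radius must exceed the scalp radius")
    u = fibonacci_cap(n_sites, coverage_deg)
    pos = u * helmet_radius_mm * 1e-3
    names, types, positions, orientations, baselines = [], [], [], [], []
    for i in range(n_sites):
        for suffix, typ in (("1", MAGNETOMETER), ("2", GRADIOMETER_X),
                            ("3", GRADIOMETER_Y)):
            names.append(f"MEG{i:03d}{suffix}")
            types.append(typ)
            positions.append(pos[i])
            orientations.append(u[i])
            baselines.append(np.nan if typ == MAGNETOMETER else baseline_mm)
    return SensorArray(names, np.array(types, object), np.array(positions),
                       np.array(orientations), np.array(baselines))


def generate_electrode_array(n_electrodes: int = 72,
                             scalp_radius_mm: float = 92.0,
                             coverage_deg: float = 115.0) -> SensorArray:
    """Synthetic EEG cap: quasi-uniform electrodes on the scalp sphere.

    ``coverage_deg`` beyond 90 extends the cap below the equator; cerebellar
    EEG sensitivity depends strongly on this inferior-posterior coverage,
    so it is a parameter rather than a claim.
    """
    if n_electrodes < 2:
        raise ValueError("n_electrodes must be >= 2")
    u = fibonacci_cap(n_electrodes, coverage_deg)
    pos = u * scalp_radius_mm * 1e-3
    names = [f"EEG{i:03d}" for i in range(n_electrodes)]
    types = np.array([ELECTRODE] * n_electrodes, object)
    return SensorArray(names, types, pos, u, np.full(n_electrodes, np.nan))
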