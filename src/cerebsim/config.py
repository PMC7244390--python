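"""Run configuration: YAML schema, validation, seed splitting.

The config is a plain nested mapping with explicit unit suffixes in every
key name (``*_mm``, ``*_s_per_m``, ``*_nam``); unknown keys are rejected so
typos fail fast.  One global seed is split into per-stage child seeds with
:class:`numpy.random.SeedSequence` so stages can be re-run in isolation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from .anatomy import PRESETS, SurfaceRecipe
from .sensors import HeadModel

_STAGES = ("anatomy", "sensors", "gain", "monte_carlo", "sensitivity")

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "results",
    "surfaces": {
        "cerebellum": {"preset": "cerebellum-like"},
        "cortex": {"preset": "cortex-like"},
        "smoothed": {"preset": "smoothed-shell"},
    },
    "head": {
        "shell_radii_mm": [80.0, 85.0, 92.0],
        "conductivities_s_per_m": [0.3, 0.006, 0.3],
    },
    "sensors": {
        "meg_sites": 102,
        "helmet_radius_mm": 108.0,
        "meg_coverage_deg": 115.0,
        "gradiometer_baseline_mm": 16.8,
        "eeg_electrodes": 72,
        "eeg_coverage_deg": 115.0,
        "layout_csv": None,
    },
    "forward": {
        "method": "sphere_analytic",
        "bem_subdivisions": 3,
        "isolated_skull": True,
    },
    "source_space": {
        "min_dist_mm": 5.0,
        # statistics run on farthest-point-sampled grids (uniform geodesic
        # density); per-surface target counts, or null for raw mesh vertices
        "decimate_to": {"cerebellum": 60000, "cortex": 20000,
                        "smoothed": 20000},
    },
    "experiment": {
        "samples": 200,
        "n_grid": [1, 2, 3, 5, 10, 30, 100, 300, 1000, 3000, 10000],
        "radii_mm": [1.0, 2.0, 3.0, 5.0, 7.5, 10.0, 15.0, 20.0, 30.0],
        "modalities": ["mag", "grad", "eeg"],
        "reference_eeg": True,
    },
    "constants": {
        "q0_am_per_mm2": 1.0e-9,
        "sensitivity_moment_nam": 100.0,
    },
}

_RECIPE_KEYS = {
    "preset", "kind", "folia_wavelength", "folia_amplitude",
    "lobule_wavelength", "lobule_amplitude", "cap_center_direction",
    "cap_angular_radius", "base_radius", "edge_length", "seed", "center",
}


def _check_keys(section: dict, allowed, path: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated run configuration."""

    raw: dict

    @classmethod
    def from_mapping(cls, mapping: dict | None = None) -> "RunConfig":
        cfg = copy.deepcopy(DEFAULT_CONFIG)
        mapping = mapping or {}
        _check_keys(mapping, DEFAULT_CONFIG, "<root>")
        for key, val in mapping.items():
            if isinstance(val, dict) and key != "surfaces":
                _check_keys(val, DEFAULT_CONFIG[key], key)
                cfg[key].update(val)
            else:
                cfg[key] = copy.deepcopy(val)
        for name, spec in cfg["surfaces"].items():
            _check_keys(spec, _RECIPE_KEYS, f"surfaces.{name}")
        out = cls(cfg)
        out.head_model()  # validate
        for name in cfg["surfaces"]:
            out.recipe(name)
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=True)

    # -- derived objects -----------------------------------------------------

    def head_model(self) -> HeadModel:
        h = self.raw["head"]
        return HeadModel(tuple(h["shell_radii_mm"]),
                         tuple(h["conductivities_s_per_m"]))

    def recipe(self, surface_name: str) -> SurfaceRecipe:
        spec = dict(self.raw["surfaces"][surface_name])
        preset = spec.pop("preset", None)
        for key in ("cap_center_direction", "center"):
            if key in spec:
                spec[key] = tuple(spec[key])
        if preset is not None:
            if preset not in PRESETS:
                raise ValueError(f"unknown surface preset {preset!r}")
            return PRESETS[preset](**spec)
        return SurfaceRecipe(**spec)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed (< 2**31)."""
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence(
            int(self.raw["seed"]), spawn_key=(_STAGES.index(stage),)
        )
        return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))

    def content_hash(self) -> str:
        import hashlib
        import json

        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
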