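"""End-to-end pipeline: anatomy -> sensors -> gain -> Monte Carlo ->
sensitivity -> report.

Stages run in dependency order; gain matrices are cached on disk keyed by a
content hash of (recipe, sensors, engine) so Monte Carlo re-runs skip the
forward computation.  A manifest (config hash, seed, stage outputs, wall
clock) is written atomically at the end and suffices to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import (
    SourceSpace,
    build_source_space,
    decimate_source_space,
    generate_folded_sheet,
)
from .cancelation import PhysiologicalConstants, normalize_to_reference
from .config import RunConfig
from .forward import ForwardEngine, GainMatrix, compute_gain
from .meshes import save_mesh
from .monte_carlo import (
    ExperimentDesign,
    run_coherent,
    run_distributed,
    samples_to_triples,
    summarize_curve,
)
from .sensitivity import norm_histogram, percentile_clip, sensitivity_map
from .sensors import SensorArray, generate_electrode_array, generate_helmet_array

logger = logging.getLogger(__name__)


def build_sensors(config: RunConfig) -> SensorArray:
    s = config.raw["sensors"]
    if s.get("layout_csv"):
        return SensorArray.from_csv(s["layout_csv"])
    head = config.head_model()
    helm = generate_helmet_array(
        s["meg_sites"], s["helmet_radius_mm"], s["meg_coverage_deg"],
        s["gradiometer_baseline_mm"], scalp_radius_mm=head.shell_radii[2],
    )
    cap = generate_electrode_array(
        s["eeg_electrodes"], head.shell_radii[2], s["eeg_coverage_deg"]
    )
    return SensorArray(
        helm.names + cap.names,
        np.concatenate([helm.types, cap.types]),
        np.vstack([helm.positions, cap.positions]),
        np.vstack([helm.orientations, cap.orientations]),
        np.concatenate([helm.baselines_mm, cap.baselines_mm]),
    )


def build_surface(config: RunConfig, name: str):
    """Mesh + source space (with exclusion and optional decimation)."""
    recipe = config.recipe(name)
    head = config.head_model()
    mesh = generate_folded_sheet(recipe, inner_skull_radius_mm=head.shell_radii[0])
    src = build_source_space(
        mesh, head.inner_skull_radius_m,
        config.raw["source_space"]["min_dist_mm"], surface=name,
    )
    dec = config.raw["source_space"]["decimate_to"]
    if isinstance(dec, dict):
        dec = dec.get(name)
    if dec:
        src = decimate_source_space(src, int(dec))
    return mesh, src


def build_engine(config: RunConfig) -> ForwardEngine:
    f = config.raw["forward"]
    return ForwardEngine(
        head=config.head_model(), method=f["method"],
        bem_subdivisions=f["bem_subdivisions"],
        isolated_skull=f["isolated_skull"],
    )


def gain_with_cache(config: RunConfig, src: SourceSpace,
                    sensors: SensorArray, cache_dir: Path | None) -> GainMatrix:
    engine = build_engine(config)
    if cache_dir is None:
        return compute_gain(src, sensors, engine)
    key = hashlib.sha256()
    key.update(src.positions.tobytes())
    key.update(src.orientations.tobytes())
    key.update(sensors.positions.tobytes())
    key.update(np.asarray(sensors.types.astype(str)).tobytes())
    key.update(json.dumps(config.raw["forward"], sort_keys=True).encode())
    key.update(json.dumps(config.raw["head"], sort_keys=True).encode())
    path = Path(cache_dir) / f"gain_{src.surface}_{key.hexdigest()[:16]}.npz"
    if path.exists():
        logger.info("gain cache hit: %s", path.name)
        return GainMatrix.load(path)
    G = compute_gain(src, sensors, engine)
    path.parent.mkdir(parents=True, exist_ok=True)
    G.save(path)
    return G


_SAMPLE_UNITS = {
    "modality": "", "n": "count", "sample": "index", "a_n_mm2": "mm^2",
    "A": "channel units", "B": "channel units", "C": "dimensionless",
    "alpha": "channel units", "beta": "channel units", "radius_mm": "mm",
}


def _unit_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Suffix every column header with its units (unit audit)."""
    ren = {}
    for c in df.columns:
        base = c
        unit = _SAMPLE_UNITS.get(base)
        if unit is None:
            for key, u in _SAMPLE_UNITS.items():
                if base.startswith(key):
                    unit = u
                    break
        ren[c] = f"{c} [{unit}]" if unit else f"{c} [-]"
    return df.rename(columns=ren)


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Execute every stage; returns the manifest mapping."""
    t_start = time.time()
    out = Path(output_dir or config.raw["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    cache = out / "cache"
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.raw["seed"],
        "stages": {},
        "files": [],
    }

    def _stage(name):
        t0 = time.time()

        def done():
            manifest["stages"][name] = round(time.time() - t0, 3)

        return done

    constants = PhysiologicalConstants(
        config.raw["constants"]["q0_am_per_mm2"],
        config.raw["constants"]["sensitivity_moment_nam"],
    )

    try:
        done = _stage("anatomy")
        surfaces = {}
        for name in config.raw["surfaces"]:
            mesh, src = build_surface(config, name)
            surfaces[name] = (mesh, src)
            p = out / f"surface_{name}.ply"
            save_mesh(p, mesh)
            manifest["files"].append(str(p))
        done()

        done = _stage("sensors")
        sensors = build_sensors(config)
        p = out / "sensors.csv"
        sensors.to_csv(p)
        manifest["files"].append(str(p))
        done()

        done = _stage("gain")
        gains = {
            name: gain_with_cache(config, src, sensors, cache)
            for name, (mesh, src) in surfaces.items()
        }
        done()

        exp = config.raw["experiment"]
        design_kwargs = dict(
            samples=exp["samples"], modalities=tuple(exp["modalities"]),
            reference_eeg=exp["reference_eeg"],
            seed=config.stage_seed("monte_carlo"),
        )

        done = _stage("monte_carlo")
        coherent = {}
        for name, (mesh, src) in surfaces.items():
            design = ExperimentDesign(
                condition="distributed", n_grid=tuple(exp["n_grid"]),
                **design_kwargs)
            dist = run_distributed(design, src, gains[name], constants)
            design = ExperimentDesign(
                condition="coherent", radii_mm=tuple(exp["radii_mm"]),
                **design_kwargs)
            coh = run_coherent(design, src, gains[name], constants)
            coherent[name] = coh
            for label, df, by in (("distributed", dist, "n"),
                                  ("coherent", coh, "radius_mm")):
                p = out / f"mc_{label}_{name}_samples.csv"
                _unit_columns(df).to_csv(p, index=False)
                manifest["files"].append(str(p))
                p = out / f"mc_{label}_{name}_summary.csv"
                _unit_columns(summarize_curve(df, by)).to_csv(p, index=False)
                manifest["files"].append(str(p))
        # cortex-normalized cerebellar curves
        if {"cerebellum", "cortex"} <= set(surfaces):
            radii = tuple(exp["radii_mm"])
            norm_rows = []
            for m in exp["modalities"]:
                cb = samples_to_triples(coherent["cerebellum"], m)
                ctx = samples_to_triples(coherent["cortex"], m)
                curve = normalize_to_reference(cb, ctx, radii)
                for i, r in enumerate(radii):
                    norm_rows.append({
                        "modality": m, "radius_mm": r,
                        "C_ratio": curve.C_ratio[i],
                        "C_ratio_sd": curve.C_ratio_sd[i],
                        "alpha_ratio": curve.alpha_ratio[i],
                        "alpha_ratio_sd": curve.alpha_ratio_sd[i],
                        "beta_ratio": curve.beta_ratio[i],
                        "beta_ratio_sd": curve.beta_ratio_sd[i],
                    })
            p = out / "normalized_curves.csv"
            df = pd.DataFrame(norm_rows)
            df.columns = [
                c + (" [mm]" if c == "radius_mm" else
                     "" if c == "modality" else " [ratio]")
                for c in df.columns
            ]
            df.to_csv(p, index=False)
            manifest["files"].append(str(p))
        done()

        done = _stage("sensitivity")
        maps = {}
        for name, (mesh, src) in surfaces.items():
            for m in exp["modalities"]:
                sm = sensitivity_map(
                    gains[name], src, m,
                    constants.sensitivity_moment_nam,
                    reference_eeg=exp["reference_eeg"],
                )
                maps[(name, m)] = sm
                df = pd.DataFrame({
                    "vertex_index [index]": np.arange(src.n_sources),
                    f"norm [{_map_unit(m)}]": sm.values,
                    "kept [bool]": src.kept.astype(int),
                })
                p = out / f"sensitivity_{name}_{m}.csv"
                df.to_csv(p, index=False)
                manifest["files"].append(str(p))
        summary = {}
        for m in exp["modalities"]:
            entry = {}
            for name in surfaces:
                sm = maps[(name, m)]
                lo, hi = percentile_clip(sm)
                entry[name] = {
                    "median": float(np.median(sm.kept_values())),
                    "clip_lo_p1": lo,
                    "clip_hi_p99": hi,
                }
            if {"cerebellum", "cortex"} <= set(surfaces):
                h = norm_histogram(maps[("cerebellum", m)],
                                   maps[("cortex", m)])
                entry["cerebellum_vs_cortex"] = {
                    "median_ratio": h.median_ratio,
                    "exceedance_fraction": h.exceedance_fraction,
                }
            summary[m] = entry
        p = out / "sensitivity_summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2)
        manifest["files"].append(str(p))
        done()
    except Exception as err:
        manifest["error"] = f"{type(err).__name__}: {err}"
        tmp = out / "manifest.partial.json"
        with open(tmp, "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    manifest["wall_clock_s"] = round(time.time() - t_start, 3)
    tmp = out / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2)
    tmp.rename(out / "manifest.json")
    return manifest


def _map_unit(modality: str) -> str:
    return {"mag": "T", "grad": "T/m", "eeg": "V"}[modality]


def make_report(output_dir) -> str:
    """Markdown report assembled from the run's CSV/JSON outputs.

    Purely presentational: every number is read back from the stage outputs,
    nothing is recomputed.
    """
    out = Path(output_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    missing = [f for f in manifest["files"] if not Path(f).exists()]
    if missing:
        raise FileNotFoundError(f"missing stage outputs: {missing}")

    lines = ["# cerebsim run report", "",
             f"config hash: `{manifest['config_hash']}`  ",
             f"seed: {manifest['seed']}  ",
             f"wall clock: {manifest.get('wall_clock_s', '?')} s", ""]
    for f in manifest["files"]:
        p = Path(f)
        if p.suffix == ".csv" and "summary" in p.name:
            lines.append(f"## {p.name}")
            lines.append("")
            lines.append(pd.read_csv(p).to_markdown(index=False))
            lines.append("")
        elif p.name == "normalized_curves.csv":
            lines.append("## cortex-normalized cerebellar curves")
            lines.append("")
            lines.append(pd.read_csv(p).to_markdown(index=False))
            lines.append("")
        elif p.suffix == ".json":
            lines.append(f"## {p.name}")
            lines.append("")
            lines.append("```json\n" + p.read_text() + "\n```")
            lines.append("")
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
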