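"""End-to-end pipeline orchestration.

``run_simulate`` renders a phantom acquisition and draws a synthetic
cohort; ``run_full`` runs the analysis chain on them:

    amplitude frames -> Doppler variance -> en-face projection
                     -> Frangi vesselness -> binarize -> BVD
    structural B-scans -> epithelium segmentation -> VET
    cohort table -> aggregates, baseline comparisons, correlations

Each stage persists its outputs, the resolved configuration is written
next to them, and a manifest with SHA-256 checksums makes reruns
comparable.  Any stage failure aborts with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .cohort import CohortEffectModel, generate_cohort
from .config import PipelineConfig
from .epithelium import compute_vet, segment_epithelium_classical
from .ibdv import compute_ibdv_volume, enface_project
from .phantom import make_tissue_scene, render_frame_sequence
from .stats import aggregate, compare_to_baseline, correlate
from .vessels import binarize_vessels, compute_bvd, frangi_vesselness

logger = logging.getLogger("endooct")

__all__ = ["run_simulate", "run_full", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, files: list[Path]) -> Path:
    manifest = {
        "files": {f.name: _checksum(f) for f in sorted(files)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result
        return wrapped
    return deco


def run_simulate(config: PipelineConfig, outdir) -> dict:
    """Render a phantom volume and draw a synthetic cohort.

    Writes the acquisition TIFF, ground-truth masks, the cohort CSV, the
    resolved config and a checksum manifest.  Deterministic under the
    config seed.
    """
    outdir = Path(outdir)
    if not outdir.parent.exists():
        raise ValueError(f"output path parent does not exist: {outdir.parent}")
    outdir.mkdir(parents=True, exist_ok=True)
    geom = config.geometry.to_geometry()
    sim = config.simulate

    scene = make_tissue_scene(
        geom,
        thickness_um=sim.thickness_um,
        vessel_fraction=sim.vessel_fraction,
        seed=config.seed,
        ablation_grid_pitch_px=sim.ablation_grid_pitch_px,
    )
    vol = render_frame_sequence(
        scene, decorrelation=sim.decorrelation,
        noise_floor=sim.noise_floor, seed=config.seed + 1,
    )
    cohort = generate_cohort(CohortEffectModel(n_patients=sim.n_patients, seed=config.seed))

    files = []
    acq_path = outdir / "acquisition.tiff"
    eio.write_acquisition(vol, acq_path)
    files += [acq_path, acq_path.with_suffix(".json")]

    truth_path = outdir / "truth_vessel_mask.tiff"
    eio.write_mask(scene.enface_vessel_mask, truth_path,
                   provenance={"enface_vessel_fraction": scene.enface_vessel_fraction,
                               **scene.params})
    files += [truth_path, truth_path.with_suffix(".json")]

    cohort_path = outdir / "cohort.csv"
    eio.write_cohort_csv(cohort, cohort_path)
    files.append(cohort_path)

    cfg_path = outdir / "config.json"
    config.write(cfg_path)
    files.append(cfg_path)
    manifest = _write_manifest(outdir, files)
    return {"outdir": outdir, "manifest": manifest, "scene": scene,
            "acquisition": acq_path, "cohort": cohort_path}


@_stage("octa")
def _stage_octa(config, vol, outdir):
    var = compute_ibdv_volume(
        vol.frames.astype(np.float64),
        lateral_window=config.ibdv.lateral_window,
        mode=config.ibdv.mode,
        geometry=vol.geometry,
    )
    z_hi = min(config.ibdv.z_hi, var.sigma2.shape[2])
    enface = enface_project(var, config.ibdv.z_lo, z_hi)
    var_path = outdir / "variance_volume.tiff"
    eio.write_variance_volume(var, var_path)
    ef_path = outdir / "enface.tiff"
    eio.write_enface(enface, ef_path)
    return enface, [var_path, var_path.with_suffix(".json"),
                    ef_path, ef_path.with_suffix(".json")]


@_stage("vessels")
def _stage_vessels(config, enface, outdir):
    vness = frangi_vesselness(enface, scales=config.frangi.scales,
                              beta=config.frangi.beta, c=config.frangi.c)
    mask = binarize_vessels(vness, method=config.binarize.method,
                            threshold=config.binarize.threshold,
                            enface=enface)
    bvd = compute_bvd(mask)
    mask_path = outdir / "vessel_mask.tiff"
    eio.write_mask(mask.mask, mask_path,
                   provenance={"threshold": mask.threshold, "method": mask.method,
                               "bvd": bvd.bvd})
    return bvd, [mask_path, mask_path.with_suffix(".json")]


@_stage("vet")
def _stage_vet(config, vol, outdir):
    seg_cfg = config.segmentation
    rows = []
    # a spread of B-scans is enough for a scan-level thickness estimate
    positions = np.unique(np.linspace(0, vol.n_slow - 1, min(vol.n_slow, 8)).astype(int))
    for y in positions:
        seg = segment_epithelium_classical(
            vol.structural_bscan(int(y)),
            smoothing_sigma=seg_cfg.smoothing_sigma,
            min_thickness_px=seg_cfg.min_thickness_px,
            max_thickness_px=seg_cfg.max_thickness_px,
        )
        prof = compute_vet(seg, vol.geometry.axial_pixel_um)
        rows.append({"slow_position": int(y), "mean_vet_um": prof.mean_vet_um,
                     "valid_fraction": prof.valid_fraction})
    df = pd.DataFrame(rows)
    path = outdir / "vet_per_bscan.csv"
    df.to_csv(path, index=False)
    return float(df["mean_vet_um"].mean()), [path]


@_stage("stats")
def _stage_stats(config, cohort, outdir):
    files = []
    aggs = pd.concat([aggregate(cohort, m) for m in ("bvd", "vet_um")], ignore_index=True)
    p = outdir / "aggregates.csv"
    aggs.to_csv(p, index=False)
    files.append(p)

    comps = pd.concat(
        [compare_to_baseline(cohort, m, test=config.stats.test,
                             mode=config.stats.baseline_mode, holm=config.stats.holm)
         for m in ("bvd", "vet_um")],
        ignore_index=True,
    )
    p = outdir / "comparisons.csv"
    comps.to_csv(p, index=False)
    files.append(p)

    pairs = [("vhi", "vsq"), ("vsq", "bvd"), ("vhi", "bvd"),
             ("vhi", "vet_um"), ("vsq", "vet_um")]
    rows = []
    for a, b in pairs:
        res = correlate(cohort, a, b)
        rows.append({"metric_a": a, "metric_b": b, "r": res.r, "abs_r": res.abs_r,
                     "strength": res.strength, "n": res.n, "p_value": res.p_value})
    corr = pd.DataFrame(rows)
    p = outdir / "correlations.csv"
    corr.to_csv(p, index=False)
    files.append(p)
    return {"aggregates": aggs, "comparisons": comps, "correlations": corr}, files


def run_full(config: PipelineConfig, outdir, simulated: dict | None = None) -> dict:
    """Run the whole analysis chain; returns the headline metrics.

    ``simulated`` may be the result of a previous :func:`run_simulate`
    (inputs are reused); otherwise simulation runs first into the same
    output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if simulated is None:
        simulated = run_simulate(config, outdir)
    vol = eio.read_acquisition(simulated["acquisition"])
    cohort = eio.read_cohort_csv(simulated["cohort"])

    files = []
    enface, f = _stage_octa(config, vol, outdir)
    files += f
    bvd, f = _stage_vessels(config, enface, outdir)
    files += f
    mean_vet, f = _stage_vet(config, vol, outdir)
    files += f
    stats_out, f = _stage_stats(config, cohort, outdir)
    files += f

    cfg_path = outdir / "config.json"
    config.write(cfg_path)
    files.append(cfg_path)
    _write_manifest(outdir, files)
    return {
        "bvd": bvd.bvd,
        "mean_vet_um": mean_vet,
        "stats": stats_out,
        "outdir": outdir,
    }
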