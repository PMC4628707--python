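"""End-to-end orchestration: preprocess -> reformat -> segment -> reconstruct.

``run_pipeline`` executes the full chain on a configuration and writes the
four artifacts (area-function CSV, contours JSON, surface mesh, run manifest);
each stage is equally usable on its own through the library API.
"""

from __future__ import annotations

import json
import logging
import os
import platform
from typing import Sequence

import numpy as np

from . import __version__
from .centerline import (CenterlineSpline, CrossSectionStack, fit_spline,
                         load_nodes, resample_cross_sections)
from .config import RunConfig
from .reconstruct import area_function, back_transform, loft_mesh, volume_between
from .snake import load_contours, save_contours, segment_stack
from .stack import ImageStack, anisotropic_diffusion, make_isotropic, read_stack

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "preprocess_stack", "segment_cross_sections"]


def preprocess_stack(stack: ImageStack, cfg: RunConfig) -> ImageStack:
    """Isotropic resample followed by edge-preserving smoothing."""
    pre = cfg.preprocess
    iso = make_isotropic(stack, pre.scale_factor)
    return anisotropic_diffusion(iso, pre.diffusion_iterations,
                                 pre.diffusion_kappa, pre.diffusion_step)


def segment_cross_sections(xsecs: CrossSectionStack, cfg: RunConfig,
                           overrides=None, masks=None, report: dict | None = None):
    sn = cfg.snake
    seed = sn.seed_uv
    if seed is None:
        c = (cfg.centerline.size_px - 1) / 2.0
        seed = (c, c)
    return segment_stack(xsecs, seed, sn.to_params(), start_index=sn.start_index,
                         overrides=overrides, masks=masks,
                         init_radius_px=sn.init_radius_px,
                         bidirectional=sn.bidirectional, report=report)


def run_pipeline(cfg: RunConfig, stack: ImageStack | None = None,
                 nodes: np.ndarray | None = None) -> dict:
    """Run the whole pipeline and write artifacts to the output directory.

    ``stack``/``nodes`` may be passed in-memory (e.g. from the phantom
    generator); otherwise they are read from the configured paths.  Returns a
    summary dict with artifact paths, the area function and total volume.
    """
    out_dir = cfg.output.directory
    os.makedirs(out_dir, exist_ok=True)

    if stack is None:
        stack = read_stack(cfg.input.stack_path, cfg.input.format,
                           cfg.input.spacing_mm)
    if nodes is None:
        nodes = load_nodes(cfg.input.nodes_path)

    log.info("preprocessing %s voxels at spacing %s", stack.shape, stack.spacing)
    filtered = preprocess_stack(stack, cfg)

    spline = fit_spline(nodes)
    ctr = cfg.centerline
    xsecs = resample_cross_sections(filtered, spline, ctr.step_mm, ctr.size_px,
                                    ctr.pixel_size_mm)
    log.info("reformatted %d cross sections (%d px at %.3g mm)",
             len(xsecs), ctr.size_px, ctr.pixel_size_mm)

    overrides = None
    if cfg.input.overrides_path:
        contours, _ = load_contours(cfg.input.overrides_path)
        overrides = {c.slice_index: c for c in contours if c is not None}
    masks = None
    if cfg.input.mask_path:
        mask_stack = read_stack(cfg.input.mask_path, cfg.input.format,
                                cfg.input.spacing_mm)
        mask_xs = resample_cross_sections(mask_stack, spline, ctr.step_mm,
                                          ctr.size_px, ctr.pixel_size_mm)
        masks = [img > 0.5 for img in mask_xs.images]

    seg_report: dict = {}
    contours = segment_cross_sections(xsecs, cfg, overrides, masks, seg_report)
    for k, info in sorted(seg_report.get("slices", {}).items()):
        if info.get("failed"):
            log.warning("slice %d: FAILED (%s)", k, info.get("error"))
        else:
            log.info("slice %d: %d iterations%s", k, info.get("iterations", 0),
                     "" if info.get("converged") else " (cap reached)")

    af = area_function(contours, ctr.step_mm, ctr.pixel_size_mm)
    world = back_transform(contours, xsecs.frames, ctr.pixel_size_mm, ctr.size_px)

    af_path = os.path.join(out_dir, "area_function.csv")
    af.to_csv(af_path)
    contours_path = os.path.join(out_dir, "contours.json")
    save_contours(contours, ctr.pixel_size_mm, contours_path)

    mesh_path = os.path.join(out_dir, f"mesh.{cfg.output.mesh_format}")
    valid = [w for w in world if w is not None]
    if len(valid) >= 2:
        mesh = loft_mesh(world)
        mesh.save(mesh_path)
    else:
        mesh = None
        mesh_path = None
        log.warning("fewer than 2 valid contours; no mesh written")

    total_volume = volume_between(af, 0, len(af) - 1) if len(af) else 0.0

    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": cfg.digest(),
        "versions": {
            "vtseg": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "n_slices": len(xsecs),
        "failed_slices": seg_report.get("failed_slices", []),
        "per_slice_iterations": {
            str(k): v.get("iterations")
            for k, v in sorted(seg_report.get("slices", {}).items())
            if not v.get("failed")
        },
        "total_volume_mm3": total_volume,
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "area_function": af,
        "contours": contours,
        "mesh": mesh,
        "total_volume_mm3": total_volume,
        "artifacts": {
            "area_function_csv": af_path,
            "contours_json": contours_path,
            "mesh": mesh_path,
            "manifest_json": manifest_path,
        },
        "report": seg_report,
    }
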