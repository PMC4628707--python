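"""Synthetic curved-tube stacks with analytically known geometry.

The generator emulates the imaging situation the pipeline is built for: a
dark, elongated, curved air lumen (the tract) embedded in brighter tissue, on
an anisotropic sagittal voxel grid.  The tube is defined by a centerline
(straight line, circular arc, or spline through user nodes) and a radius
profile r(s); a voxel is lumen when its distance to the centerline is below
r(s).  The border is smoothed with a Gaussian of configurable width and
seeded Gaussian noise is added, so both the edge-preserving filter and the
snake's edge attraction are exercised.  The analytic centerline and area
function come back alongside the stack as ground truth.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .centerline import CenterlineSpline, fit_spline
from .reconstruct import AreaFunction
from .stack import ImageStack

__all__ = ["PhantomSpec", "generate"]


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, contrast and noise of a synthetic tube stack.

    Defaults mirror the source imaging conditions: a 128^3 grid of
    1.04 x 1.04 x 1.8 mm voxels, an 8 mm-radius tube bent on a 40 mm
    curvature radius, lumen darker than tissue (air is dark in MRI), border
    blur under a voxel and noise at 5% of the lumen/wall contrast.
    """

    centerline_kind: str = "arc"            # straight | arc | spline-nodes
    radius_profile: str = "constant"        # constant | linear-taper | sinusoidal
    radius_mm: float = 8.0
    radius_end_mm: float | None = None      # linear-taper end radius
    sin_amplitude_mm: float = 2.0           # sinusoidal profile
    sin_period_mm: float = 30.0
    curvature_radius_mm: float = 40.0       # arc
    arc_angle_deg: float = 90.0
    length_mm: float = 60.0                 # straight
    nodes: Sequence[Sequence[float]] | None = None  # spline-nodes
    lumen_intensity: float = 20.0
    wall_intensity: float = 120.0
    noise_sd: float = 5.0
    blur_sd_mm: float = 0.7
    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.04, 1.04, 1.8)
    end_padding_mm: float = 6.0             # tube continues past the centerline ends
    truth_step_mm: float = 1.04
    n_spline_nodes: int = 7                 # nodes of the returned centerline

    def __post_init__(self) -> None:
        if self.lumen_intensity == self.wall_intensity:
            raise ValueError("lumen and wall intensities must be distinct")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        if self.radius_mm <= 2.0 * max(self.spacing):
            raise ValueError(
                f"radius {self.radius_mm} mm not resolvable at spacing {self.spacing}"
            )

    @property
    def contrast(self) -> float:
        return abs(self.wall_intensity - self.lumen_intensity)


def _centerline_points(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    """Analytic centerline point(s) at arc length s; s may run past [0, L]."""
    center = 0.5 * (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing)
    if spec.centerline_kind == "straight":
        # along z through the grid center
        pts = np.zeros((len(s), 3))
        pts[:, 0] = center[0]
        pts[:, 1] = center[1]
        pts[:, 2] = center[2] - spec.length_mm / 2 + s
        return pts
    if spec.centerline_kind == "arc":
        # circular arc of radius R in the x-z plane, centered in the grid
        R = spec.curvature_radius_mm
        span = np.deg2rad(spec.arc_angle_deg)
        phi = s / R - span / 2.0  # phi = 0 at mid-arc
        arc_center = center.copy()
        arc_center[0] -= R * np.cos(span / 4)  # keep the arc near the grid middle
        pts = np.zeros((len(s), 3))
        pts[:, 0] = arc_center[0] + R * np.cos(phi)
        pts[:, 1] = center[1]
        pts[:, 2] = arc_center[2] + R * np.sin(phi)
        return pts
    raise ValueError(f"no analytic form for centerline kind {spec.centerline_kind!r}")


def _analytic_length(spec: PhantomSpec) -> float:
    if spec.centerline_kind == "straight":
        return spec.length_mm
    if spec.centerline_kind == "arc":
        return spec.curvature_radius_mm * np.deg2rad(spec.arc_angle_deg)
    raise ValueError(f"no analytic length for {spec.centerline_kind!r}")


def radius_at(spec: PhantomSpec, s: np.ndarray | float) -> np.ndarray:
    """Tube radius r(s) in mm at arc length s (clamped to the tube extent)."""
    s = np.clip(np.asarray(s, dtype=float), 0.0, _tube_length(spec))
    if spec.radius_profile == "constant":
        return np.full_like(s, spec.radius_mm)
    if spec.radius_profile == "linear-taper":
        end = spec.radius_end_mm if spec.radius_end_mm is not None else spec.radius_mm / 2
        return spec.radius_mm + (end - spec.radius_mm) * s / _tube_length(spec)
    if spec.radius_profile == "sinusoidal":
        return spec.radius_mm + spec.sin_amplitude_mm * np.sin(
            2 * np.pi * s / spec.sin_period_mm)
    raise ValueError(f"unknown radius profile {spec.radius_profile!r}")


def _tube_length(spec: PhantomSpec) -> float:
    if spec.centerline_kind == "spline-nodes":
        from .centerline import arc_length

        return arc_length(fit_spline(np.asarray(spec.nodes)))
    return _analytic_length(spec)


def _dense_centerline(spec: PhantomSpec, ds: float = 0.25
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(points, s-values) densely sampled, extended past both ends by the padding."""
    L = _tube_length(spec)
    pad = spec.end_padding_mm
    if spec.centerline_kind == "spline-nodes":
        spline = fit_spline(np.asarray(spec.nodes))
        s_in = np.arange(0.0, L + ds, ds)
        pts = np.stack([spline.point_at_arclength(s) for s in s_in])
        # extend tangentially
        t0 = pts[1] - pts[0]
        t0 /= np.linalg.norm(t0)
        t1 = pts[-1] - pts[-2]
        t1 /= np.linalg.norm(t1)
        pre_s = np.arange(-pad, 0.0, ds)
        post_s = np.arange(L + ds, L + pad + ds, ds)
        pre = pts[0] + pre_s[:, None] * t0[None]
        post = pts[-1] + (post_s - L)[:, None] * t1[None]
        return np.vstack([pre, pts, post]), np.concatenate([pre_s, s_in, post_s])
    s = np.arange(-pad, L + pad + ds, ds)
    if spec.centerline_kind == "straight":
        return _centerline_points(spec, s), s
    # arc: extend tangentially beyond the arc ends rather than around the circle
    s_in = np.clip(s, 0.0, L)
    pts = _centerline_points(spec, s_in)
    for idx, (s_end, sign) in (((s < 0), (0.0, 1.0)), ((s > L), (L, 1.0))):
        if np.any(idx):
            p = _centerline_points(spec, np.array([s_end]))[0]
            eps = 1e-4
            tangent = (_centerline_points(spec, np.array([s_end + eps]))[0]
                       - _centerline_points(spec, np.array([s_end - eps]))[0])
            tangent /= np.linalg.norm(tangent)
            pts[idx] = p[None] + (s[idx] - s_end)[:, None] * tangent[None]
    return pts, s


def centerline_nodes(spec: PhantomSpec) -> np.ndarray:
    """Node points a user would click: evenly spaced along the analytic curve."""
    if spec.centerline_kind == "spline-nodes":
        return np.asarray(spec.nodes, dtype=float)
    L = _tube_length(spec)
    s = np.linspace(0.0, L, spec.n_spline_nodes)
    return _centerline_points(spec, s)


def generate(spec: PhantomSpec, seed: int = 0
             ) -> tuple[ImageStack, CenterlineSpline, AreaFunction]:
    """Build the voxel stack, the centerline spline and the analytic area function.

    Deterministic for a given (spec, seed).  Raises if the tube (including its
    radius) leaves the voxel grid.
    """
    pts, s_vals = _dense_centerline(spec)
    L = _tube_length(spec)
    r_max = float(radius_at(spec, np.linspace(0, L, 201)).max())
    bounds_hi = (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing)
    core = (s_vals >= 0) & (s_vals <= L)
    if (np.any(pts[core] - r_max < 0) or np.any(pts[core] + r_max > bounds_hi)):
        raise ValueError("tube exits the voxel grid; enlarge the grid or shrink the tube")

    spacing = np.asarray(spec.spacing)
    grids = [np.arange(n) * spacing[ax] for ax, n in enumerate(spec.shape)]
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    vox = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    tree = cKDTree(pts)
    dist, idx = tree.query(vox, workers=-1)
    r_here = radius_at(spec, s_vals[idx])
    lumen = dist < r_here
    img = np.where(lumen, spec.lumen_intensity, spec.wall_intensity)
    img = img.reshape(spec.shape).astype(np.float64)

    if spec.blur_sd_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sd_mm / spacing)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    stack = ImageStack(img, tuple(spec.spacing))
    spline = fit_spline(centerline_nodes(spec))
    s_truth = np.arange(0.0, L + 1e-9, spec.truth_step_mm)
    truth = AreaFunction(s_truth, np.pi * radius_at(spec, s_truth) ** 2)
    return stack, spline, truth
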