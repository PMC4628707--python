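"""Centerline spline, Frenet frames and curved planar reformation.

A user supplies an ordered list of node points threading the vocal-tract lumen
(in world mm).  A piecewise cubic ``c_i(t) = a_{i,3} t^3 + a_{i,2} t^2 +
a_{i,1} t + a_{i,0}``, ``t in [0, 1]`` per segment, interpolates them with C1
continuity (Catmull–Rom tangents).  At any arc-length position the local frame
is derived from the Frenet triad: the slice x-axis is the normalized binormal
``b = c' x c''``, the y-axis the negated normalized normal ``-n``, and the
z-axis the normalized tangent; together with the centerline point they form a
rigid 4x4 affine mapping slice coordinates to world.  Resampling the volume on
planes placed at fixed arc-length steps turns the curved tract into a stack of
true cross sections.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.integrate import quad

from .stack import ImageStack

__all__ = [
    "CenterlineSpline",
    "SliceFrame",
    "CrossSectionStack",
    "fit_spline",
    "frenet_frame",
    "frames_along",
    "arc_length",
    "resample_cross_sections",
    "load_nodes",
    "save_nodes",
]

# Straightness threshold for ||c' x c''|| relative to ||c'||^2; below it the
# Frenet normal is numerically undefined and the frame is parallel-transported.
FRENET_EPS = 1e-8


@dataclasses.dataclass
class CenterlineSpline:
    """Piecewise-cubic centerline through ordered 3-D nodes (mm).

    ``coefficients[i]`` holds the four 3-vectors ``(a_{i,3}, a_{i,2}, a_{i,1},
    a_{i,0})`` of segment ``i`` so that ``c_i(t)`` runs from node ``i`` at
    ``t = 0`` to node ``i+1`` at ``t = 1``.
    """

    nodes: np.ndarray           # (n, 3)
    coefficients: np.ndarray    # (n - 1, 4, 3), highest power first

    @property
    def n_segments(self) -> int:
        return len(self.coefficients)

    def position(self, segment: int, t: float | np.ndarray) -> np.ndarray:
        a3, a2, a1, a0 = self.coefficients[segment]
        t = np.asarray(t, dtype=float)[..., None]
        return a3 * t**3 + a2 * t**2 + a1 * t + a0

    def derivative(self, segment: int, t: float | np.ndarray) -> np.ndarray:
        a3, a2, a1, _ = self.coefficients[segment]
        t = np.asarray(t, dtype=float)[..., None]
        return 3 * a3 * t**2 + 2 * a2 * t + a1

    def second_derivative(self, segment: int, t: float | np.ndarray) -> np.ndarray:
        a3, a2, _, _ = self.coefficients[segment]
        t = np.asarray(t, dtype=float)[..., None]
        return 6 * a3 * t + 2 * a2

    # -- arc-length parameterisation ------------------------------------

    def _speed(self, segment: int, t: float) -> float:
        return float(np.linalg.norm(self.derivative(segment, t)))

    def segment_lengths(self) -> np.ndarray:
        return np.array([
            quad(lambda t: self._speed(i, t), 0.0, 1.0, epsabs=1e-10, epsrel=1e-9,
                 limit=200)[0]
            for i in range(self.n_segments)
        ])

    def _arclength_table(self, samples_per_segment: int = 256):
        if not hasattr(self, "_table"):
            ts = np.linspace(0.0, 1.0, samples_per_segment)
            u_all, s_all = [], []
            offset = 0.0
            for i in range(self.n_segments):
                speeds = np.linalg.norm(
                    np.stack([self.derivative(i, t) for t in ts]), axis=1)
                # cumulative trapezoid within the segment
                ds = np.concatenate(
                    [[0.0], np.cumsum(0.5 * (speeds[1:] + speeds[:-1]) * np.diff(ts))])
                u_all.append(i + ts)
                s_all.append(offset + ds)
                offset += ds[-1]
            self._table = (np.concatenate(u_all), np.concatenate(s_all))
        return self._table

    def param_at_arclength(self, s: float) -> tuple[int, float]:
        """Invert arc length: return ``(segment, t)`` at distance ``s`` from the start."""
        u_tab, s_tab = self._arclength_table()
        s = float(np.clip(s, 0.0, s_tab[-1]))
        u = float(np.interp(s, s_tab, u_tab))
        seg = min(int(u), self.n_segments - 1)
        t = u - seg
        # two Newton corrections against the exact speed
        for _ in range(2):
            ds = float(np.interp(seg + t, u_tab, s_tab)) - s
            v = self._speed(seg, t)
            if v > 0:
                t = float(np.clip(t - ds / v, 0.0, 1.0))
        return seg, t

    def point_at_arclength(self, s: float) -> np.ndarray:
        seg, t = self.param_at_arclength(s)
        return self.position(seg, t)


@dataclasses.dataclass
class SliceFrame:
    """Rigid frame of one cross-section plane.

    ``axis_x``/``axis_y``/``axis_z`` are the orthonormal world directions of
    the slice u, v and through-plane axes (normalized binormal, negated
    normalized normal, normalized tangent); ``origin`` is the centerline point
    the slice is centered on.
    """

    origin: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray

    @property
    def affine(self) -> np.ndarray:
        """4x4 matrix with the axes as columns mapping slice coords (mm) to world."""
        T = np.eye(4)
        T[:3, 0] = self.axis_x
        T[:3, 1] = self.axis_y
        T[:3, 2] = self.axis_z
        T[:3, 3] = self.origin
        return T

    def to_world(self, u_mm: float, v_mm: float) -> np.ndarray:
        return self.origin + u_mm * self.axis_x + v_mm * self.axis_y

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "axis_x": self.axis_x.tolist(),
            "axis_y": self.axis_y.tolist(),
            "axis_z": self.axis_z.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SliceFrame":
        return cls(*(np.asarray(d[k], dtype=float)
                     for k in ("origin", "axis_x", "axis_y", "axis_z")))


@dataclasses.dataclass
class CrossSectionStack:
    """Cross-section images with their frames along the centerline."""

    images: list[np.ndarray]
    frames: list[SliceFrame]
    pixel_size: float  # mm per in-plane pixel
    step: float        # mm between consecutive slice centers

    def __post_init__(self) -> None:
        if len(self.images) != len(self.frames):
            raise ValueError("images and frames must have equal length")
        if self.pixel_size <= 0 or self.step <= 0:
            raise ValueError("pixel_size and step must be > 0")

    def __len__(self) -> int:
        return len(self.images)

    def save(self, tiff_path: str | os.PathLike, sidecar_path: str | os.PathLike) -> None:
        import tifffile

        tifffile.imwrite(os.fspath(tiff_path),
                         np.stack(self.images).astype(np.float32))
        meta = {
            "pixel_size_mm": self.pixel_size,
            "step_mm": self.step,
            "frames": [f.to_dict() for f in self.frames],
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, tiff_path: str | os.PathLike, sidecar_path: str | os.PathLike
             ) -> "CrossSectionStack":
        import tifffile

        images = [np.asarray(p, dtype=np.float64) for p in tifffile.imread(tiff_path)]
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        frames = [SliceFrame.from_dict(d) for d in meta["frames"]]
        return cls(images, frames, meta["pixel_size_mm"], meta["step_mm"])


def fit_spline(nodes: Sequence[Sequence[float]]) -> CenterlineSpline:
    """Interpolate ordered nodes with a C1 piecewise cubic (Catmull–Rom tangents).

    Node tangents are central finite differences ``(p_{i+1} - p_{i-1}) / 2``;
    the ends use one-sided differences, so two nodes degenerate to the straight
    segment between them.
    """
    pts = np.asarray(nodes, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need an ordered (n >= 2, 3) array of node points")
    seg = np.diff(pts, axis=0)
    if np.any(np.linalg.norm(seg, axis=1) < 1e-12):
        raise ValueError("duplicate consecutive nodes")

    tangents = np.empty_like(pts)
    tangents[1:-1] = 0.5 * (pts[2:] - pts[:-2])
    tangents[0] = pts[1] - pts[0]
    tangents[-1] = pts[-1] - pts[-2]

    coeffs = np.empty((len(pts) - 1, 4, 3))
    for i in range(len(pts) - 1):
        p0, p1 = pts[i], pts[i + 1]
        m0, m1 = tangents[i], tangents[i + 1]
        coeffs[i, 0] = 2 * p0 - 2 * p1 + m0 + m1        # a3
        coeffs[i, 1] = -3 * p0 + 3 * p1 - 2 * m0 - m1   # a2
        coeffs[i, 2] = m0                               # a1
        coeffs[i, 3] = p0                               # a0
    return CenterlineSpline(pts, coeffs)


def arc_length(spline: CenterlineSpline) -> float:
    """Total centerline length in mm by adaptive quadrature of ``||c'||``."""
    return float(spline.segment_lengths().sum())


def _any_perpendicular(t_hat: np.ndarray) -> np.ndarray:
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(t_hat)))] = 1.0
    perp = ref - np.dot(ref, t_hat) * t_hat
    return perp / np.linalg.norm(perp)


def frenet_frame(spline: CenterlineSpline, segment: int, t: float,
                 prev: SliceFrame | None = None) -> SliceFrame:
    """Frame at ``(segment, t)``: ``axis_z = t_hat``, ``axis_x = b_hat``,
    ``axis_y = -n_hat``.

    Where curvature vanishes (``||c' x c''|| < eps * ||c'||^2``) the binormal
    is undefined; the previous frame's x-axis is then parallel-transported
    onto the new normal plane (an arbitrary fixed perpendicular seeds a fully
    straight curve).  When a previous frame is supplied, the binormal sign is
    chosen to minimize the angle to its x-axis so adjacent slices never flip
    by 180 degrees.
    """
    d1 = spline.derivative(segment, t)
    speed = np.linalg.norm(d1)
    if speed < 1e-12:
        raise ValueError(f"degenerate centerline: zero tangent at ({segment}, {t})")
    t_hat = d1 / speed
    d2 = spline.second_derivative(segment, t)
    cross = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross)

    if cross_norm < FRENET_EPS * speed * speed:
        x_seed = prev.axis_x if prev is not None else _any_perpendicular(t_hat)
        x = x_seed - np.dot(x_seed, t_hat) * t_hat
        nrm = np.linalg.norm(x)
        if nrm < 1e-9:  # previous x happens to be parallel to the new tangent
            x_seed = prev.axis_y if prev is not None else _any_perpendicular(t_hat)
            x = x_seed - np.dot(x_seed, t_hat) * t_hat
            nrm = np.linalg.norm(x)
        x = x / nrm
    else:
        x = cross / cross_norm
        if prev is not None and np.dot(x, prev.axis_x) < 0:
            x = -x
    y = np.cross(t_hat, x)
    origin = spline.position(segment, t)
    return SliceFrame(origin=origin, axis_x=x, axis_y=y, axis_z=t_hat)


def frames_along(spline: CenterlineSpline, step_mm: float) -> list[SliceFrame]:
    """Frames at equal arc-length increments from the start to the end of the spline."""
    if step_mm <= 0:
        raise ValueError("step_mm must be > 0")
    total = arc_length(spline)
    n = int(np.floor(total / step_mm)) + 1
    frames: list[SliceFrame] = []
    prev: SliceFrame | None = None
    for k in range(n):
        seg, t = spline.param_at_arclength(k * step_mm)
        frame = frenet_frame(spline, seg, t, prev=prev)
        frames.append(frame)
        prev = frame
    return frames


def resample_cross_sections(stack: ImageStack, spline: CenterlineSpline,
                            step_mm: float, size_px: int,
                            pixel_size_mm: float) -> CrossSectionStack:
    """Resample the volume into cross-section images orthogonal to the centerline.

    Frames are placed every ``step_mm`` of arc length; each image is
    ``size_px x size_px`` with the slice center pixel on the centerline, pixel
    (u, v) sampled trilinearly at ``origin + (u - c) px X + (v - c) px Y``
    with ``c = (size_px - 1) / 2``.  Samples outside the volume take 0.
    """
    if size_px < 1 or pixel_size_mm <= 0:
        raise ValueError("size_px must be >= 1 and pixel_size_mm > 0")
    frames = frames_along(spline, step_mm)
    c = (size_px - 1) / 2.0
    uv = (np.arange(size_px) - c) * pixel_size_mm
    uu, vv = np.meshgrid(uv, uv, indexing="ij")
    spacing = np.asarray(stack.spacing)

    images = []
    for frame in frames:
        world = (frame.origin[None, None, :]
                 + uu[..., None] * frame.axis_x[None, None, :]
                 + vv[..., None] * frame.axis_y[None, None, :])
        coords = (world / spacing).transpose(2, 0, 1)
        img = ndimage.map_coordinates(stack.voxels, coords, order=1,
                                      mode="constant", cval=0.0)
        images.append(img)
    return CrossSectionStack(images, frames, pixel_size_mm, step_mm)


def load_nodes(path: str | os.PathLike) -> np.ndarray:
    """Read centerline nodes from a JSON array of [x, y, z] world-mm triples."""
    with open(path) as fh:
        data = json.load(fh)
    pts = np.asarray(data, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{path}: expected a JSON array of [x, y, z] triples")
    return pts


def save_nodes(nodes: np.ndarray, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(np.asarray(nodes, dtype=float).tolist(), fh, indent=1)
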