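"""Geometry outputs: area functions, volumes, world-space contours and meshes.

Per-slice cross-sectional areas (shoelace formula on the closed contour
polygon, scaled by the pixel size) are assembled into the area function
A(s) — the 1-D descriptor acoustic models consume.  Volumes follow by
superposition of slice areas (rectangle rule, area x step).  Contours can be
mapped back from slice pixel coordinates to world mm through their rigid slice
frames, and the resulting ring stack lofted into a triangulated surface mesh.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from typing import Sequence

import numpy as np

from .centerline import SliceFrame
from .snake import Contour

__all__ = [
    "AreaFunction",
    "SurfaceMesh",
    "contour_area",
    "area_function",
    "volume_between",
    "back_transform",
    "loft_mesh",
]


@dataclasses.dataclass
class AreaFunction:
    """Cross-sectional area (mm^2) vs arc-length position (mm), fixed step.

    Failed slices are NaN.
    """

    positions: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.positions.shape != self.areas.shape:
            raise ValueError("positions and areas must have equal length")
        if len(self.positions) > 1:
            steps = np.diff(self.positions)
            if np.any(steps <= 0) or np.ptp(steps) > 1e-9 * steps[0]:
                raise ValueError("positions must increase with a constant step")
        with np.errstate(invalid="ignore"):
            if np.any(self.areas < 0):
                raise ValueError("areas must be >= 0")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0]) if len(self) > 1 else 0.0

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("position_mm,area_mm2\n")
            for s, a in zip(self.positions, self.areas):
                fh.write(f"{s:.6f},{'' if np.isnan(a) else format(a, '.6f')}\n")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "AreaFunction":
        pos, areas = [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                s, a = line.strip().split(",")
                pos.append(float(s))
                areas.append(float(a) if a else np.nan)
        return cls(np.asarray(pos), np.asarray(areas))


@dataclasses.dataclass
class SurfaceMesh:
    """Triangle mesh in world mm."""

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray     # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def volume(self) -> float:
        """Enclosed volume (mm^3) by the divergence theorem; needs closed caps."""
        return float(abs(self.to_trimesh().volume))

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def save(self, path: str | os.PathLike) -> None:
        """Write PLY (ascii) or OBJ, by extension."""
        path = os.fspath(path)
        mesh = self.to_trimesh()
        if path.lower().endswith(".ply"):
            from trimesh.exchange.ply import export_ply

            with open(path, "wb") as fh:
                fh.write(export_ply(mesh, encoding="ascii"))
        elif path.lower().endswith(".obj"):
            mesh.export(path, file_type="obj")
        else:
            raise ValueError(f"unsupported mesh format for {path} (use .ply or .obj)")


def contour_area(contour: Contour, pixel_size_mm: float) -> float:
    """Polygon area in mm^2: |shoelace sum| / 2 times pixel_size^2.

    Orientation does not matter; a self-intersecting polygon triggers a
    warning and the signed-area magnitude is still returned.
    """
    pts = contour.nodes
    if len(pts) < 3:
        raise ValueError("need >= 3 nodes for an area")
    if not contour.is_simple():
        warnings.warn(f"slice {contour.slice_index}: self-intersecting contour; "
                      "returning signed-area magnitude", stacklevel=2)
    x, y = pts[:, 0], pts[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(signed)) * pixel_size_mm ** 2


def area_function(contours: Sequence[Contour | None], step_mm: float,
                  pixel_size_mm: float, interpolate_missing: bool = True
                  ) -> AreaFunction:
    """Assemble per-slice areas into an area function.

    Slices that failed (``None``) become NaN; interior gaps flanked by valid
    slices are linearly interpolated when ``interpolate_missing`` is set,
    leading/trailing gaps stay missing.
    """
    areas = np.array([
        np.nan if c is None else contour_area(c, pixel_size_mm) for c in contours
    ])
    positions = np.arange(len(areas)) * step_mm
    if interpolate_missing and np.any(np.isnan(areas)) and np.any(~np.isnan(areas)):
        valid = np.flatnonzero(~np.isnan(areas))
        interior = (np.arange(len(areas)) >= valid[0]) & (np.arange(len(areas)) <= valid[-1])
        gap = np.isnan(areas) & interior
        if np.any(gap):
            areas[gap] = np.interp(positions[gap], positions[valid], areas[valid])
    return AreaFunction(positions, areas)


def volume_between(af: AreaFunction, from_index: int, to_index: int,
                   rule: str = "rectangle") -> float:
    """Volume (mm^3) over slices ``from_index..to_index`` inclusive.

    Default is superposition of segment areas (area x step summed); the
    trapezoid rule is available as an option.  Missing slices in the range are
    skipped with a warning.
    """
    n = len(af)
    if not (0 <= from_index <= to_index < n):
        raise ValueError(f"invalid slice range [{from_index}, {to_index}] for {n} slices")
    areas = af.areas[from_index:to_index + 1]
    if np.any(np.isnan(areas)):
        warnings.warn("missing areas in volume range; treated as absent slices",
                      stacklevel=2)
    if rule == "rectangle":
        return float(np.nansum(areas) * af.step)
    if rule == "trapezoid":
        a = areas[~np.isnan(areas)]
        if len(a) < 2:
            return float(np.nansum(areas) * af.step)
        return float((a[0] / 2 + a[1:-1].sum() + a[-1] / 2) * af.step)
    raise ValueError(f"unknown rule {rule!r}")


def back_transform(contours: Sequence[Contour | None], frames: Sequence[SliceFrame],
                   pixel_size_mm: float, image_size_px: int
                   ) -> list[np.ndarray | None]:
    """Map contours from slice pixel coordinates back to world mm.

    Pixel node (u, v) of slice k maps to
    ``origin_k + (u - c) px X_k + (v - c) px Y_k`` with ``c = (size - 1) / 2``,
    the exact inverse of the cross-section sampling convention.
    """
    if len(contours) != len(frames):
        raise ValueError(f"{len(contours)} contours vs {len(frames)} frames")
    c = (image_size_px - 1) / 2.0
    out: list[np.ndarray | None] = []
    for contour, frame in zip(contours, frames):
        if contour is None:
            out.append(None)
            continue
        uv = (contour.nodes - c) * pixel_size_mm
        world = (frame.origin[None, :]
                 + uv[:, 0:1] * frame.axis_x[None, :]
                 + uv[:, 1:2] * frame.axis_y[None, :])
        out.append(world)
    return out


def _resample_ring(ring: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed 3-D polygon to n vertices, uniform in arc length."""
    closed = np.vstack([ring, ring[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, s, closed[:, d])
    return out


def _ring_normal(ring: np.ndarray) -> np.ndarray:
    """Newell normal of a (possibly non-planar) closed polygon."""
    nxt = np.roll(ring, -1, axis=0)
    n = np.array([
        np.sum((ring[:, 1] - nxt[:, 1]) * (ring[:, 2] + nxt[:, 2])),
        np.sum((ring[:, 2] - nxt[:, 2]) * (ring[:, 0] + nxt[:, 0])),
        np.sum((ring[:, 0] - nxt[:, 0]) * (ring[:, 1] + nxt[:, 1])),
    ])
    nrm = np.linalg.norm(n)
    return n / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])


def loft_mesh(world_polygons: Sequence[np.ndarray | None], n_ring: int | None = None,
              caps: bool = True) -> SurfaceMesh:
    """Stitch a stack of world-space contour rings into a triangle mesh.

    Rings are resampled to a common vertex count (the largest ring by default)
    so the tube body is watertight, wound consistently, and each consecutive
    pair rotationally aligned by the cyclic shift minimizing total inter-ring
    edge length (minimal twist).  Degenerate rings (< 3 points) are skipped
    with a warning; optional centroid-fan caps close the ends.
    """
    rings = [np.asarray(r, dtype=float) for r in world_polygons if r is not None]
    good = []
    for r in rings:
        if len(r) < 3:
            warnings.warn("skipping degenerate ring with < 3 points", stacklevel=2)
        else:
            good.append(r)
    if len(good) < 2:
        raise ValueError("need at least 2 valid rings to loft a surface")
    n = n_ring or max(len(r) for r in good)
    rings = [_resample_ring(r, n) for r in good]

    # consistent winding: flip rings whose normal opposes the previous one
    ref = _ring_normal(rings[0])
    for k in range(1, len(rings)):
        nk = _ring_normal(rings[k])
        if np.dot(nk, ref) < 0:
            rings[k] = rings[k][::-1].copy()
            nk = -nk
        ref = nk

    # minimal-twist cyclic alignment of each ring to its predecessor
    for k in range(1, len(rings)):
        prev, cur = rings[k - 1], rings[k]
        costs = [np.linalg.norm(prev - np.roll(cur, -shift, axis=0), axis=1).sum()
                 for shift in range(n)]
        rings[k] = np.roll(cur, -int(np.argmin(costs)), axis=0)

    vertices = np.vstack(rings)
    faces = []
    for k in range(len(rings) - 1):
        a = k * n
        b = (k + 1) * n
        for i in range(n):
            j = (i + 1) % n
            faces.append([a + i, b + i, a + j])
            faces.append([b + i, b + j, a + j])
    if caps:
        c0 = len(vertices)
        vertices = np.vstack([vertices, rings[0].mean(axis=0)[None],
                              rings[-1].mean(axis=0)[None]])
        last = (len(rings) - 1) * n
        for i in range(n):
            j = (i + 1) % n
            faces.append([c0, i, j])                      # start cap
            faces.append([c0 + 1, last + j, last + i])    # end cap, opposite winding
    return SurfaceMesh(vertices, np.asarray(faces, dtype=int))
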