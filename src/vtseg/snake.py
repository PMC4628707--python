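"""Greedy active contours on cross-section images with inter-slice coupling.

Each closed contour node carries the energy balance

    E = E_cont + E_curv + E_ext + E_dev

with, for a candidate position ``v`` of node ``i``:

* ``E_cont = alpha * (||v_{i+1} - v||^2 + ||v - v_{i-1}||^2) / 2``  (symmetric
  first difference of the contour curve; with the default ``alpha < 0`` the
  minimizer rewards stretching, i.e. the contour expands from its circular
  seed — the symmetric form rewards only radial stretch, a one-sided
  difference would also reward tangential drift),
* ``E_curv = beta * ||v_{i+1} - 2 v + v_{i-1}||^2``  (bending stiffness),
* ``E_ext = -gamma * ||grad I||^2``  (edge attraction, sampled bilinearly),
* ``E_dev = delta * d^4`` where ``d`` is the distance to the nearest node of
  the previous slice's contour (zero on the first slice) — the cross link that
  keeps adjacent cross sections coherent along the tube.

A greedy pass moves every node, in order, to the lowest-energy position of its
(window x window) pixel neighbourhood; node insertion/deletion keeps spacings
inside ``[s_min, s_max]``; a slice converges when no node moves, or after
``max_iter`` passes.  Everything is deterministic.

Because the four raw terms live on incommensurate scales (px^2 vs
intensity^2/px^2 vs px^4), each term is min–max normalized over the search
window before weighting, the standard greedy-snake practice; raw mode is
available.  The external term's normalization denominator is floored at 5% of
the image-wide gradient maximum so that noise in flat regions is not blown up
to full scale.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "SnakeParams",
    "Contour",
    "GradientImage",
    "init_circle",
    "default_node_count",
    "node_energy",
    "greedy_iterate",
    "resample_nodes",
    "segment_slice",
    "segment_stack",
    "estimate_lumen_radius",
    "SegmentationFailure",
]

# Fraction of the global gradient maximum used to floor the min-max
# denominator of the external term inside flat windows.
EXT_NORM_FLOOR = 0.05


class SegmentationFailure(RuntimeError):
    """Raised when a contour collapses below 3 nodes on a slice."""


def _default_s_max(p: "SnakeParams") -> float:
    return 4.0 * p.s_min


@dataclasses.dataclass
class SnakeParams:
    """Weights and limits of the greedy snake.

    ``alpha`` multiplies the continuity term (negative by default: expansion),
    ``beta`` the curvature term, ``gamma`` the edge term, ``delta`` the
    inter-slice deviation term.  ``s_min``/``s_max`` bound node spacing in
    pixels (``s_max = 4 s_min`` unless overridden), ``max_iter`` caps greedy
    passes per slice and ``window`` is the odd side length of the search
    neighbourhood.
    """

    alpha: float = -0.8
    beta: float = 0.8
    gamma: float = 2.0
    delta: float = 0.4
    s_min: float = 3.0
    s_max: float | None = None
    max_iter: int = 30
    window: int = 3
    normalize: bool = True
    resample_each_iter: bool = True
    dev_to_segments: bool = False  # measure d to polyline segments, not vertices
    edge_blur_px: float = 4.0      # coarsest capture blur of the edge map (0 = sharp)
    refine_iter: int = 15          # extra sharp-map passes after capture

    def __post_init__(self) -> None:
        if self.s_max is None:
            self.s_max = _default_s_max(self)
        if self.s_min < 1:
            raise ValueError("s_min must be >= 1 px")
        if self.s_max < self.s_min:
            raise ValueError("s_max must be >= s_min")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


@dataclasses.dataclass
class Contour:
    """Ordered closed polygon of real-valued node positions in slice pixels."""

    nodes: np.ndarray  # (n, 2) float (u, v) pixel coordinates
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2 or len(self.nodes) < 3:
            raise ValueError("a contour needs at least 3 (u, v) nodes")

    def __len__(self) -> int:
        return len(self.nodes)

    def spacings(self) -> np.ndarray:
        """Distance from each node to its successor (closed)."""
        return np.linalg.norm(np.roll(self.nodes, -1, axis=0) - self.nodes, axis=1)

    def is_simple(self) -> bool:
        from shapely.geometry import Polygon

        return Polygon(self.nodes).is_valid


@dataclasses.dataclass
class GradientImage:
    """Squared gradient-magnitude image ``||grad I||^2`` (edge map)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("squared gradient magnitude cannot be negative")
        self.global_max = float(self.values.max()) if self.values.size else 0.0

    @classmethod
    def from_image(cls, image: np.ndarray, method: str = "central") -> "GradientImage":
        image = np.asarray(image, dtype=np.float64)
        if method == "central":
            gu, gv = np.gradient(image)
        elif method == "sobel":
            gu = ndimage.sobel(image, axis=0) / 8.0
            gv = ndimage.sobel(image, axis=1) / 8.0
        else:
            raise ValueError(f"unknown gradient method {method!r}")
        return cls(gu * gu + gv * gv)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Bilinear samples at (n, 2) pixel positions; 0 outside."""
        pts = np.atleast_2d(points)
        return ndimage.map_coordinates(self.values, pts.T, order=1,
                                       mode="constant", cval=0.0)


def default_node_count(radius: float, s_min: float) -> int:
    """Node count so the initial spacing is ``2 s_min`` (mid-range of the bounds)."""
    return max(3, int(np.ceil(2.0 * np.pi * radius / (2.0 * s_min))))


def init_circle(center: Sequence[float], radius: float, n_nodes: int,
                slice_index: int = 0) -> Contour:
    """Counter-clockwise circular seed contour with equally spaced nodes."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    angles = 2.0 * np.pi * np.arange(n_nodes) / n_nodes
    cx, cy = center
    nodes = np.stack([cx + radius * np.cos(angles), cy + radius * np.sin(angles)], axis=1)
    return Contour(nodes, slice_index)


# ---------------------------------------------------------------------------
# energy terms


def _window_offsets(window: int) -> np.ndarray:
    """Integer offsets in tie-break preference order.

    (0, 0) first, then increasing squared magnitude, then row-major order of
    the window grid.
    """
    half = window // 2
    offs = [(du, dv) for du in range(-half, half + 1) for dv in range(-half, half + 1)]
    order = sorted(range(len(offs)),
                   key=lambda k: (offs[k] != (0, 0),
                                  offs[k][0] ** 2 + offs[k][1] ** 2, k))
    return np.asarray([offs[k] for k in order], dtype=float)


def _nearest_prev_distance(cands: np.ndarray, prev: Contour,
                           to_segments: bool) -> np.ndarray:
    """Distance from each candidate to the previous slice's contour."""
    if not to_segments:
        diff = cands[:, None, :] - prev.nodes[None, :, :]
        return np.sqrt((diff ** 2).sum(-1)).min(axis=1)
    a = prev.nodes
    b = np.roll(prev.nodes, -1, axis=0)
    ab = b - a
    denom = (ab ** 2).sum(-1)
    denom[denom == 0] = 1.0
    ap = cands[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None]).sum(-1) / denom[None], 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d = np.sqrt(((cands[:, None, :] - proj) ** 2).sum(-1))
    return d.min(axis=1)


def _raw_terms(contour: Contour, i: int, cands: np.ndarray, grad: GradientImage,
               prev: Contour | None, p: SnakeParams) -> np.ndarray:
    """(4, n_candidates) array of unweighted, unnormalized term values."""
    n = len(contour)
    v_prev = contour.nodes[(i - 1) % n]
    v_next = contour.nodes[(i + 1) % n]
    # symmetric first-difference: tangential moves trade one neighbour distance
    # against the other, so only radial stretch changes the term (see methods)
    cont = 0.5 * (((v_next - cands) ** 2).sum(-1) + ((cands - v_prev) ** 2).sum(-1))
    curv = ((v_next - 2.0 * cands + v_prev) ** 2).sum(-1)
    ext = -grad.sample(cands)
    if prev is None:
        dev = np.zeros(len(cands))
    else:
        dev = _nearest_prev_distance(cands, prev, p.dev_to_segments) ** 4
    return np.stack([cont, curv, ext, dev])


def _normalize_terms(terms: np.ndarray, grad: GradientImage) -> np.ndarray:
    """Min–max normalize each term over the candidate set.

    The external term's denominator is floored at ``EXT_NORM_FLOOR`` times the
    global gradient maximum; constant terms normalize to zero.
    """
    out = np.zeros_like(terms)
    for k in range(terms.shape[0]):
        lo = terms[k].min()
        rng = terms[k].max() - lo
        if k == 2:
            rng = max(rng, EXT_NORM_FLOOR * grad.global_max)
        if rng > 1e-12:
            out[k] = (terms[k] - lo) / rng
    return out


def _candidate_energies(contour: Contour, i: int, cands: np.ndarray,
                        grad: GradientImage, prev: Contour | None,
                        p: SnakeParams,
                        mask: np.ndarray | None) -> np.ndarray:
    weights = np.array([p.alpha, p.beta, p.gamma, p.delta])
    terms = _raw_terms(contour, i, cands, grad, prev, p)
    if p.normalize:
        terms = _normalize_terms(terms, grad)
    energy = weights @ terms
    # candidates outside the image (or in the forbidden mask) are never taken
    h, w = grad.values.shape
    oob = ((cands[:, 0] < 0) | (cands[:, 0] > h - 1)
           | (cands[:, 1] < 0) | (cands[:, 1] > w - 1))
    if mask is not None:
        iu = np.clip(np.rint(cands[:, 0]).astype(int), 0, h - 1)
        iv = np.clip(np.rint(cands[:, 1]).astype(int), 0, w - 1)
        oob |= mask[iu, iv].astype(bool)
    energy[oob] = np.inf
    return energy


def node_energy(contour: Contour, i: int, candidate: Sequence[float],
                grad: GradientImage, prev: Contour | None,
                p: SnakeParams, mask: np.ndarray | None = None) -> float:
    """Energy of moving node ``i`` to ``candidate``.

    In normalized mode the min–max statistics are taken over the node's search
    window centered on its current position, with the candidate included, so
    the value matches what a greedy pass would score.
    """
    candidate = np.asarray(candidate, dtype=float)
    cands = contour.nodes[i] + _window_offsets(p.window)
    # evaluate the query candidate jointly with the window so normalization
    # statistics are shared
    all_c = np.vstack([cands, candidate[None]])
    energies = _candidate_energies(contour, i, all_c, grad, prev, p, mask)
    return float(energies[-1])


def greedy_iterate(contour: Contour, grad: GradientImage,
                   prev: Contour | None, p: SnakeParams,
                   mask: np.ndarray | None = None) -> tuple[Contour, int]:
    """One greedy pass: each node, in order, moves to its window's energy minimum.

    Ties prefer the current position, then the smallest offset magnitude, then
    row-major window order.  Returns the updated contour and how many nodes
    moved.
    """
    nodes = contour.nodes.copy()
    work = Contour(nodes, contour.slice_index)
    offsets = _window_offsets(p.window)
    moved = 0
    for i in range(len(nodes)):
        cands = nodes[i] + offsets
        energies = _candidate_energies(work, i, cands, grad, prev, p, mask)
        best = int(np.argmin(energies))  # offsets are in preference order
        if best != 0 and np.isfinite(energies[best]):
            nodes[i] = cands[best]
            moved += 1
    return work, moved


def resample_nodes(contour: Contour, p: SnakeParams) -> Contour:
    """Insert midpoints where spacing > s_max, then delete the second node of
    pairs closer than s_min (never dropping below 3 nodes)."""
    nodes = contour.nodes
    n = len(nodes)
    out: list[np.ndarray] = []
    for i in range(n):
        a, b = nodes[i], nodes[(i + 1) % n]
        out.append(a)
        if np.linalg.norm(b - a) > p.s_max:
            out.append(0.5 * (a + b))
    pruned: list[np.ndarray] = []
    remaining = len(out)
    skip = False
    for i in range(len(out)):
        if skip:
            skip = False
            continue
        a = out[i]
        b = out[(i + 1) % len(out)]
        pruned.append(a)
        if remaining > 3 and np.linalg.norm(b - a) < p.s_min and i + 1 < len(out):
            skip = True  # drop the second point of the close pair
            remaining -= 1
    return Contour(np.asarray(pruned), contour.slice_index)


def _snake_loop(contour: Contour, grad: GradientImage, prev: Contour | None,
                p: SnakeParams, mask: np.ndarray | None,
                max_iter: int) -> tuple[Contour, int, bool]:
    iterations = 0
    moved = 0
    for _ in range(max_iter):
        contour, moved = greedy_iterate(contour, grad, prev, p, mask)
        iterations += 1
        if moved == 0:
            break
        if p.resample_each_iter:
            contour = resample_nodes(contour, p)
        if len(contour) < 3:
            raise SegmentationFailure(
                f"contour collapsed on slice {contour.slice_index}")
    return contour, iterations, moved == 0


def segment_slice(image: np.ndarray, init: Contour, prev: Contour | None,
                  p: SnakeParams, mask: np.ndarray | None = None,
                  grad: GradientImage | None = None,
                  report: dict | None = None) -> Contour:
    """Run the greedy snake on one cross section until it stops moving or the
    iteration cap is reached.

    With ``edge_blur_px > 0`` the main passes run on a coarse-to-fine ladder
    of Gaussian-blurred edge maps (sigma halving from ``edge_blur_px`` down to
    1 px) so the attraction basin first spans the whole lumen and then
    sharpens, followed by up to ``refine_iter`` passes on the raw map to land
    on the true gradient ridge.  Passing ``grad`` explicitly skips the capture
    ladder and uses that map throughout.
    """
    sharp = grad if grad is not None else GradientImage.from_image(image)
    sigmas: list[float] = []
    if grad is None and p.edge_blur_px > 0:
        s = float(p.edge_blur_px)
        while s >= 2.0:
            sigmas.append(s)
            s /= 2.0
    contour = Contour(init.nodes.copy(), init.slice_index)
    iterations = 0
    converged = True
    for s in sigmas:
        blurred = GradientImage(ndimage.gaussian_filter(sharp.values, s))
        contour, extra, converged = _snake_loop(contour, blurred, prev, p,
                                                mask, p.max_iter)
        iterations += extra
    final_cap = p.refine_iter if sigmas else p.max_iter
    if final_cap > 0:
        contour, extra, converged = _snake_loop(contour, sharp, prev, p, mask,
                                                final_cap)
        iterations += extra
    if not p.resample_each_iter:
        contour = resample_nodes(contour, p)
    if report is not None:
        report["iterations"] = iterations
        report["converged"] = bool(converged)
    if not contour.is_simple():
        log.warning("slice %d: converged contour self-intersects", init.slice_index)
    return contour


def estimate_lumen_radius(image: np.ndarray, seed: Sequence[float],
                          tol_frac: float = 0.5) -> float:
    """Equivalent radius (px) of the intensity region around the seed point.

    Pixels within ``tol_frac`` of the image's maximum deviation from the seed
    intensity are flood-connected; the connected component containing the seed
    gives an equivalent circular radius.  This mimics how an operator sizes
    the starting circle inside the lumen.
    """
    image = np.asarray(image, dtype=float)
    iu = int(np.clip(round(seed[0]), 0, image.shape[0] - 1))
    iv = int(np.clip(round(seed[1]), 0, image.shape[1] - 1))
    dev = np.abs(image - image[iu, iv])
    region = dev < tol_frac * dev.max() if dev.max() > 0 else np.ones_like(dev, bool)
    labels, _ = ndimage.label(region)
    comp = labels == labels[iu, iv]
    return float(np.sqrt(comp.sum() / np.pi))


def segment_stack(xsecs, seed: Sequence[float], p: SnakeParams,
                  start_index: int = 0,
                  overrides: Mapping[int, Contour] | None = None,
                  masks: Sequence[np.ndarray | None] | None = None,
                  init_radius_px: float | None = None,
                  bidirectional: bool = True,
                  report: dict | None = None) -> list[Contour | None]:
    """Segment every cross section, propagating contours between slices.

    The start slice grows a circular seed centered on ``seed`` (sized by
    :func:`estimate_lumen_radius` unless ``init_radius_px`` is given); each later
    slice reuses its predecessor's result as both the initialization and the
    ``prev`` contour of the deviation energy.  ``overrides`` replace computed
    contours verbatim (the file-based stand-in for manual correction) and feed
    their successors; ``masks`` marks forbidden pixels (e.g. the teeth region)
    with infinite external energy.  A failed slice is recorded and skipped;
    propagation continues from the last good contour.
    """
    overrides = dict(overrides or {})
    n = len(xsecs.images)
    if not 0 <= start_index < n:
        raise ValueError(f"start_index {start_index} outside stack of {n} slices")
    results: list[Contour | None] = [None] * n
    info: dict[int, dict] = {}

    def mask_for(k: int):
        return None if masks is None else masks[k]

    def process(k: int, init: Contour | None, prev: Contour | None) -> Contour | None:
        if k in overrides:
            c = Contour(np.asarray(overrides[k].nodes, dtype=float), k)
            info[k] = {"iterations": 0, "converged": True, "override": True}
            return c
        if init is None:
            return None
        rep: dict = {}
        try:
            c = segment_slice(xsecs.images[k], Contour(init.nodes.copy(), k),
                              prev, p, mask=mask_for(k), report=rep)
        except SegmentationFailure as exc:
            log.error("slice %d failed: %s", k, exc)
            info[k] = {"failed": True, "error": str(exc)}
            return None
        info[k] = rep
        return c

    if init_radius_px is None:
        est = estimate_lumen_radius(xsecs.images[start_index], seed)
        init_radius_px = max(3.0, 0.8 * est)
        # node budget sized for the estimated final perimeter, not the
        # deliberately shrunken starting circle
        n_seed = default_node_count(max(est, init_radius_px), p.s_min)
    else:
        n_seed = default_node_count(init_radius_px, p.s_min)
    seed_contour = init_circle(seed, init_radius_px, n_seed, start_index)
    results[start_index] = process(start_index, seed_contour, None)

    last = results[start_index]
    for k in range(start_index + 1, n):
        out = process(k, last, last)
        results[k] = out
        if out is not None:
            last = out
    if bidirectional:
        last = results[start_index]
        for k in range(start_index - 1, -1, -1):
            out = process(k, last, last)
            results[k] = out
            if out is not None:
                last = out
    if report is not None:
        report["slices"] = info
        report["failed_slices"] = sorted(k for k, v in info.items() if v.get("failed"))
    return results


# ---------------------------------------------------------------------------
# contour JSON I/O


def save_contours(contours: Sequence[Contour | None], pixel_size_mm: float,
                  path: str | os.PathLike) -> None:
    data = {
        "pixel_size_mm": pixel_size_mm,
        "contours": [
            None if c is None else {"slice_index": c.slice_index,
                                    "nodes": c.nodes.tolist()}
            for c in contours
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_contours(path: str | os.PathLike) -> tuple[list[Contour | None], float]:
    with open(path) as fh:
        data = json.load(fh)
    contours = [
        None if c is None else Contour(np.asarray(c["nodes"]), c["slice_index"])
        for c in data["contours"]
    ]
    return contours, float(data["pixel_size_mm"])
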