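"""The six measuring functions on radially split lesion halves.

A splitting line through the lesion's center of mass divides it in two.
Each half yields, per measuring function, a vertex-filtered graph whose
size function summarizes that half:

* ``boundary`` — boundary polyline points strictly on one side, connected
  as along the contour, valued by their perpendicular distance to the
  line (arcs cut by the line fall apart into separate components);
* ``mass`` — a path graph along the line (unit-pixel arc positions t),
  valued by the sum of interpolated grey levels along the orthogonal
  segment into that side, clipped to the lesion mask;
* ``color`` — the same path graph, valued by the summed RGB-space
  distances between consecutive samples along the orthogonal segment.

The three ``*_neg`` variants negate the values on the same graphs (the
size function then reads superlevel rather than sublevel structure).  The
two halves of one (line, function) pair are jointly normalized by the
largest absolute value so that distances are dimensionless and comparable
across lesion sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .imaging import LesionSegmentation
from .sfcore import SizeGraph

__all__ = [
    "SplittingLine",
    "DegenerateHalfError",
    "boundary_mf",
    "mass_mf",
    "color_mf",
    "negate_mf",
    "joint_normalize",
    "half_graphs",
    "MF_BASES",
    "MF_ORDER",
]

MF_BASES = ("boundary", "mass", "color")
MF_ORDER = ("boundary", "mass", "color", "boundary_neg", "mass_neg", "color_neg")


class DegenerateHalfError(ValueError):
    pass


@dataclass(frozen=True)
class SplittingLine:
    """A line through ``center`` at ``angle`` radians in [0, pi).

    Tangent (row, col) = (sin a, cos a); normal = (cos a, -sin a).  The
    sign of the projection onto the normal defines the two sides.
    """

    angle: float
    center: tuple

    def __post_init__(self):
        if not (0.0 <= self.angle < math.pi):
            raise ValueError("angle must lie in [0, pi)")

    @property
    def tangent(self):
        return np.array([math.sin(self.angle), math.cos(self.angle)])

    @property
    def normal(self):
        return np.array([math.cos(self.angle), -math.sin(self.angle)])


def _path_graph(ts, values):
    tlist = [int(t) for t in ts]
    present = set(tlist)
    edges = {(t, t + 1) for t in tlist if t + 1 in present}
    return SizeGraph(
        vertices=tlist,
        edges=edges,
        phi={t: float(v) for t, v in zip(tlist, values)},
    )


def boundary_mf(seg: LesionSegmentation, line: SplittingLine, side: int) -> SizeGraph:
    """Distance-to-line measuring function on one boundary half."""
    pts = seg.boundary
    s = (pts - np.asarray(line.center)) @ line.normal
    keep = s > 0 if side > 0 else s < 0
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        raise DegenerateHalfError("degenerate half")
    n = len(pts)
    kept = set(idx.tolist())
    edges = {(int(i), int((i + 1) % n)) for i in idx if int((i + 1) % n) in kept}
    return SizeGraph(
        vertices=[int(i) for i in idx],
        edges=edges,
        phi={int(i): float(abs(s[i])) for i in idx},
    )


def _ray_grid(seg: LesionSegmentation, line: SplittingLine, side: int):
    """Sample grid: rows = integer arc positions t along the line, cols =
    unit steps s outward along the normal into the given side."""
    pts = seg.boundary
    c = np.asarray(line.center)
    tproj = (pts - c) @ line.tangent
    nproj = (pts - c) @ line.normal
    t0, t1 = int(math.ceil(tproj.min())), int(math.floor(tproj.max()))
    if t1 < t0:
        raise DegenerateHalfError("degenerate half")
    smax = int(math.ceil(np.abs(nproj).max())) + 2
    ts = np.arange(t0, t1 + 1)
    ss = np.arange(0, smax + 1)
    base = c[None, None, :] + ts[:, None, None] * line.tangent[None, None, :]
    grid = base + (side * ss)[None, :, None] * line.normal[None, None, :]
    return ts, grid  # grid shape (T, S, 2)


def _inside(seg, grid):
    coords = np.stack([grid[..., 0].ravel(), grid[..., 1].ravel()])
    vals = ndi.map_coordinates(
        seg.mask.astype(np.float64), coords, order=1, mode="constant", cval=0.0
    )
    return (vals >= 0.5).reshape(grid.shape[:2])


def _interp(field, grid):
    coords = np.stack([grid[..., 0].ravel(), grid[..., 1].ravel()])
    vals = ndi.map_coordinates(field, coords, order=1, mode="nearest")
    return vals.reshape(grid.shape[:2])


def mass_mf(
    gray: np.ndarray, seg: LesionSegmentation, line: SplittingLine, side: int
) -> SizeGraph:
    """Summed grey levels along orthogonal segments into one half."""
    ts, grid = _ray_grid(seg, line, side)
    inside = _inside(seg, grid)
    vals = _interp(np.asarray(gray, dtype=np.float64), grid)
    phi = np.where(inside, vals, 0.0).sum(axis=1)
    occupied = inside.any(axis=1)
    if not occupied.any():
        raise DegenerateHalfError("degenerate half")
    return _path_graph(ts[occupied], phi[occupied])


def color_mf(
    img: np.ndarray, seg: LesionSegmentation, line: SplittingLine, side: int
) -> SizeGraph:
    """Summed RGB distances of consecutive samples along orthogonal segments."""
    ts, grid = _ray_grid(seg, line, side)
    inside = _inside(seg, grid)
    chans = np.stack(
        [_interp(img[..., c].astype(np.float64), grid) for c in range(3)], axis=-1
    )
    step = np.linalg.norm(np.diff(chans, axis=1), axis=-1)  # (T, S-1)
    pair_inside = inside[:, :-1] & inside[:, 1:]
    phi = np.where(pair_inside, step, 0.0).sum(axis=1)
    occupied = inside.any(axis=1)
    if not occupied.any():
        raise DegenerateHalfError("degenerate half")
    return _path_graph(ts[occupied], phi[occupied])


def negate_mf(g: SizeGraph) -> SizeGraph:
    """Same graph, phi -> -phi (superlevel-set reading of the same data)."""
    return SizeGraph(
        vertices=list(g.vertices),
        edges=set(g.edges),
        phi={v: -p for v, p in g.phi.items()},
    )


def joint_normalize(gplus: SizeGraph, gminus: SizeGraph):
    """Divide phi on both halves by their joint max |phi| (no-op if zero)."""
    s = max(
        max((abs(p) for p in gplus.phi.values()), default=0.0),
        max((abs(p) for p in gminus.phi.values()), default=0.0),
    )
    if s == 0:
        return gplus, gminus

    def scaled(g):
        return SizeGraph(
            vertices=list(g.vertices),
            edges=set(g.edges),
            phi={v: p / s for v, p in g.phi.items()},
        )

    return scaled(gplus), scaled(gminus)


def half_graphs(
    img: np.ndarray,
    gray: np.ndarray,
    seg: LesionSegmentation,
    line: SplittingLine,
    mf_id: str,
):
    """Jointly normalized (plus-side, minus-side) graphs for one measuring
    function on one splitting line.  Raises DegenerateHalfError if either
    half is empty."""
    base = mf_id[:-4] if mf_id.endswith("_neg") else mf_id
    if base == "boundary":
        gp = boundary_mf(seg, line, +1)
        gm = boundary_mf(seg, line, -1)
    elif base == "mass":
        gp = mass_mf(gray, seg, line, +1)
        gm = mass_mf(gray, seg, line, -1)
    elif base == "color":
        gp = color_mf(img, seg, line, +1)
        gm = color_mf(img, seg, line, -1)
    else:
        raise ValueError(f"unknown measuring function {mf_id!r}")
    if mf_id.endswith("_neg"):
        gp, gm = negate_mf(gp), negate_mf(gm)
    return joint_normalize(gp, gm)


def dump_half(g: SizeGraph, path_prefix) -> None:
    """Debug dump: the half's size-function diagram as JSON and its
    vertex values as CSV (``<prefix>.json`` / ``<prefix>.csv``)."""
    from pathlib import Path

    from .sfcore import compute_size_function, diagram_to_json

    prefix = Path(path_prefix)
    prefix.with_suffix(".json").write_text(
        diagram_to_json(compute_size_function(g))
    )
    lines = ["vertex,phi"] + [f"{v},{g.phi[v]!r}" for v in g.vertices]
    prefix.with_suffix(".csv").write_text("\n".join(lines) + "\n")
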