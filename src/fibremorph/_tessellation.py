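"""Seeded-point tessellation primitives for the tissue simulator.

Poisson-disc sampling (Bridson's algorithm) gives blue-noise seed points;
a mirrored Voronoi construction yields cells clipped to the image
rectangle; Lloyd relaxation regularises the cells towards the isotropic,
packed-polygon look of real muscle cross-sections.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

# Empirical Bridson point density is ~0.68/r^2, giving a mean cell area of
# ~1.47 r^2 and an equivalent cell diameter of ~1.37 r.
EQUIV_DIAMETER_PER_RADIUS = 1.37


def poisson_disc_sample(width: float, height: float, radius: float,
                        rng: np.random.Generator, k: int = 30) -> np.ndarray:
    """Bridson Poisson-disc sampling of [0, width] x [0, height].

    Returns an (n, 2) array of points with pairwise distance >= radius.
    """
    cell = radius / np.sqrt(2.0)
    gw, gh = int(np.ceil(width / cell)), int(np.ceil(height / cell))
    grid = -np.ones((gw, gh), dtype=np.int64)
    points: list[np.ndarray] = []
    active: list[int] = []

    def grid_idx(p: np.ndarray) -> tuple[int, int]:
        return int(p[0] / cell), int(p[1] / cell)

    def fits(p: np.ndarray) -> bool:
        gx, gy = grid_idx(p)
        x0, x1 = max(gx - 2, 0), min(gx + 3, gw)
        y0, y1 = max(gy - 2, 0), min(gy + 3, gh)
        for i in grid[x0:x1, y0:y1].ravel():
            if i >= 0 and np.hypot(*(points[i] - p)) < radius:
                return False
        return True

    p0 = rng.uniform([0, 0], [width, height])
    points.append(p0)
    grid[grid_idx(p0)] = 0
    active.append(0)

    while active:
        idx = int(rng.integers(len(active)))
        base = points[active[idx]]
        for _ in range(k):
            r = radius * (1 + rng.uniform())
            theta = rng.uniform(0, 2 * np.pi)
            cand = base + r * np.array([np.cos(theta), np.sin(theta)])
            if 0 <= cand[0] < width and 0 <= cand[1] < height and fits(cand):
                points.append(cand)
                grid[grid_idx(cand)] = len(points) - 1
                active.append(len(points) - 1)
                break
        else:
            active.pop(idx)

    return np.array(points)


def bounded_voronoi(points: np.ndarray, width: float, height: float) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to [0, width] x [0, height].

    Cells are bounded by mirroring every point across the four rectangle
    edges, so each interior cell is finite; the result is clipped to the
    rectangle for numerical safety.  Returns one polygon per input point,
    in input order.
    """
    mirrors = [
        points * [-1, 1],                         # across x = 0
        points * [-1, 1] + [2 * width, 0],        # across x = width
        points * [1, -1],                         # across y = 0
        points * [1, -1] + [0, 2 * height],       # across y = height
    ]
    augmented = np.vstack([points] + mirrors)
    vor = Voronoi(augmented)
    frame = box(0.0, 0.0, width, height)

    cells: list[Polygon] = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        poly = Polygon(verts)
        if not poly.is_valid:
            poly = poly.buffer(0)
        clipped = poly.intersection(frame)
        if clipped.geom_type != "Polygon":
            # keep the largest piece of a degenerate multi-part clip
            parts = [g for g in getattr(clipped, "geoms", []) if g.geom_type == "Polygon"]
            clipped = max(parts, key=lambda g: g.area) if parts else Polygon()
        cells.append(clipped)
    return cells


def lloyd_relax(points: np.ndarray, width: float, height: float,
                iterations: int = 2) -> tuple[np.ndarray, list[Polygon]]:
    """Apply Lloyd relaxation: move each point to its cell centroid.

    Returns the relaxed points and their final Voronoi cells.
    """
    pts = np.asarray(points, dtype=float)
    cells = bounded_voronoi(pts, width, height)
    for _ in range(iterations):
        pts = np.array([
            (cell.centroid.x, cell.centroid.y) if not cell.is_empty else p
            for p, cell in zip(pts, cells)
        ])
        cells = bounded_voronoi(pts, width, height)
    return pts, cells
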