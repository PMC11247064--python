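"""Hexagonal-grid cross-section geometry.

A vessel cross-section lives on a pointy-top hexagonal lattice (row pitch
sqrt(3)/2 * spacing, odd rows shifted half a site).  Each site carries one
tissue label; the lumen boundary is extracted as the exact outline of the
union of lumen hexagon cells, which makes contour areas consistent with site
counts down to a single-site lumen.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "EXTERIOR", "LUMEN", "MEDIA", "ADVENTITIA", "PLAQUE", "VOID",
    "LABEL_NAMES", "HexGrid", "build_hex_grid", "CrossSection", "Contour",
    "lumen_contour", "polygon_area", "hydraulic_diameter",
    "distance_to_lumen", "smooth_contour", "map_nodes_to_plane",
    "connected_components",
]

# site labels
EXTERIOR, LUMEN, MEDIA, ADVENTITIA, PLAQUE, VOID = range(6)
LABEL_NAMES = {EXTERIOR: "exterior", LUMEN: "lumen", MEDIA: "media",
               ADVENTITIA: "adventitia", PLAQUE: "plaque", VOID: "void"}
TISSUE_LABELS = (MEDIA, ADVENTITIA, PLAQUE)

_SQRT3_2 = np.sqrt(3.0) / 2.0
#: neighbor directions in CCW angular order: E, NE, NW, W, SW, SE
_ANGLES = np.deg2rad(60.0 * np.arange(6))


class HexGrid:
    """Pointy-top hexagonal lattice with 6-neighbor adjacency.

    Sites are indexed row-major; ``centers`` holds mm coordinates and
    ``neighbors`` a (N, 6) table in CCW order (E, NE, NW, W, SW, SE) with -1
    where a neighbor falls outside the grid.
    """

    def __init__(self, n_rows: int, n_cols: int, spacing: float):
        if n_rows < 1 or n_cols < 1 or spacing <= 0:
            raise ValueError("grid dimensions and spacing must be positive")
        self.n_rows, self.n_cols, self.spacing = n_rows, n_cols, float(spacing)
        rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
        x = (cols + 0.5 * (rows % 2)) * spacing
        y = rows * _SQRT3_2 * spacing
        self.centers = np.column_stack([x, y])
        self.neighbors = self._build_neighbors(rows, cols)

    def _build_neighbors(self, rows, cols) -> np.ndarray:
        n_rows, n_cols = self.n_rows, self.n_cols
        odd = rows % 2
        # (drow, dcol_even, dcol_odd) per direction at angle 60*d:
        # E, NE, NW, W, SW, SE (y grows with the row index)
        offs = [(0, 1, 1), (1, 0, 1), (1, -1, 0),
                (0, -1, -1), (-1, -1, 0), (-1, 0, 1)]
        out = np.full((rows.size, 6), -1, dtype=np.int64)
        for d, (dr, dce, dco) in enumerate(offs):
            nr = rows + dr
            nc = cols + np.where(odd == 0, dce, dco)
            ok = (nr >= 0) & (nr < n_rows) & (nc >= 0) & (nc < n_cols)
            out[ok, d] = nr[ok] * n_cols + nc[ok]
        return out

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def site_area(self) -> float:
        """Area of one hexagonal cell [mm^2] (flat-to-flat = spacing)."""
        return _SQRT3_2 * self.spacing ** 2

    def site_index(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol(self, idx):
        return np.divmod(np.asarray(idx), self.n_cols)

    def nearest_site(self, xy) -> np.ndarray:
        """Rasterize mm coordinates to nearest site indices (vectorized)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        row = np.rint(xy[:, 1] / (_SQRT3_2 * self.spacing)).astype(np.int64)
        row = np.clip(row, 0, self.n_rows - 1)
        col = np.rint(xy[:, 0] / self.spacing - 0.5 * (row % 2)).astype(np.int64)
        col = np.clip(col, 0, self.n_cols - 1)
        return row * self.n_cols + col


def build_hex_grid(n_rows: int = 300, n_cols: int = 300,
                   spacing: float = 0.0375) -> HexGrid:
    """Standard simulation lattice: 300 x 300 sites at 0.0375 mm/site."""
    return HexGrid(n_rows, n_cols, spacing)


@dataclass
class CrossSection:
    """Tissue-labelled cross-section on a hex grid for one axial plane."""

    grid: HexGrid
    labels: np.ndarray                       # (n_sites,) int codes
    plane_id: int = 0
    axial_pos: float = 0.0                   # mm along the vessel
    damage: Optional[np.ndarray] = None      # per-site damage in [0, 1]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (self.grid.n_sites,):
            raise ValueError("labels must have one entry per site")

    def copy(self) -> "CrossSection":
        return CrossSection(self.grid, self.labels.copy(), self.plane_id,
                            self.axial_pos,
                            None if self.damage is None else self.damage.copy())

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def lumen_area(self) -> float:
        """Lumen area from the site count [mm^2] (void recesses excluded)."""
        return self.count(LUMEN) * self.grid.site_area


def connected_components(grid: HexGrid, mask: np.ndarray) -> list[np.ndarray]:
    """Connected components (6-neighbor) of a boolean site mask, largest
    first."""
    mask = np.asarray(mask, bool)
    seen = np.zeros(grid.n_sites, bool)
    comps = []
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        stack = [int(start)]
        seen[start] = True
        comp = []
        while stack:
            s = stack.pop()
            comp.append(s)
            for nb in grid.neighbors[s]:
                if nb >= 0 and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(int(nb))
        comps.append(np.asarray(comp))
    comps.sort(key=len, reverse=True)
    return comps


@dataclass
class Contour:
    """Closed simple polyline [mm], counter-clockwise."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("contour needs >= 3 2D points")
        self.points = pts

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _hex_vertices(center: np.ndarray, spacing: float) -> np.ndarray:
    """Six cell-corner points, CCW, first at angle 30 deg."""
    R = spacing / np.sqrt(3.0)
    ang = np.deg2rad(30.0 + 60.0 * np.arange(6))
    return center + R * np.column_stack([np.cos(ang), np.sin(ang)])


def region_contour(cs: CrossSection, mask: np.ndarray) -> Contour:
    """Outline of the union of the masked sites' hexagon cells.

    Returns the largest closed loop (the outer boundary of the main
    component), CCW.  Vertex spacing equals the hexagon edge length
    spacing/sqrt(3) < spacing.
    """
    mask = np.asarray(mask, bool)
    sites = np.flatnonzero(mask)
    if sites.size == 0:
        raise ValueError("empty region has no contour")
    comps = connected_components(cs.grid, mask)
    main = np.zeros(cs.grid.n_sites, bool)
    main[comps[0]] = True
    spacing = cs.grid.spacing
    from collections import defaultdict
    edges: dict[tuple, list] = defaultdict(list)

    # hexagon corners live on an exact half-integer / sqrt(3)/6 lattice, so
    # keying on the rounded lattice indices is collision-free
    def key(p):
        return (round(p[0] / (spacing * 0.5)),
                round(p[1] / (spacing * np.sqrt(3.0) / 6.0)))

    edge_list = []       # (start_key, end_key, a, b)
    for s in np.flatnonzero(main):
        nbrs = cs.grid.neighbors[s]
        boundary_dirs = [d for d in range(6)
                         if nbrs[d] < 0 or not main[nbrs[d]]]
        if not boundary_dirs:
            continue
        verts = _hex_vertices(cs.grid.centers[s], spacing)
        for d in boundary_dirs:
            # shared edge of direction d spans corners d-1 and d (CCW,
            # region on the left)
            a, b = verts[d - 1], verts[d]
            edges[key(a)].append(len(edge_list))
            edge_list.append((key(a), key(b), a, b))
    # successor of each directed edge: among edges leaving its head, the one
    # turning most sharply left (hugs the region at pinch vertices)
    succ = np.full(len(edge_list), -1, dtype=int)
    for i, (_, kb, a, b) in enumerate(edge_list):
        cands = edges.get(kb, [])
        if len(cands) == 1:
            succ[i] = cands[0]
            continue
        v = b - a
        best, best_turn = -1, -np.inf
        for j in cands:
            aa, bb = edge_list[j][2], edge_list[j][3]
            u = bb - aa
            turn = np.arctan2(v[0] * u[1] - v[1] * u[0], v @ u)
            if turn > best_turn:
                best, best_turn = j, turn
        succ[i] = best
    # orbits of the successor map are the boundary loops
    loops = []
    seen = np.zeros(len(edge_list), bool)
    for i0 in range(len(edge_list)):
        if seen[i0]:
            continue
        pts = []
        i = i0
        while not seen[i]:
            seen[i] = True
            pts.append(edge_list[i][3])
            i = succ[i]
            if i < 0:
                break
        if len(pts) >= 3:
            loops.append(Contour(np.asarray(pts)))
    if not loops:
        raise ValueError("degenerate region boundary")
    return max(loops, key=lambda c: c.signed_area())


def lumen_contour(cs: CrossSection, include_void: bool = False) -> Contour:
    """Boundary polyline between lumen and tissue, CCW.

    With ``include_void`` the laceration recesses (void sites) connected to
    the lumen are part of the flow domain, as after element deletion.
    """
    mask = cs.labels == LUMEN
    if include_void:
        mask |= cs.labels == VOID
    if not mask.any():
        raise ValueError(f"plane {cs.plane_id}: no lumen sites")
    return region_contour(cs, mask)


def polygon_area(contour: Contour) -> float:
    """Shoelace area [mm^2] (magnitude; CCW input gives it directly).

    Rings that merely touch themselves at isolated points (pinch vertices
    from rasterized outlines) are accepted; genuinely self-crossing input
    raises.
    """
    area = contour.signed_area()
    import shapely.geometry as sg
    poly = sg.Polygon(contour.points)
    if not poly.is_valid:
        fixed = poly.buffer(0)
        # a crossing folds part of the ring back, so the shoelace magnitude
        # disagrees with the point-set area; a pinch leaves them equal
        if fixed.area <= 0 or abs(fixed.area - abs(area)) > 1e-6 * max(
                fixed.area, 1e-12):
            raise ValueError("self-intersecting contour")
    return abs(area)


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """4 A / P [mm]; equals the diameter for a circle."""
    if perimeter <= 0:
        raise ValueError("perimeter must be > 0")
    return 4.0 * area / perimeter


def wall_sites(cs: CrossSection, flow_mask: np.ndarray | None = None) -> np.ndarray:
    """Tissue sites adjacent to the flow domain (lumen wall)."""
    if flow_mask is None:
        flow_mask = (cs.labels == LUMEN) | (cs.labels == VOID)
    tissue = np.isin(cs.labels, TISSUE_LABELS)
    nbrs = cs.grid.neighbors
    touches = np.zeros(cs.grid.n_sites, bool)
    for d in range(6):
        nb = nbrs[:, d]
        ok = nb >= 0
        touches[ok] |= flow_mask[nb[ok]]
    return np.flatnonzero(tissue & touches)


def distance_to_lumen(cs: CrossSection,
                      flow_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-site Euclidean distance [mm] to the nearest lumen-wall site center.

    Wall sites map to 0; non-tissue sites (lumen, void, exterior) carry +inf
    and are excluded from the stimuli.
    """
    out = np.full(cs.grid.n_sites, np.inf)
    walls = wall_sites(cs, flow_mask)
    if walls.size == 0:
        return out
    tissue = np.flatnonzero(np.isin(cs.labels, TISSUE_LABELS))
    tree = cKDTree(cs.grid.centers[walls])
    d, _ = tree.query(cs.grid.centers[tissue])
    out[tissue] = d
    out[walls] = 0.0
    return out


def smooth_contour(contour: Contour, window: int = 5,
                   max_area_change: float = 0.02) -> Contour:
    """Circular moving average of vertex radii about the contour centroid.

    ``window`` must be odd; ``window=1`` is the identity.  If a full
    application would change the enclosed area by more than
    ``max_area_change``, the smoothing is blended back toward the input until
    the guard holds.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return contour
    c = contour.centroid
    rel = contour.points - c
    r = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    kernel = np.ones(window) / window
    n = len(r)
    r_pad = np.concatenate([r[-(window // 2):], r, r[: window // 2]])
    r_s = np.convolve(r_pad, kernel, mode="valid")[:n]

    base_area = abs(contour.signed_area())

    def build(t):
        rr = (1 - t) * r + t * r_s
        return Contour(c + np.column_stack([rr * np.cos(theta),
                                            rr * np.sin(theta)]))

    t = 1.0
    out = build(t)
    if base_area > 0:
        for _ in range(20):
            if abs(abs(out.signed_area()) - base_area) / base_area <= max_area_change:
                break
            t *= 0.5
            out = build(t)
    return out


def map_nodes_to_plane(nodes3d: np.ndarray, labels: np.ndarray,
                       damage: np.ndarray, origin, normal, grid: HexGrid,
                       slab_half_width: float = 1.0,
                       plane_id: int = 0) -> CrossSection:
    """Project labelled 3D nodes onto a plane and rasterize to the hex grid.

    Nodes within ``slab_half_width`` of the plane are rotated into plane
    coordinates (origin mapped to the grid center), scaled by 1/spacing and
    assigned to the nearest site.  Per-site damage is the maximum of the
    contributing nodes (a partially failed site behaves as failed); the label
    is taken from the maximum-damage node.
    """
    nodes3d = np.asarray(nodes3d, float)
    labels = np.asarray(labels)
    damage = np.asarray(damage, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    rel = nodes3d - np.asarray(origin, float)
    dist = rel @ normal
    keep = np.abs(dist) <= slab_half_width
    if not keep.any():
        raise ValueError(f"plane {plane_id}: no nodes within the slab")
    # in-plane orthonormal basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    center = grid.centers.mean(axis=0)
    xy = np.column_stack([rel[keep] @ u, rel[keep] @ v]) + center
    sites = grid.nearest_site(xy)

    out_labels = np.full(grid.n_sites, EXTERIOR, dtype=np.int8)
    out_damage = np.zeros(grid.n_sites)
    best = np.full(grid.n_sites, -1.0)
    for s, lab, dmg in zip(sites, labels[keep], damage[keep]):
        if dmg > best[s]:
            best[s] = dmg
            out_labels[s] = lab
        out_damage[s] = max(out_damage[s], dmg)
    return CrossSection(grid, out_labels, plane_id=plane_id, damage=out_damage)
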