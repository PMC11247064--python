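"""Multi-plane orchestration.

Runs the replicate-per-plane remodeling simulations, selects the
representative replicate at each coupling boundary (minimum contour RMSD
from the replicate average), restarts replicates from the selected state,
and reconstructs the follow-up lumen surface by lofting the per-plane
contours.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .abm import PlaneRunResult, PlaneState, run_plane
from .geometry import Contour, CrossSection
from .params import SimulationConfig

__all__ = ["select_replicate", "contour_radii", "RemodelingResult",
           "run_framework", "loft_surface", "replicate_seed"]


def contour_radii(contour: Contour, center: np.ndarray,
                  n_angles: int = 360) -> np.ndarray:
    """Radius profile of a contour sampled at equal angles about ``center``.

    Vertex (angle, radius) pairs are sorted and interpolated periodically;
    adequate for the star-shaped lumen outlines produced by the simulation.
    """
    rel = contour.points - np.asarray(center, float)
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2.0 * np.pi)
    r = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(theta, kind="stable")
    theta, r = theta[order], r[order]
    grid = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    return np.interp(grid, theta, r, period=2.0 * np.pi)


def select_replicate(contours: Sequence[Contour],
                     n_angles: int = 360) -> int:
    """Index of the replicate whose lumen contour minimizes the RMSD of
    radii from the replicate-average contour (ties -> lowest index).

    Radii are sampled at ``n_angles`` equal angles about the shared centroid
    of the replicate average.
    """
    contours = [c for c in contours if c is not None]
    if len(contours) < 2:
        return 0
    center = np.mean([c.centroid for c in contours], axis=0)
    radii = np.stack([contour_radii(c, center, n_angles) for c in contours])
    avg = radii.mean(axis=0)
    rmsd = np.sqrt(np.mean((radii - avg) ** 2, axis=1))
    # ties (to float noise) resolve to the lowest index
    return int(np.argmin(np.round(rmsd, 12)))


def replicate_seed(seed: int, plane: int, replicate: int) -> int:
    """Deterministic per-(plane, replicate) child seed below 2^31."""
    ss = np.random.SeedSequence([int(seed) % (2 ** 31), plane, replicate])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RemodelingResult:
    """Outcome of the coupled multi-plane simulation.

    ``area`` carries the representative (selected-replicate) flow-domain
    contour area per plane per day; ``selected`` the chosen replicate index
    per plane per coupling cycle; ``checkpoint_contours`` the smoothed lumen
    contours at day 0 and each coupling boundary, keyed by (plane, day).
    """

    days: np.ndarray
    area: np.ndarray                       # (n_planes, n_days+1) mm^2
    lumen_area: np.ndarray                 # site-count based, same shape
    selected: np.ndarray                   # (n_planes, n_cycles) int
    checkpoint_contours: dict = field(default_factory=dict)
    axial_positions: np.ndarray = None
    final_states: list = field(default_factory=list)
    compositions: list = field(default_factory=list)

    def surface(self, day: int):
        """Lofted lumen surface at a checkpoint day (trimesh.Trimesh)."""
        planes = sorted({p for (p, d) in self.checkpoint_contours if d == day})
        contours = [self.checkpoint_contours[(p, day)] for p in planes]
        return loft_surface(contours, self.axial_positions[planes])


def run_framework(sections: Sequence[CrossSection],
                  damage_fields: Sequence[np.ndarray],
                  wss_source=None,
                  config: SimulationConfig | None = None,
                  seed: int = 0,
                  deleted_plaque_masks: Optional[Sequence[np.ndarray]] = None,
                  ) -> RemodelingResult:
    """Coupled hemodynamics-remodeling loop over all planes.

    For each coupling cycle: run ``config.n_replicates`` simulations per
    plane, pick the representative by contour RMSD, restart every replicate
    from the selected state, and re-derive WSS from the remodeled geometry
    (handled inside :func:`~restenosim.abm.run_plane` at cycle boundaries).
    ``wss_source`` may be None (surrogate), a per-plane list of
    :class:`WSSField` for the first cycle, or a callable.
    """
    config = config or SimulationConfig()
    n_planes = len(sections)
    if len(damage_fields) != n_planes:
        raise ValueError("one damage field per plane required")
    horizon = int(round(config.horizon_days))
    coupling = int(round(config.coupling_days))
    n_cycles = max(1, -(-horizon // coupling))
    n_reps = config.n_replicates

    days = np.arange(horizon + 1, dtype=float)
    area = np.zeros((n_planes, horizon + 1))
    lumen_area = np.zeros((n_planes, horizon + 1))
    selected = np.zeros((n_planes, n_cycles), dtype=int)
    ckpt: dict = {}
    final_states: list = [None] * n_planes
    compositions: list = [None] * n_planes

    for plane_idx, (cs, dmg) in enumerate(zip(sections, damage_fields)):
        plane_wss = wss_source
        if isinstance(wss_source, (list, tuple)):
            plane_wss = wss_source[plane_idx]
        dpm = (None if deleted_plaque_masks is None
               else deleted_plaque_masks[plane_idx])
        states: list[Optional[PlaneState]] = [None] * n_reps
        comp_rows = []
        try:
            for cycle in range(n_cycles):
                start = cycle * coupling
                dur = min(coupling, horizon - start)
                results: list[PlaneRunResult] = []
                for rep in range(n_reps):
                    res = run_plane(
                        cs, dmg, wss_source=plane_wss, config=config,
                        seed=replicate_seed(seed, plane_idx, rep),
                        duration_days=dur, coupling_days=coupling,
                        deleted_plaque_mask=dpm,
                        initial_state=(None if states[rep] is None
                                       else states[rep].copy()),
                        start_day=start)
                    results.append(res)
                sel = select_replicate([r.contours[-1] for r in results])
                selected[plane_idx, cycle] = sel
                best = results[sel]
                sl = slice(start, start + dur + 1)
                area[plane_idx, sl] = best.contour_area
                lumen_area[plane_idx, sl] = best.lumen_area
                comp_rows.append(best.composition if cycle == 0
                                 else best.composition.iloc[1:])
                if cycle == 0 and best.contours[0] is not None:
                    ckpt[(plane_idx, 0)] = best.contours[0]
                if best.contours[-1] is not None:
                    ckpt[(plane_idx, start + dur)] = best.contours[-1]
                states = [best.state for _ in range(n_reps)]
            final_states[plane_idx] = states[0]
            import pandas as pd
            compositions[plane_idx] = pd.concat(comp_rows, ignore_index=True)
        except Exception as exc:
            raise RuntimeError(f"plane {cs.plane_id} failed: {exc}") from exc

    return RemodelingResult(
        days=days, area=area, lumen_area=lumen_area, selected=selected,
        checkpoint_contours=ckpt,
        axial_positions=np.asarray([cs.axial_pos for cs in sections]),
        final_states=final_states, compositions=compositions)


def resample_contour(contour: Contour, n_vertices: int = 200) -> np.ndarray:
    """Resample to ``n_vertices`` points at equal angles about the centroid,
    start vertex at angle 0 (loft alignment)."""
    c = contour.centroid
    r = contour_radii(contour, c, n_vertices)
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return c + np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def loft_surface(contours: Sequence[Contour], axial_positions,
                 n_vertices: int = 200):
    """Ruled triangle surface between stacked planar contours.

    Contours are resampled to a common vertex count with aligned start
    vertices; consecutive rings are joined by quads split into triangles.
    Returns a ``trimesh.Trimesh`` (open cylinder topology: V - E + F = 0).
    """
    import trimesh

    if len(contours) < 2:
        raise ValueError("lofting needs at least two planes")
    axial_positions = np.asarray(axial_positions, float)
    if len(axial_positions) != len(contours):
        raise ValueError("one axial position per contour required")
    rings = [resample_contour(c, n_vertices) for c in contours]
    verts = np.concatenate([
        np.column_stack([ring, np.full(n_vertices, z)])
        for ring, z in zip(rings, axial_positions)])
    faces = []
    for k in range(len(contours) - 1):
        base0, base1 = k * n_vertices, (k + 1) * n_vertices
        for j in range(n_vertices):
            j2 = (j + 1) % n_vertices
            faces.append([base0 + j, base0 + j2, base1 + j])
            faces.append([base0 + j2, base1 + j2, base1 + j])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                           process=False)
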