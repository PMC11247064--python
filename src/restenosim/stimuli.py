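"""Driving inputs of the remodeling simulation.

Two fields push the agent event probabilities above baseline: Dinput, the
balloon-injury damage weighted by a transient post-intervention inflammation
curve, and WSSinput, a sigmoid transform of lumen wall shear stress (low WSS
-> high endothelial dysfunction) propagated a short distance into the media.
WSS itself comes either from an external CSV (e.g. CFD results sampled on
cross-sectional planes) or from a built-in Poiseuille-style surrogate that
concentrates low shear in lumen recesses.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import (Contour, CrossSection, LUMEN, MEDIA, VOID,
                       polygon_area, wall_sites, distance_to_lumen)
from .params import StimulusParams

__all__ = [
    "WSSField", "inflammation", "dinput", "wss_sigmoid",
    "propagate_wssinput", "wss_surrogate", "read_wss_csv",
    "poiseuille_wss",
]


@dataclass
class WSSField:
    """Wall shear stress magnitude [Pa] sampled on lumen-wall sites."""

    sites: np.ndarray    # site indices on the lumen wall
    wss: np.ndarray      # Pa, >= 0
    plane_id: int = 0

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.wss = np.asarray(self.wss, dtype=float)
        if self.sites.shape != self.wss.shape:
            raise ValueError("sites and wss must align")
        if np.any(self.wss < 0):
            raise ValueError("WSS must be >= 0")


def inflammation(t_days, params: StimulusParams = StimulusParams()) -> np.ndarray:
    """Normalized post-intervention inflammatory curve, peak value 1.

    Zero before ``delay``; sin^2 rise over one day to the peak at
    ``delay + 1``; raised-cosine decay reaching exactly 0 at
    ``inflammation_end`` and staying there.  Shape chosen to match the
    stated landmarks (peak around day 3, vanishing at one month); the
    simulation outcome depends on its time integral, not the exact form.
    """
    t = np.asarray(t_days, dtype=float)
    d0, d1 = params.delay, params.delay + 1.0
    dend = params.inflammation_end
    rise = np.sin(0.5 * np.pi * np.clip((t - d0) / (d1 - d0), 0.0, 1.0)) ** 2
    decay = 0.5 * (1.0 + np.cos(
        np.pi * np.clip((t - d1) / max(dend - d1, 1e-9), 0.0, 1.0)))
    out = np.where(t < d1, rise, decay)
    out = np.where((t < d0) | (t >= dend), 0.0, out)
    return out if out.ndim else float(out)


def dinput(damage: np.ndarray, t_days: float,
           params: StimulusParams = StimulusParams()) -> np.ndarray:
    """Inflammatory input: site damage x inflammation(t); bounded by damage."""
    damage = np.asarray(damage, dtype=float)
    return damage * inflammation(t_days, params)


def wss_sigmoid(wss, params: StimulusParams = StimulusParams()):
    """Endothelial dysfunction D(WSS) = 1 - 1/(1 + exp(L1 (WSS - L2))).

    Monotone decreasing for L1 < 0, with D(L2) = 0.5.
    """
    wss = np.asarray(wss, dtype=float)
    out = 1.0 - 1.0 / (1.0 + np.exp(params.L1 * (wss - params.L2)))
    return out if out.ndim else float(out)


def propagate_wssinput(dvals: np.ndarray, wall: np.ndarray,
                       cs: CrossSection,
                       params: StimulusParams = StimulusParams(),
                       dist_field: np.ndarray | None = None) -> np.ndarray:
    """Propagate wall D(WSS) values into the media band.

    Lumen-wall sites receive D(WSS) itself.  A deeper media site h within
    depth ``dist`` of the wall receives
    sum_i D(WSS)_i * Amp * (1 + cos(pi x_hi / dist)) over wall sites i within
    Euclidean radius ``dist``, clamped to [0, 2 Amp].  Adventitia and plaque
    receive 0.
    """
    out = np.zeros(cs.grid.n_sites)
    if wall.size == 0:
        return out
    if dist_field is None:
        dist_field = distance_to_lumen(cs)
    media = np.flatnonzero((cs.labels == MEDIA) & (dist_field < params.dist))
    interior = np.setdiff1d(media, wall, assume_unique=False)
    tree = cKDTree(cs.grid.centers[wall])
    if interior.size:
        pairs = tree.query_ball_point(cs.grid.centers[interior], params.dist)
        for j, idxs in enumerate(pairs):
            if not idxs:
                continue
            x = np.linalg.norm(cs.grid.centers[wall[idxs]]
                               - cs.grid.centers[interior[j]], axis=1)
            out[interior[j]] = np.sum(
                dvals[idxs] * params.Amp * (1.0 + np.cos(np.pi * x / params.dist)))
    wall_media = wall[cs.labels[wall] == MEDIA]
    pos = {s: k for k, s in enumerate(wall)}
    out[wall_media] = dvals[[pos[s] for s in wall_media]]
    return np.clip(out, 0.0, 2.0 * params.Amp)


def poiseuille_wss(area_mm2: float, flow_rate_ml_min: float = 100.0,
                   viscosity_pa_s: float = 0.0035) -> float:
    """Poiseuille WSS 4 mu Q / (pi R^3) [Pa] for the equivalent-area circle."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    q = flow_rate_ml_min * 1e-6 / 60.0          # m^3/s
    r_eq = np.sqrt(area_mm2 / np.pi) * 1e-3     # m
    return 4.0 * viscosity_pa_s * q / (np.pi * r_eq ** 3)


def wss_surrogate(contour: Contour, cs: CrossSection,
                  flow_rate_ml_min: float = 100.0,
                  viscosity_pa_s: float = 0.0035,
                  exponent: float = 3.0,
                  flow_mask: np.ndarray | None = None) -> WSSField:
    """Poiseuille-style WSS surrogate on the lumen wall.

    Every wall site receives tau_P(A) * (r_mean / r_local)^p where tau_P is
    the Poiseuille value for the equivalent-area circle, r_local the site's
    distance from the contour centroid and r_mean its wall average.  A circle
    recovers the exact Poiseuille value; recesses (r_local > r_mean, e.g.
    laceration pockets) receive low WSS with strength set by ``p``.
    """
    if flow_rate_ml_min <= 0:
        raise ValueError("flow rate must be positive")
    area = polygon_area(contour)
    tau = poiseuille_wss(area, flow_rate_ml_min, viscosity_pa_s)
    walls = wall_sites(cs, flow_mask)
    if walls.size == 0:
        raise ValueError("cross-section has no lumen wall")
    c = contour.centroid
    r_local = np.linalg.norm(cs.grid.centers[walls] - c, axis=1)
    r_local = np.maximum(r_local, 1e-9)
    r_mean = r_local.mean()
    return WSSField(walls, tau * (r_mean / r_local) ** exponent,
                    plane_id=cs.plane_id)


def uniform_wss_source(value_pa: float):
    """A ``wss_source`` callable assigning one WSS value to every wall site
    (e.g. a saturating value to probe homeostasis without shear stimulus)."""
    if value_pa < 0:
        raise ValueError("WSS must be >= 0")

    def source(cs: CrossSection, contour=None) -> WSSField:
        walls = wall_sites(cs)
        return WSSField(walls, np.full(walls.size, float(value_pa)),
                        plane_id=cs.plane_id)
    return source


def read_wss_csv(path, cs: CrossSection, plane_id: int | None = None,
                 flow_mask: np.ndarray | None = None) -> WSSField:
    """Map externally computed WSS samples onto the lumen-wall sites.

    Expects columns ``plane_id``, ``angle_or_arc_position`` (radians about
    the lumen centroid, or arc-length fraction in [0,1)) and ``wss_pa``.
    Each wall site takes the value of its nearest sample by angle.
    """
    df = pd.read_csv(path)
    required = {"plane_id", "angle_or_arc_position", "wss_pa"}
    if not required.issubset(df.columns):
        raise ValueError(f"WSS CSV must have columns {sorted(required)}")
    if plane_id is not None:
        df = df[df["plane_id"] == plane_id]
    if df.empty:
        raise ValueError("no WSS samples for the requested plane")
    if (df["wss_pa"] < 0).any():
        raise ValueError("negative WSS in input")
    pos = df["angle_or_arc_position"].to_numpy(float)
    # arc fractions in [0,1) are treated as turns; radians pass through
    if np.all((pos >= 0) & (pos < 1.0)) and pos.max() <= 1.0:
        ang_samples = pos * 2.0 * np.pi
    else:
        ang_samples = pos
    vals = df["wss_pa"].to_numpy(float)
    walls = wall_sites(cs, flow_mask)
    if walls.size == 0:
        raise ValueError("cross-section has no lumen wall")
    if flow_mask is None:
        flow_mask = (cs.labels == LUMEN) | (cs.labels == VOID)
    c = cs.grid.centers[flow_mask].mean(axis=0)
    rel = cs.grid.centers[walls] - c
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    # nearest sample on the circle
    diff = np.abs(ang[:, None] - ang_samples[None, :])
    diff = np.minimum(diff, 2.0 * np.pi - diff)
    nearest = np.argmin(diff, axis=1)
    return WSSField(walls, vals[nearest], plane_id=cs.plane_id)
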