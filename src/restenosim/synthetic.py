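"""Synthetic post-angioplasty vessel generator.

Builds the inputs the remodeling simulation needs without any patient data:
two-layer (media + adventitia) cross-sections with an eccentric plaque on a
hex grid, balloon-injury damage fields produced by driving the constitutive
library with a virtual circumferential overstretch, element-deletion
laceration masks, and matched wall-shear-stress fields with low WSS inside
the laceration recesses.

The virtual expansion applies a radially attenuated circumferential stretch
peaking at the lumen, amplified at the plaque shoulders where balloon
inflation concentrates strain; this reproduces the qualitative damage
localization of a finite-element balloon expansion (lumen-adjacent media
plus plaque shoulders) without solving one.  Deletion acts on the
neighborhood-minimum of the site damage — the analogue of element-wise
removal on a nodal damage field — so a high-damage rim survives around each
laceration and supplies the SMC migration candidates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import (element_deletion, evolve_damage,
                           plaque_damage_1d, uniaxial_stretch_state)
from .geometry import (ADVENTITIA, EXTERIOR, LUMEN, MEDIA, PLAQUE, VOID,
                       CrossSection, HexGrid, build_hex_grid)
from .params import MEDIA as MEDIA_PARAMS
from .params import PLAQUE as PLAQUE_PARAMS
from .params import LayerMaterialParams, PlaqueParams

__all__ = ["VesselSpec", "generate_vessel", "generate_damage",
           "generate_wss", "media_damage_from_stretch"]


@dataclass
class VesselSpec:
    """Geometry and virtual-expansion description of a synthetic vessel.

    Defaults emulate a diseased superficial femoral artery segment: 11
    cross-sections 2 mm apart, lumen radius tapering 1.65 -> 1.45 mm, a
    ~0.7 mm wall and an eccentric plaque bulging into the lumen over the
    central planes.  ``expansion_ratio`` is the balloon-to-lumen ratio of
    the virtual dilation; ``fe_char_length`` the regularization length of
    the emulated finite-element discretization [mm].
    """

    n_planes: int = 11
    plane_spacing: float = 2.0
    lumen_radius_in: float = 1.65
    lumen_radius_out: float = 1.45
    media_thickness: float = 0.35
    adventitia_thickness: float = 0.35
    plaque_angle_deg: float = 120.0
    plaque_center_deg: float = 0.0
    plaque_max_thickness: float = 0.6
    plaque_plane_start: int = 2
    plaque_plane_end: int = 8
    eccentricity: float = 0.1
    expansion_ratio: float = 1.6
    shoulder_concentration: float = 2.5
    shoulder_sigma_deg: float = 12.0
    radial_attenuation: float = 2.0
    noise_sd: float = 0.05
    fe_char_length: float = 0.3
    n_rows: int = 300
    n_cols: int = 300
    spacing: float = 0.0375
    seed: int = 0

    def __post_init__(self):
        for name in ("lumen_radius_in", "lumen_radius_out", "media_thickness",
                     "adventitia_thickness", "plane_spacing", "spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.expansion_ratio < 1.0:
            raise ValueError("expansion_ratio must be >= 1")
        span = min(self.n_cols, self.n_rows * np.sqrt(3) / 2) * self.spacing
        outer = 2 * (self.lumen_radius_in + self.media_thickness
                     + self.adventitia_thickness) + 2 * self.eccentricity
        if outer > span:
            raise ValueError("vessel exceeds the grid extent")

    @classmethod
    def scaled_down(cls, **overrides) -> "VesselSpec":
        """Reduced 150 x 150 grid variant with a slightly thinner wall so the
        vessel (plus remodeling margin) fits the smaller lattice; used for
        fast property checks."""
        kw = dict(n_rows=150, n_cols=150, media_thickness=0.30,
                  adventitia_thickness=0.25, eccentricity=0.05)
        kw.update(overrides)
        return cls(**kw)

    def lumen_radius(self, plane: int) -> float:
        f = plane / max(self.n_planes - 1, 1)
        return (1 - f) * self.lumen_radius_in + f * self.lumen_radius_out

    def plaque_thickness(self, plane: int, theta: np.ndarray) -> np.ndarray:
        """Plaque bulge thickness [mm] vs angle, zero outside its extent."""
        lo, hi = self.plaque_plane_start, self.plaque_plane_end
        if not lo <= plane <= hi or self.plaque_max_thickness <= 0:
            return np.zeros_like(theta)
        axial = np.sin(np.pi * (plane - lo) / max(hi - lo, 1)) ** 2 \
            if hi > lo else 1.0
        half = np.deg2rad(self.plaque_angle_deg) / 2.0
        dtheta = np.angle(np.exp(1j * (theta - np.deg2rad(self.plaque_center_deg))))
        prof = np.where(np.abs(dtheta) < half,
                        np.cos(np.pi * dtheta / (2 * half)) ** 2, 0.0)
        return self.plaque_max_thickness * axial * prof


def generate_vessel(spec: VesselSpec) -> list[CrossSection]:
    """Rasterize the vessel onto hex grids, one cross-section per plane."""
    grid = build_hex_grid(spec.n_rows, spec.n_cols, spec.spacing)
    out = []
    for plane in range(spec.n_planes):
        out.append(_build_plane(spec, grid, plane))
    return out


def _plane_centers(spec: VesselSpec, grid: HexGrid, plane: int):
    """(lumen center, polar coords about it) for one plane."""
    center = grid.centers.mean(axis=0)
    # lumen shifted away from the plaque side
    shift = -spec.eccentricity * np.array([
        np.cos(np.deg2rad(spec.plaque_center_deg)),
        np.sin(np.deg2rad(spec.plaque_center_deg))])
    lum_c = center + shift
    rel = grid.centers - lum_c
    r = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    return lum_c, r, theta


def _build_plane(spec: VesselSpec, grid: HexGrid, plane: int) -> CrossSection:
    _, r, theta = _plane_centers(spec, grid, plane)
    r_l = spec.lumen_radius(plane)
    t_p = spec.plaque_thickness(plane, theta)
    labels = np.full(grid.n_sites, EXTERIOR, dtype=np.int8)
    r_media_out = r_l + spec.media_thickness
    r_adv_out = r_media_out + spec.adventitia_thickness
    labels[r < r_adv_out] = ADVENTITIA
    labels[r < r_media_out] = MEDIA
    # plaque bulges inward from the media's inner boundary
    plaque = (r >= r_l - t_p) & (r < r_l + 0.25 * spec.media_thickness) \
        & (t_p > 0.01)
    labels[plaque] = PLAQUE
    lumen = (r < r_l) & ~plaque
    labels[lumen] = LUMEN
    return CrossSection(grid, labels, plane_id=plane,
                        axial_pos=plane * spec.plane_spacing)


def media_damage_from_stretch(lam: float,
                              params: LayerMaterialParams = MEDIA_PARAMS
                              ) -> float:
    """Scalar site damage of media tissue after a monotone circumferential
    stretch ramp to ``lam`` (incompressible: transverse stretches
    lam^(-1/2)).  Returns the maximum of the matrix and fiber damage
    variables."""
    if lam <= 1.0:
        return 0.0
    traj = evolve_damage([uniaxial_stretch_state(lam)], params)
    d = traj[-1]
    return max(d.d_m, d.d_fA1, d.d_fA2)


def _stretch_field(spec: VesselSpec, cs: CrossSection, plane: int,
                   expansion_ratio: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Virtual circumferential stretch per site for the balloon dilation."""
    _, r, theta = _plane_centers(spec, cs.grid, plane)
    r_l = spec.lumen_radius(plane)
    base = (expansion_ratio - 1.0) * np.clip(r_l / np.maximum(r, 1e-6), 0.0,
                                             2.0) ** spec.radial_attenuation
    # strain concentration at the two plaque shoulders
    half = np.deg2rad(spec.plaque_angle_deg) / 2.0
    sig = np.deg2rad(spec.shoulder_sigma_deg)
    c0 = np.deg2rad(spec.plaque_center_deg)
    t_p = spec.plaque_thickness(plane, theta)
    factor = np.ones_like(theta)
    if np.any(t_p > 0):
        for sh in (c0 - half, c0 + half):
            dth = np.angle(np.exp(1j * (theta - sh)))
            factor += spec.shoulder_concentration * np.exp(
                -0.5 * (dth / sig) ** 2)
    noise = np.exp(rng.normal(0.0, spec.noise_sd, cs.grid.n_sites))
    # damage saturates far below stretch 4; cap to keep the ramp physical
    return np.minimum(1.0 + base * factor * noise, 4.0)


def generate_damage(sections: list[CrossSection],
                    expansion_ratio: float | None = None,
                    spec: VesselSpec | None = None,
                    media_params: LayerMaterialParams = MEDIA_PARAMS,
                    plaque_params: PlaqueParams = PLAQUE_PARAMS,
                    deletion_threshold: float = 0.8,
                    seed: int | None = None,
                    ) -> tuple[list[np.ndarray], list[np.ndarray],
                               list[np.ndarray], list[CrossSection]]:
    """Virtual balloon expansion: damage fields, lacerations, opened sections.

    Per site, the virtual stretch drives the media damage law or the plaque
    ductile surrogate (adventitia damage is disabled).  Element-level damage
    (neighborhood-minimum) at or above ``deletion_threshold`` deletes sites,
    which become void; higher ``expansion_ratio`` deletes monotonically more
    sites under the same seed.

    Returns (damage_fields, laceration_masks, deleted_plaque_masks,
    post_deletion_sections).
    """
    spec = spec or VesselSpec()
    ratio = spec.expansion_ratio if expansion_ratio is None else expansion_ratio
    if ratio < 1.0:
        raise ValueError("expansion_ratio must be >= 1")
    seed = spec.seed if seed is None else seed
    damage_fields, masks, plaque_masks, opened = [], [], [], []
    for plane, cs in enumerate(sections):
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([int(seed) % (2 ** 31), plane])))
        lam = _stretch_field(spec, cs, plane, ratio, rng)
        damage = np.zeros(cs.grid.n_sites)
        media_sites = np.flatnonzero(cs.labels == MEDIA)
        # cache the smooth stretch->damage map on a fine grid: the media law
        # is deterministic and monotone in the stretch
        lam_grid = np.linspace(1.0, max(lam.max(), 1.001), 512)
        d_grid = np.array([media_damage_from_stretch(l, media_params)
                           for l in lam_grid])
        damage[media_sites] = np.interp(lam[media_sites], lam_grid, d_grid)
        for s in np.flatnonzero(cs.labels == PLAQUE):
            damage[s] = plaque_damage_1d([1.0, lam[s]], plaque_params,
                                         char_length=spec.fe_char_length)
        # element-wise deletion on the neighborhood-minimum over tissue
        # neighbors (nodal -> element); non-tissue neighbors do not count,
        # so a fully damaged wall site opens the recess to the lumen
        deletable = np.isin(cs.labels, (MEDIA, PLAQUE))
        nodal = np.where(deletable, damage, np.inf)
        elem = damage.copy()
        for d in range(6):
            nb = cs.grid.neighbors[:, d]
            ok = nb >= 0
            elem[ok] = np.minimum(elem[ok], nodal[nb[ok]])
        elem = np.where(np.isfinite(elem), elem, damage)
        elem = np.clip(elem, 0.0, 1.0)
        mask = element_deletion(elem, deletion_threshold) & deletable
        plaque_mask = mask & (cs.labels == PLAQUE)
        cs2 = cs.copy()
        cs2.labels[mask] = VOID
        cs2.damage = damage
        damage_fields.append(damage)
        masks.append(mask)
        plaque_masks.append(plaque_mask)
        opened.append(cs2)
    return damage_fields, masks, plaque_masks, opened


def generate_wss(sections: list[CrossSection],
                 laceration_masks: list[np.ndarray],
                 flow_rate_ml_min: float = 100.0,
                 viscosity_pa_s: float = 0.0035,
                 laceration_wss_max: float = 0.95):
    """Surrogate WSS on the post-deletion lumen, low inside lacerations.

    Applies the Poiseuille-style surrogate to the opened (void-merged)
    contour; wall sites lining a deleted cluster are additionally capped at
    ``laceration_wss_max`` Pa, emulating the recirculating flow a CFD
    solution shows in dissection recesses.
    """
    from .geometry import lumen_contour
    from .stimuli import wss_surrogate

    fields = []
    for cs, mask in zip(sections, laceration_masks):
        contour = lumen_contour(cs, include_void=True)
        field = wss_surrogate(contour, cs, flow_rate_ml_min, viscosity_pa_s)
        lines_lac = np.zeros(cs.grid.n_sites, bool)
        for d in range(6):
            nb = cs.grid.neighbors[:, d]
            ok = nb >= 0
            lines_lac[ok] |= mask[nb[ok]]
        capped = lines_lac[field.sites]
        field.wss[capped] = np.minimum(field.wss[capped], laceration_wss_max)
        fields.append(field)
    return fields
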