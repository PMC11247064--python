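"""Fibrous-tissue constitutive library.

Point-wise evaluation of the anisotropic hyperelastic strain-energy function
(isotropic matrix + two exponential fiber families with dispersion) together
with continuum damage of matrix and fibers, a one-dimensional elastoplastic
ductile-damage surrogate for atherosclerotic plaque, and the element-deletion
rule that turns damage fields into laceration masks.

Damage follows the classical (1-d) energy-reduction form: an energy norm
Xi = sqrt(2 W0) is tracked over the loading history, a linear reduction
factor s maps [Xi0, XiF] to [0, 1], and a quintic smoothstep maps s to the
damage variable d.  Damage is irreversible: s is evaluated at the maximum Xi
reached so far, so unloading never heals the tissue.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .params import LayerMaterialParams, PlaqueParams

__all__ = [
    "DeformationState",
    "Invariants",
    "DamageState",
    "isochoric_invariants",
    "fiber_strains",
    "matrix_energy",
    "fiber_energy",
    "damage_norm",
    "reduction_factor",
    "smoothstep_damage",
    "undamaged_sef",
    "damaged_sef",
    "evolve_damage",
    "uniaxial_stretch_state",
    "plaque_damage_1d",
    "element_deletion",
]

_DET_TOL = 1e-6


class InvalidDeformationError(ValueError):
    """Deformation state violates its invariants (e.g. det(Cbar) != 1)."""


@dataclass(frozen=True)
class DeformationState:
    """Isochoric right Cauchy-Green tensor plus the two structural tensors.

    ``A1 = n_c (x) n_c`` and ``A2 = n_l (x) n_l`` are rank-1 projectors built
    from the unit circumferential and longitudinal fiber directions.
    """

    Cbar: np.ndarray
    A1: np.ndarray
    A2: np.ndarray

    def __post_init__(self):
        C = np.asarray(self.Cbar, dtype=float)
        object.__setattr__(self, "Cbar", C)
        object.__setattr__(self, "A1", np.asarray(self.A1, dtype=float))
        object.__setattr__(self, "A2", np.asarray(self.A2, dtype=float))
        if C.shape != (3, 3) or not np.allclose(C, C.T, atol=1e-9):
            raise InvalidDeformationError("Cbar must be 3x3 symmetric")
        if abs(np.linalg.det(C) - 1.0) > 1e-4:
            raise InvalidDeformationError(
                f"Cbar must be isochoric (det={np.linalg.det(C):.6g})")
        for A in (self.A1, self.A2):
            if abs(np.trace(A) - 1.0) > 1e-8:
                raise InvalidDeformationError("structural tensors need unit trace")

    @classmethod
    def from_directions(cls, Cbar, n_c, n_l) -> "DeformationState":
        n_c = np.asarray(n_c, float) / np.linalg.norm(n_c)
        n_l = np.asarray(n_l, float) / np.linalg.norm(n_l)
        return cls(Cbar, np.outer(n_c, n_c), np.outer(n_l, n_l))


@dataclass(frozen=True)
class Invariants:
    """Isochoric invariants: I1bar = tr(Cbar), I4bar/I6bar the squared
    fiber stretches along the two families."""

    I1bar: float
    I4bar: float
    I6bar: float


def isochoric_invariants(state: DeformationState) -> Invariants:
    """I1bar = tr(Cbar), I4bar = Cbar:A1, I6bar = Cbar:A2."""
    C = state.Cbar
    return Invariants(
        I1bar=float(np.trace(C)),
        I4bar=float(np.tensordot(C, state.A1)),
        I6bar=float(np.tensordot(C, state.A2)),
    )


def uniaxial_stretch_state(lam: float, axis: int = 0) -> DeformationState:
    """Isochoric uniaxial stretch ``lam`` along a coordinate axis, fiber
    family A1 on that axis and A2 on the next one. Convenience constructor."""
    if lam <= 0:
        raise ValueError("stretch must be positive")
    stretches = np.full(3, lam ** -0.5)
    stretches[axis] = lam
    C = np.diag(stretches ** 2)
    n_c = np.eye(3)[axis]
    n_l = np.eye(3)[(axis + 1) % 3]
    return DeformationState.from_directions(C, n_c, n_l)


def fiber_strains(inv: Invariants, kappa: float) -> tuple[float, float]:
    """Dispersion-weighted fiber strain measures.

    E4 = kappa (I1-3) + (1-3 kappa)(I4-1), likewise E6 with I6.  Negative
    values are returned as-is; downstream energy applies the Macaulay bracket.
    """
    if not 0.0 <= kappa <= 1.0 / 3.0 + 1e-12:
        raise ValueError("kappa must lie in [0, 1/3]")
    e4 = kappa * (inv.I1bar - 3.0) + (1.0 - 3.0 * kappa) * (inv.I4bar - 1.0)
    e6 = kappa * (inv.I1bar - 3.0) + (1.0 - 3.0 * kappa) * (inv.I6bar - 1.0)
    return e4, e6


def matrix_energy(I1bar: float, c10: float) -> float:
    """Neo-Hookean matrix energy c10 (I1-3) [MPa], clamped at 0 from below."""
    return max(c10 * (I1bar - 3.0), 0.0)


def _family_energy(e: float, k_stiff: float, k_exp: float) -> float:
    e = max(e, 0.0)  # Macaulay bracket: compressed fibers store no energy
    if k_exp == 0.0:
        return 0.5 * k_stiff * e * e  # quadratic limit
    return k_stiff / (2.0 * k_exp) * np.expm1(min(k_exp * e * e, 700.0))


def fiber_energy(e4: float, e6: float,
                 params: LayerMaterialParams) -> tuple[float, float]:
    """Per-family exponential fiber energies [MPa], bracket applied."""
    return (_family_energy(e4, params.k1, params.k2),
            _family_energy(e6, params.k3, params.k4))


def damage_norm(undamaged_energy: float) -> float:
    """Energy norm Xi = sqrt(2 W0) [MPa^(1/2)]."""
    if undamaged_energy < 0:
        raise ValueError("energy must be >= 0")
    return float(np.sqrt(2.0 * undamaged_energy))


def reduction_factor(xi_history_max: float, Xi0: float, XiF: float) -> float:
    """Linear damage driver s = clamp((Xi_max - Xi0)/(XiF - Xi0), 0, 1).

    Evaluated at the historical maximum norm so damage is irreversible.
    """
    if not XiF > Xi0:
        raise ValueError("XiF must exceed Xi0")
    return float(np.clip((xi_history_max - Xi0) / (XiF - Xi0), 0.0, 1.0))


def smoothstep_damage(s: float) -> float:
    """Quintic smoothstep d = s^3 (10 - 15 s + 6 s^2); C1 at both ends."""
    if s < 0.0 or s > 1.0:
        import warnings
        warnings.warn("reduction factor outside [0,1]; clamped", stacklevel=2)
        s = float(np.clip(s, 0.0, 1.0))
    return s ** 3 * (10.0 - 15.0 * s + 6.0 * s * s)


@dataclass
class DamageState:
    """Damage variables and their history-maximum energy norms."""

    d_m: float = 0.0
    d_fA1: float = 0.0
    d_fA2: float = 0.0
    ximax_m: float = 0.0
    ximax_fA1: float = 0.0
    ximax_fA2: float = 0.0

    def copy(self) -> "DamageState":
        return dataclasses.replace(self)


def undamaged_sef(state: DeformationState,
                  params: LayerMaterialParams) -> tuple[float, float, float]:
    """(matrix, fiber A1, fiber A2) undamaged isochoric energies [MPa]."""
    inv = isochoric_invariants(state)
    e4, e6 = fiber_strains(inv, params.kappa)
    w_m = matrix_energy(inv.I1bar, params.c10)
    w_f1, w_f2 = fiber_energy(e4, e6, params)
    return w_m, w_f1, w_f2


def damaged_sef(state: DeformationState, params: LayerMaterialParams,
                dmg: DamageState) -> float:
    """Damage-reduced total isochoric energy
    (1-d_m) W0_m + (1-d_fA1) W0_fA1 + (1-d_fA2) W0_fA2 [MPa]."""
    w_m, w_f1, w_f2 = undamaged_sef(state, params)
    return ((1.0 - dmg.d_m) * w_m + (1.0 - dmg.d_fA1) * w_f1
            + (1.0 - dmg.d_fA2) * w_f2)


def _update_mechanism(ximax: float, w0: float, Xi0, XiF) -> tuple[float, float]:
    """Advance one damage mechanism; returns (new ximax, d)."""
    xi = damage_norm(w0)
    ximax = max(ximax, xi)
    if Xi0 is None:
        return ximax, 0.0
    return ximax, smoothstep_damage(reduction_factor(ximax, Xi0, XiF))


def evolve_damage(history: Iterable[DeformationState],
                  params: LayerMaterialParams,
                  initial: DamageState | None = None) -> list[DamageState]:
    """Integrate the damage state along an ordered deformation history.

    At each step the undamaged energies are evaluated, the historical maximum
    norms updated and (s, d) recomputed, so each damage variable is
    non-decreasing.  Fiber mechanisms accumulate no norm while the Macaulay
    bracket is active (zero energy contributes Xi = 0).
    """
    dmg = (initial or DamageState()).copy()
    out: list[DamageState] = []
    for state in history:
        w_m, w_f1, w_f2 = undamaged_sef(state, params)
        dmg.ximax_m, dmg.d_m = _update_mechanism(
            dmg.ximax_m, w_m, params.Xi0_m, params.XiF_m)
        dmg.ximax_fA1, dmg.d_fA1 = _update_mechanism(
            dmg.ximax_fA1, w_f1, params.Xi0_fA1, params.XiF_fA1)
        dmg.ximax_fA2, dmg.d_fA2 = _update_mechanism(
            dmg.ximax_fA2, w_f2, params.Xi0_fA2, params.XiF_fA2)
        out.append(dmg.copy())
    return out


def plaque_damage_1d(stretch_history: Sequence[float],
                     params: PlaqueParams,
                     char_length: float | None = None) -> float:
    """One-dimensional ductile-damage surrogate for plaque tissue.

    Plastic flow starts once the stretch exceeds the yield stretch
    ``lambda_y`` at constant yield stress; the equivalent plastic strain is
    the history maximum of ln(lambda/lambda_y).  Damage initiates when it
    reaches ``uf_pl`` and then evolves exponentially with the plastic work
    dissipated past initiation, normalized by Gf over a characteristic
    length: D = 1 - exp(-sigma_y * L * (eps_pl - uf_pl) / Gf), saturating
    at 1.
    """
    L = params.char_length if char_length is None else char_length
    eps_pl = 0.0
    for lam in stretch_history:
        if lam <= 0:
            raise ValueError("stretch must be positive")
        if lam > params.lambda_y:
            eps_pl = max(eps_pl, np.log(lam / params.lambda_y))
    if eps_pl < params.uf_pl:
        return 0.0
    if params.Gf == 0:
        return 1.0
    w_post = params.sigma_y * L * (eps_pl - params.uf_pl)
    return float(1.0 - np.exp(-w_post / params.Gf))


def element_deletion(damage_field: np.ndarray,
                     threshold: float = 0.8) -> np.ndarray:
    """Boolean laceration mask: True exactly where damage >= threshold."""
    damage_field = np.asarray(damage_field, dtype=float)
    if np.any((damage_field < 0) | (damage_field > 1)):
        raise ValueError("damage values must lie in [0, 1]")
    return damage_field >= threshold
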