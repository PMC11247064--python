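"""Model parameters: arterial-layer constitutive constants, plaque plasticity,
stimulus-curve constants and agent-event rates, plus config (de)serialization.

Units follow vascular-mechanics convention: stresses and energies in MPa
(= mJ/mm^3), lengths in mm, WSS in Pa, time in days unless noted.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "LayerMaterialParams",
    "PlaqueParams",
    "StimulusParams",
    "ABMRates",
    "MEDIA",
    "ADVENTITIA",
    "PLAQUE",
    "calibrated_beta_med",
    "SimulationConfig",
]


@dataclass(frozen=True)
class LayerMaterialParams:
    """Anisotropic hyperelastic (two fiber family) layer with optional
    matrix/fiber damage.

    ``c10`` is the neo-Hookean matrix stiffness [MPa]; ``k1``/``k3`` fiber
    stiffnesses [MPa] and ``k2``/``k4`` dimensionless fiber exponents for the
    circumferential (A1) and longitudinal (A2) families; ``kappa`` the fiber
    dispersion in [0, 1/3].  ``Xi0_*``/``XiF_*`` are the energy-norm onset/end
    thresholds [MPa^(1/2)] of the matrix and per-family fiber damage; ``None``
    disables damage for that mechanism (the adventitia has no damage).
    """

    c10: float
    k1: float
    k2: float
    k3: float
    k4: float
    kappa: float = 0.0  # perfectly aligned families by default
    Xi0_m: Optional[float] = None
    XiF_m: Optional[float] = None
    Xi0_fA1: Optional[float] = None
    XiF_fA1: Optional[float] = None
    Xi0_fA2: Optional[float] = None
    XiF_fA2: Optional[float] = None
    layer: str = "media"

    def __post_init__(self) -> None:
        for name in ("c10", "k1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12:
            raise ValueError("kappa must lie in [0, 1/3]")
        for lo, hi in (("Xi0_m", "XiF_m"), ("Xi0_fA1", "XiF_fA1"),
                       ("Xi0_fA2", "XiF_fA2")):
            a, b = getattr(self, lo), getattr(self, hi)
            if (a is None) != (b is None):
                raise ValueError(f"{lo}/{hi} must be given together")
            if a is not None and not b > a:
                raise ValueError(f"{hi} must exceed {lo}")

    @property
    def matrix_damage_enabled(self) -> bool:
        return self.Xi0_m is not None


@dataclass(frozen=True)
class PlaqueParams:
    """Elastoplastic ductile-damage plaque constants.

    ``sigma_y`` yield stress [MPa], ``lambda_y`` yield stretch [-],
    ``Gf`` fracture energy [mJ/mm^2], ``uf_pl`` equivalent plastic strain at
    damage initiation [-], ``char_length`` regularization length [mm].
    """

    c10: float = 0.0863
    sigma_y: float = 0.43
    lambda_y: float = 1.75
    Gf: float = 0.0215
    uf_pl: float = 0.1
    char_length: float = 0.0375

    def __post_init__(self) -> None:
        for name in ("c10", "sigma_y", "Gf", "uf_pl", "char_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.lambda_y > 1.0:
            raise ValueError("lambda_y must exceed 1")


#: Media-layer constants (human distal SFA calibration).
MEDIA = LayerMaterialParams(
    c10=0.183, k1=0.080, k2=0.253, k3=0.127, k4=0.217,
    Xi0_m=0.497, XiF_m=0.808,
    Xi0_fA1=0.005, XiF_fA1=2.323,
    Xi0_fA2=0.040, XiF_fA2=2.179,
    layer="media",
)

#: Adventitia-layer constants; damage disabled (no thresholds published).
ADVENTITIA = LayerMaterialParams(
    c10=0.104, k1=0.168, k2=0.009, k3=0.205, k4=0.009,
    layer="adventitia",
)

#: Moderately calcified plaque.
PLAQUE = PlaqueParams()


@dataclass(frozen=True)
class StimulusParams:
    """Constants of the two driving inputs.

    ``L1`` [1/Pa] sigmoid slope and ``L2`` [Pa] half-maximum of the
    endothelial-dysfunction curve D(WSS); ``Amp`` [-] and ``dist`` [mm] scale
    and depth of the transmural propagation; ``delay`` [d] inflammation onset
    and ``inflammation_end`` [d] its vanishing time.
    """

    L1: float = -7.5
    L2: float = 5.0
    Amp: float = 1.0
    dist: float = 0.1415
    delay: float = 3.0
    inflammation_end: float = 30.0

    def __post_init__(self) -> None:
        if self.dist <= 0:
            raise ValueError("dist must be > 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if not self.inflammation_end > self.delay:
            raise ValueError("inflammation_end must exceed delay")


def calibrated_beta_med(smc_ecm_ratio: float = 0.72) -> float:
    """Degradation divisor balancing media ECM turnover in homeostasis.

    With ECM production hosted by SMCs and degradation by ECM agents, both on
    the ECM clock cadence, zero expected drift requires
    ``beta_med = N_ECM / N_SMC = 1 / smc_ecm_ratio``.
    """
    if smc_ecm_ratio <= 0:
        raise ValueError("smc_ecm_ratio must be > 0")
    return 1.0 / smc_ecm_ratio


@dataclass(frozen=True)
class ABMRates:
    """Per-cycle event probabilities/weights of the agent rules.

    ``alpha1`` baseline mitosis/apoptosis, ``alpha2``/``alpha3`` WSS- and
    damage-driven mitosis weights, ``alpha4`` baseline ECM production,
    ``alpha5``/``alpha6`` its stimulus weights, ``beta_med``/``beta_adv``
    degradation divisors.  ``beta_med`` defaults to the homeostasis-calibrated
    value (see :func:`calibrated_beta_med`); the literature baseline 1.85 can
    be set explicitly.  ``migration_threshold`` is the site-damage level above
    which a lumen-lining SMC is a migration candidate.
    """

    alpha1: float = 0.05
    alpha2: float = 0.11
    alpha3: float = 0.66
    alpha4: float = 0.008
    alpha5: float = 0.0413
    alpha6: float = 0.21
    beta_med: float = field(default_factory=calibrated_beta_med)
    beta_adv: float = 2.5
    migration_threshold: float = 0.8
    collagen_fraction: float = 0.63 / 1.63  # collagen share of produced ECM

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.beta_med == 0 or self.beta_adv == 0:
            raise ValueError("beta divisors must be positive")


@dataclass
class SimulationConfig:
    """Full run configuration (mirrors the published parameter tables).

    Composition ratios: ``smc_ecm_ratio`` SMC/ECM in the media,
    ``collagen_elastin_ratio`` within media ECM, ``fib_collagen_ratio``
    fibroblast/collagen in the adventitia.
    """

    n_rows: int = 300
    n_cols: int = 300
    spacing: float = 0.0375           # mm per site (1.5 cells of ~25 um)
    dt_hours: float = 2.0
    t_cell_hours: float = 24.0
    t_ecm_hours: float = 4.0
    horizon_days: float = 60.0
    coupling_days: float = 30.0
    n_replicates: int = 3
    n_planes: int = 11
    plane_spacing: float = 2.0        # mm
    smc_ecm_ratio: float = 0.72
    collagen_elastin_ratio: float = 0.63
    fib_collagen_ratio: float = 0.43
    deletion_threshold: float = 0.8
    flow_rate_ml_min: float = 100.0
    viscosity_pa_s: float = 0.0035
    media: LayerMaterialParams = field(default_factory=lambda: MEDIA)
    adventitia: LayerMaterialParams = field(default_factory=lambda: ADVENTITIA)
    plaque: PlaqueParams = field(default_factory=lambda: PLAQUE)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    rates: ABMRates = field(default_factory=ABMRates)
    seed: int = 0

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            return obj
        return enc(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(d) - known)
        if bad:
            raise ValueError(f"unknown config keys: {', '.join(bad)}")
        for key, sub in (("media", LayerMaterialParams),
                         ("adventitia", LayerMaterialParams),
                         ("plaque", PlaqueParams),
                         ("stimulus", StimulusParams),
                         ("rates", ABMRates)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)
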