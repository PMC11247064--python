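# Methods

`restenosim` simulates arterial restenosis after balloon angioplasty
(percutaneous transluminal angioplasty, PTA) as a coupled sequence of three
desk-scale stages: a continuum damage description of the balloon injury, a
surrogate hemodynamics stage producing wall shear stress (WSS), and a
hexagonal-lattice agent-based model (ABM) of wall remodeling over the first
two post-operative months. This note records the model equations, every
tunable that matters, the design decisions taken where the problem was
genuinely open, and the limits of what the synthetic test bed can show.

## Tissue constitutive model and damage

The media layer is an anisotropic hyperelastic solid: an isotropic
neo-Hookean matrix plus two exponential fiber families along the
circumferential and longitudinal directions, with isochoric invariants
`I1 = tr(C̄)`, `I4 = C̄:A1`, `I6 = C̄:A2` and dispersion-weighted fiber
strains `E4 = κ(I1−3) + (1−3κ)(I4−1)` (likewise `E6`). Compressed fibers
store no energy (Macaulay bracket). Matrix and per-family fiber energies are
reduced by independent scalar damage variables `d = s³(10 − 15s + 6s²)`,
where `s` maps the energy norm `Ξ = √(2W₀)` linearly from an onset `Ξ0` to a
failure value `ΞF`. Defaults carry the published human distal
superficial-femoral-artery calibration (media `c10 = 0.183` MPa,
`k1 = 0.080`, `k2 = 0.253`, `k3 = 0.127`, `k4 = 0.217`, matrix thresholds
0.497/0.808 MPa^½, fiber thresholds 0.005/2.323 and 0.040/2.179 MPa^½); the
adventitia has no published damage thresholds, so its damage is disabled.

Decisions taken here:

* **Irreversibility.** `s` is evaluated at the running maximum of `Ξ`, so
  unloading never heals tissue. Without this, post-PTA damage maps would
  vanish on recoil.
* **Fiber dispersion.** `κ` defaults to 0 (perfectly aligned families),
  the only value under which the published stiffness table retains its
  meaning; it is configurable in `LayerMaterialParams`.
* **Plaque.** The plaque is elastoplastic (neo-Hookean, perfect plasticity
  at `σy = 0.43` MPa beyond the yield stretch `λy = 1.75`) with ductile
  damage: plastic strain is `max ln(λ/λy)` over the history, damage starts
  at an equivalent plastic strain of `uf_pl = 0.1` and then evolves as
  `D = 1 − exp(−σy·L·(ε_pl − uf_pl)/Gf)` with fracture energy
  `Gf = 0.0215` mJ/mm². The regularization length `L` is configurable; the
  constitutive default is the ABM site spacing (0.0375 mm), while the
  synthetic generator passes `fe_char_length = 0.3` mm, the element size of
  the finite-element discretization it emulates — with the site spacing a
  stretch of ~16 would be needed to reach deletion-level damage.
* **Element deletion.** Sites whose damage reaches 0.8 are removed and
  become void (lacerations). The generator applies the threshold to the
  *neighborhood minimum* of the site damage — the lattice analogue of
  element-wise deletion on a nodal damage field — so a rim of surviving
  high-damage sites remains around each laceration. That rim is exactly the
  population of migration-capable cells (see below); deleting on raw site
  damage would remove them all.

## Cross-section geometry

Each plane lives on a pointy-top hexagonal lattice (default 300 × 300 sites,
0.0375 mm/site ≈ 1.5 smooth-muscle-cell diameters). The lumen boundary is
traced as the exact outline of the union of lumen hexagons (edge chaining
with sharpest-left-turn resolution at pinch vertices), which keeps contour
areas consistent with site counts from a single site (its hexagon) up to
full discs (< 1 % area error at clinically relevant radii). Reported
contours are additionally regularized by a circular moving average of the
vertex radii about the centroid (window 5, area-change guard 2 %). A
grid-level relabeling smoother exists (`smooth_interface`) but is not part
of the default loop: at any permissive threshold its pocket-filling step
preferentially reverses removal events and biases the homeostatic state by
a few sites per day.

## Stimuli

Two fields push event probabilities above baseline:

* **Dinput** — the static injury field times a normalized inflammation
  curve. Only the curve's landmarks are published (onset delay 3 d, peak
  near day 3–4, gone at day 30); the implementation uses a sin² rise over
  one day and a raised-cosine decay to exactly zero at day 30, all
  configurable. Results depend on the curve's time integral rather than its
  exact shape.
* **WSSinput** — endothelial dysfunction
  `D(WSS) = 1 − 1/(1 + e^{L1(WSS−L2)})` with `L1 = −7.5` Pa⁻¹ and
  `L2 = 5` Pa evaluated on lumen-wall sites and propagated into the media
  by `Σᵢ D(WSS)ᵢ · Amp · (1 + cos(π x/dist))` over wall sites within
  `dist = 0.1415` mm, clamped to `[0, 2·Amp]`. The pairing of interior
  sites with wall sites is not published; summing over all wall sites
  within Euclidean radius `dist` reduces to the printed single-site form
  and makes the support exactly the depth-`dist` band.

WSS itself comes from an external CSV (plane id, angle, Pa) or from a
Poiseuille-style surrogate: `τ = 4μQ/(πR_eq³)` for the equivalent-area
circle (Q = 100 mL/min, μ = 3.5 mPa·s by default), scaled per wall site by
`(r_mean/r_local)^p` with `p = 3`, which concentrates low WSS in recesses;
sites lining a laceration are additionally capped below 1 Pa, emulating the
recirculation a CFD solution shows in dissection pockets. The WSS field is
frozen within each 30-day coupling cycle and recomputed from the remodeled
geometry at the boundary; the *propagated* input is re-evaluated daily on
the current wall (frozen sigmoid values mapped to the moving wall by
nearest neighbor), because a literally frozen map would stall growth at the
original wall line.

## Agent-based model

One agent per tissue site: SMCs, collagen and elastin in the media
(SMC/ECM = 0.72, collagen/elastin = 0.63), fibroblasts and collagen in the
adventitia (0.43), inert matrix in the plaque. Cells carry a 24-h cycle
clock, matrix turnover runs on a 4-h cadence, both desynchronized at start
and advanced in 2-h steps. When a clock wraps, the agent draws for its
events:

```
media SMC:  p_div  = α1 + α2·WSSinput + α3·Dinput     p_apo = α1
            p_prod = α4 + α5·WSSinput + α6·Dinput
media ECM:  p_deg  = α4 / β_med
adventitia: p_div = p_apo = α1,  p_prod = α4,  p_deg = α4 / β_adv
```

with `α1 = 0.05`, `α2 = 0.11`, `α3 = 0.66`, `α4 = 0.008`, `α5 = 0.0413`,
`α6 = 0.21`, `β_adv = 2.5`, all clamped to [0, 1]. Division and apoptosis
compete on a single uniform draw (division on the lower tail, apoptosis on
the upper), which is unbiased when the two probabilities are equal; a
two-draw scheme would add a net `α1²` growth per cycle and break
homeostasis.

**Event hosting and the calibration of β_med.** The published rules do not
say which agents host ECM production. Here production is performed by cells
(SMCs in the media, fibroblasts in the adventitia) on the 4-h cadence and
degradation by ECM agents on the same cadence. Homeostasis then requires
`β_med = N_ECM/N_SMC = 1/0.72 ≈ 1.389`, which is the package default;
`calibrated_beta_med()` recomputes it from any composition. The literature
value 1.85 remains available in the configuration but produces ~40 % media
growth over 60 days under zero stimuli with this hosting scheme. The
adventitia analogue of the balance argument gives `1/0.43 ≈ 2.33`, close to
the published `β_adv = 2.5`, which supports the hosting choice; the small
residual adventitia drift only moves the outer boundary.

**Growth mechanics.** Media insertions shift the radial chain of agents
between the event site and the nearest flow site (BFS through media,
deterministic tie-breaks), annexing exactly one lumen/void site; removals
pull the chain back and free exactly one. Adventitia chains run to the
external boundary, leaving the lumen untouched. ECM production creates
collagen with probability 0.63/1.63, else elastin, preserving the initial
ECM composition in expectation.

**Migration.** SMCs on lumen-lining media sites with injury damage ≥ 0.8
may jump to free lumen/void sites lining a still-open laceration, with
probability `1/d_min` (site-spacing units) toward the nearest free target
(ties to the lowest site index). The vacated site joins the lumen — the
same bookkeeping as an outward chain shift, but strictly local. A migrated
SMC converts its target to media permanently. Targets are recomputed
against the *currently open* laceration so migration stops once the
dissection has healed.

## Pipeline

Per plane and coupling cycle, `n_replicates = 3` stochastic replicates run
from the same state with independent RNG streams (per-cycle seeds derived
from `SeedSequence([seed, cycle])`, per-replicate seeds from
`(seed, plane, replicate)`); the replicate minimizing the contour-radius
RMSD from the replicate average (360 equal angles about the shared
centroid) is selected, all replicates restart from it, and WSS is
recomputed. The coupling loop is checkpoint-restartable: a 30 + 30-day run
with a restart is bit-identical to a 60-day run. Follow-up lumen surfaces
are lofted through the per-plane contours (200 aligned vertices each,
ruled triangles; open-cylinder topology).

## Synthetic vessel and virtual expansion

The generator emulates a diseased femoral segment: 11 planes 2 mm apart,
lumen radius tapering 1.65 → 1.45 mm (target lumen area 8.55 mm² at the
inlet), ~0.7 mm two-layer wall, and an eccentric plaque bulging into the
lumen over the central planes. The virtual balloon applies a circumferential
stretch `λ = 1 + (ratio − 1)·(r_ref/r)^2` peaking at the lumen, amplified by
Gaussian factors at the two plaque shoulders where inflation concentrates
strain, with 5 % lognormal noise; media damage follows the constitutive law
(incompressible uniaxial ramp), plaque damage the ductile surrogate. The
default balloon-to-lumen ratio is 1.6, a moderate overexpansion that
produces shoulder lacerations without tearing the whole wall; deleted-site
counts are monotone in the ratio under a fixed seed.

What the synthetic bed does *not* emulate: patient geometry, the true
finite-element strain field (only its qualitative localization), CFD
secondary flows (only the low-WSS-in-recess signature), or endothelial
recovery. Consequently the passing dynamic tests certify internal
consistency — homeostasis without stimuli, bounded composition drift,
laceration recovery, growth slow-down after the inflammation window and the
month-1 WSS update — not clinical restenosis magnitudes. With the surrogate
WSS (~1.7 Pa everywhere, far below `L2 = 5` Pa) the shear stimulus is
saturated and the simulated restenosis is more aggressive than the
published patient case; the self-limiting mechanism (narrowing raises WSS
toward `L2`, shutting growth off) is the same.

## Numerical choices and problem sizes

Probabilities clamp to [0, 1]; WSSinput clamps to `2·Amp`; chain searches
cap at 200 sites and blocked events are skipped and counted; a plane whose
flow domain falls below 10 sites is frozen for the remaining days; RMSD
ties and migration-target ties resolve to the lowest index; all randomness
flows through `numpy` PCG64 generators seeded as above, making every
trajectory reproducible bit-for-bit. The stochastic whole-simulation checks
run on a 150 × 150 lattice with a proportionally thinner wall
(`VesselSpec.scaled_down()`), the statistical initialization checks on the
full 300 × 300 lattice; both sizes are first-class configurations.

## Known limitations

* The event-hosting scheme for ECM production is an interpretation; other
  schemes imply different balanced `β_med` values.
* The inflammation curve's analytic form between its published landmarks is
  chosen, not derived.
* The 1D plaque surrogate reproduces initiation and energy-controlled
  softening but not mesh-dependent stress redistribution.
* Lofting assumes star-shaped contours about their centroid; deeply
  non-convex lumens would need arc-length parameterization.
* The Mann–Whitney exact branch enumerates up to n+m = 12 (the 11-plane
  use case); beyond that a tie-corrected normal approximation is used.
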