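"""Agent-based model of arterial wall remodeling on one cross-section.

Every tissue site hosts one agent: smooth muscle cells (SMC), collagen and
elastin in the media; fibroblasts and collagen in the adventitia; inert
matrix in the plaque.  Agents carry desynchronized biological clocks
(T_cell = 24 h for cell events, T_ECM = 4 h for matrix turnover) advanced in
2-h steps; an agent whose clock wraps draws for its events against
stimulus-dependent probabilities.  Growth is oriented inward in the media
(each insertion converts one lumen site to tissue, each removal frees one)
and outward in the adventitia (lumen unaffected), implemented by shifting
the radial chain of agents between the event site and the relevant boundary.
Lumen-lining SMCs with high balloon-injury damage can migrate onto the lumen
sites lining lacerated plaque, seeding the recovery of dissection voids.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import (ADVENTITIA, CrossSection, EXTERIOR, LUMEN, MEDIA,
                       PLAQUE, VOID)
from .params import ABMRates

__all__ = [
    "AGENT_NONE", "SMC", "FIBROBLAST", "COLLAGEN", "ELASTIN", "PLAQUE_MATRIX",
    "AGENT_NAMES", "AgentGrid", "EventLog", "PlaneState",
    "initialize_agents", "event_probabilities", "find_migration_pairs",
    "migration_step", "apply_event", "step",
]

AGENT_NONE, SMC, FIBROBLAST, COLLAGEN, ELASTIN, PLAQUE_MATRIX = range(6)
AGENT_NAMES = {AGENT_NONE: "none", SMC: "smc", FIBROBLAST: "fibroblast",
               COLLAGEN: "collagen", ELASTIN: "elastin",
               PLAQUE_MATRIX: "plaque_matrix"}

_CELL_KINDS = (SMC, FIBROBLAST)
_ECM_KINDS = (COLLAGEN, ELASTIN)

# event type codes for the log
EV_MIGRATION, EV_MITOSIS, EV_APOPTOSIS, EV_PRODUCTION, EV_DEGRADATION, \
    EV_SMOOTH_FILL, EV_SMOOTH_CARVE = range(7)
EVENT_NAMES = {EV_MIGRATION: "migration", EV_MITOSIS: "mitosis",
               EV_APOPTOSIS: "apoptosis", EV_PRODUCTION: "ecm_production",
               EV_DEGRADATION: "ecm_degradation",
               EV_SMOOTH_FILL: "smoothing_fill",
               EV_SMOOTH_CARVE: "smoothing_carve"}


@dataclass
class AgentGrid:
    """Flat per-site agent state (one agent per occupied site).

    ``clock_cell`` gates mitosis/apoptosis (cells), ``clock_ecm`` gates ECM
    production draws (hosted by cells) and degradation draws (ECM agents).
    """

    kind: np.ndarray
    clock_cell: np.ndarray
    clock_ecm: np.ndarray
    t_cell: float = 24.0
    t_ecm: float = 4.0

    def copy(self) -> "AgentGrid":
        return AgentGrid(self.kind.copy(), self.clock_cell.copy(),
                         self.clock_ecm.copy(), self.t_cell, self.t_ecm)


class EventLog:
    """Time-stamped record of every applied event (seed-reproducible)."""

    def __init__(self):
        self.t_hours: list[float] = []
        self.site: list[int] = []
        self.kind: list[int] = []
        self.event: list[int] = []
        self.probability: list[float] = []
        self.draw: list[float] = []

    def add(self, t, site, kind, event, p, u):
        self.t_hours.append(float(t))
        self.site.append(int(site))
        self.kind.append(int(kind))
        self.event.append(int(event))
        self.probability.append(float(p))
        self.draw.append(float(u))

    def __len__(self):
        return len(self.site)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "t_hours": self.t_hours, "site": self.site,
            "agent": [AGENT_NAMES[k] for k in self.kind],
            "event": [EVENT_NAMES[e] for e in self.event],
            "probability": self.probability, "draw": self.draw,
        })

    def signature(self) -> tuple:
        """Hashable trajectory fingerprint for determinism checks."""
        return (tuple(self.site), tuple(self.event),
                tuple(np.round(self.draw, 12)))


@dataclass
class PlaneState:
    """Mutable simulation state of one cross-sectional plane."""

    cs: CrossSection
    agents: AgentGrid
    damage: np.ndarray                      # static balloon-injury field
    deleted_mask: np.ndarray                # sites removed by element deletion
    deleted_plaque_mask: np.ndarray         # the plaque subset of the above
    log: EventLog = field(default_factory=EventLog)
    t_hours: float = 0.0
    skipped_events: int = 0

    def copy(self) -> "PlaneState":
        log = EventLog()
        log.t_hours = list(self.log.t_hours)
        log.site = list(self.log.site)
        log.kind = list(self.log.kind)
        log.event = list(self.log.event)
        log.probability = list(self.log.probability)
        log.draw = list(self.log.draw)
        out = PlaneState(self.cs.copy(), self.agents.copy(),
                         self.damage.copy(), self.deleted_mask.copy(),
                         self.deleted_plaque_mask.copy(), log,
                         self.t_hours, self.skipped_events)
        return out

    def flow_mask(self) -> np.ndarray:
        return (self.cs.labels == LUMEN) | (self.cs.labels == VOID)

    def void_fraction(self) -> float:
        """Fraction of originally deleted sites still devoid of tissue."""
        n0 = int(self.deleted_mask.sum())
        if n0 == 0:
            return 0.0
        open_now = self.flow_mask() & self.deleted_mask
        return float(open_now.sum()) / n0


def initialize_agents(cs: CrossSection, rng: np.random.Generator,
                      smc_ecm_ratio: float = 0.72,
                      collagen_elastin_ratio: float = 0.63,
                      fib_collagen_ratio: float = 0.43,
                      t_cell: float = 24.0, t_ecm: float = 4.0) -> AgentGrid:
    """Populate tissue sites with agents at the physiological composition.

    Media sites draw SMC with probability r/(1+r) for SMC/ECM ratio r, the
    rest split into collagen/elastin by their ratio; adventitia sites draw
    fibroblast vs collagen likewise; plaque sites get inert matrix.  Clocks
    start uniformly within their cycles (desynchronization).
    """
    for name, r in (("smc_ecm_ratio", smc_ecm_ratio),
                    ("collagen_elastin_ratio", collagen_elastin_ratio),
                    ("fib_collagen_ratio", fib_collagen_ratio)):
        if r < 0:
            raise ValueError(f"{name} must be >= 0")
    n = cs.grid.n_sites
    kind = np.full(n, AGENT_NONE, dtype=np.int8)

    media = np.flatnonzero(cs.labels == MEDIA)
    u = rng.random(media.size)
    is_smc = u < smc_ecm_ratio / (1.0 + smc_ecm_ratio)
    kind[media[is_smc]] = SMC
    ecm_sites = media[~is_smc]
    u2 = rng.random(ecm_sites.size)
    is_col = u2 < collagen_elastin_ratio / (1.0 + collagen_elastin_ratio)
    kind[ecm_sites[is_col]] = COLLAGEN
    kind[ecm_sites[~is_col]] = ELASTIN

    adv = np.flatnonzero(cs.labels == ADVENTITIA)
    u3 = rng.random(adv.size)
    is_fib = u3 < fib_collagen_ratio / (1.0 + fib_collagen_ratio)
    kind[adv[is_fib]] = FIBROBLAST
    kind[adv[~is_fib]] = COLLAGEN

    kind[cs.labels == PLAQUE] = PLAQUE_MATRIX

    clock_cell = np.zeros(n)
    clock_ecm = np.zeros(n)
    cells = np.isin(kind, _CELL_KINDS)
    ecm = np.isin(kind, _ECM_KINDS)
    clock_cell[cells] = rng.random(int(cells.sum())) * t_cell
    clock_ecm[cells] = rng.random(int(cells.sum())) * t_ecm
    clock_ecm[ecm] = rng.random(int(ecm.sum())) * t_ecm
    return AgentGrid(kind, clock_cell, clock_ecm, t_cell, t_ecm)


def event_probabilities(kinds: np.ndarray, labels: np.ndarray,
                        din: np.ndarray, wssin: np.ndarray,
                        rates: ABMRates) -> dict[str, np.ndarray]:
    """Per-agent event probabilities, clamped to [0, 1].

    Media SMC: p_division = a1 + a2 WSSinput + a3 Dinput, p_apoptosis = a1,
    p_production = a4 + a5 WSSinput + a6 Dinput; media ECM degrades with
    a4/beta_med.  Adventitia keeps baseline rates (production a4, degradation
    a4/beta_adv).  Plaque matrix is inert.
    """
    kinds = np.asarray(kinds)
    labels = np.asarray(labels)
    din = np.asarray(din, dtype=float)
    wssin = np.asarray(wssin, dtype=float)
    clip = lambda p: np.clip(p, 0.0, 1.0)
    in_media = labels == MEDIA
    in_adv = labels == ADVENTITIA
    is_smc = kinds == SMC
    is_fib = kinds == FIBROBLAST
    is_ecm = np.isin(kinds, _ECM_KINDS)

    p_div = np.zeros(kinds.shape)
    p_apo = np.zeros(kinds.shape)
    p_pro = np.zeros(kinds.shape)
    p_deg = np.zeros(kinds.shape)

    m = in_media & is_smc
    p_div[m] = clip(rates.alpha1 + rates.alpha2 * wssin[m]
                    + rates.alpha3 * din[m])
    p_apo[m] = clip(np.full(int(m.sum()), rates.alpha1))
    p_pro[m] = clip(rates.alpha4 + rates.alpha5 * wssin[m]
                    + rates.alpha6 * din[m])
    p_deg[in_media & is_ecm] = clip(rates.alpha4 / rates.beta_med)

    a = in_adv & is_fib
    p_div[a] = clip(rates.alpha1)
    p_apo[a] = clip(rates.alpha1)
    p_pro[a] = clip(rates.alpha4)
    p_deg[in_adv & is_ecm] = clip(rates.alpha4 / rates.beta_adv)
    return {"division": p_div, "apoptosis": p_apo,
            "production": p_pro, "degradation": p_deg}


# ---------------------------------------------------------------------------
# chain mechanics

_MAX_CHAIN = 200


def _find_chain(state: PlaneState, start: int, through: int,
                terminal_labels: tuple[int, ...]) -> Optional[list[int]]:
    """Shortest site path from ``start`` through ``through``-labelled tissue
    to the first site with a terminal label (BFS; deterministic tie-break by
    site index).  Returns [start, ..., terminal] or None if blocked."""
    labels = state.cs.labels
    nbrs = state.cs.grid.neighbors
    prev = {start: -1}
    frontier = [start]
    for _ in range(_MAX_CHAIN):
        nxt = []
        for s in frontier:
            for nb in nbrs[s]:
                if nb < 0 or nb in prev:
                    continue
                lab = labels[nb]
                if lab in terminal_labels:
                    path = [int(nb), int(s)]
                    p = prev[s]
                    while p >= 0:
                        path.append(int(p))
                        p = prev[p]
                    path.reverse()
                    return path
                if lab == through:
                    prev[nb] = s
                    nxt.append(int(nb))
        if not nxt:
            return None
        frontier = sorted(nxt)
    return None


def _shift_out(state: PlaneState, path: list[int], daughter: int,
               new_label: int) -> None:
    """Insert ``daughter`` at path[0]; agents shift toward the terminal,
    which is annexed as tissue with label ``new_label``."""
    ag = state.agents
    labels = state.cs.labels
    term = path[-1]
    labels[term] = new_label
    for i in range(len(path) - 1, 0, -1):
        ag.kind[path[i]] = ag.kind[path[i - 1]]
        ag.clock_cell[path[i]] = ag.clock_cell[path[i - 1]]
        ag.clock_ecm[path[i]] = ag.clock_ecm[path[i - 1]]
    ag.kind[path[0]] = daughter
    ag.clock_cell[path[0]] = 0.0
    ag.clock_ecm[path[0]] = 0.0


def _shift_in(state: PlaneState, path: list[int], freed_label: int) -> None:
    """Remove the agent at path[0]; the chain pulls back toward it and the
    innermost tissue site joins the boundary domain with ``freed_label``."""
    ag = state.agents
    labels = state.cs.labels
    for i in range(1, len(path) - 1):
        ag.kind[path[i - 1]] = ag.kind[path[i]]
        ag.clock_cell[path[i - 1]] = ag.clock_cell[path[i]]
        ag.clock_ecm[path[i - 1]] = ag.clock_ecm[path[i]]
    freed = path[-2]  # innermost tissue site of the chain
    ag.kind[freed] = AGENT_NONE
    labels[freed] = freed_label


def apply_event(state: PlaneState, site: int, event: int,
                daughter_kind: int = AGENT_NONE) -> bool:
    """Apply one mitosis/apoptosis/production/degradation event at ``site``.

    Media events displace the radial chain toward/away from the lumen
    (changing the flow-domain site count by exactly -1/+1); adventitia events
    displace it through the external boundary (lumen unchanged).  Returns
    False when the chain is blocked (event skipped).
    """
    layer = state.cs.labels[site]
    if layer == MEDIA:
        path = _find_chain(state, site, MEDIA, (LUMEN, VOID))
        if path is None:
            return False
        if event in (EV_MITOSIS, EV_PRODUCTION):
            _shift_out(state, path, daughter_kind, MEDIA)
        else:
            _shift_in(state, path, LUMEN)
    elif layer == ADVENTITIA:
        path = _find_chain(state, site, ADVENTITIA, (EXTERIOR,))
        if path is None:
            return False
        if event in (EV_MITOSIS, EV_PRODUCTION):
            _shift_out(state, path, daughter_kind, ADVENTITIA)
        else:
            _shift_in(state, path, EXTERIOR)
    else:
        return False
    return True


# ---------------------------------------------------------------------------
# migration

def find_migration_pairs(state: PlaneState,
                         rates: ABMRates) -> tuple[np.ndarray, np.ndarray]:
    """Migration candidates and free target sites.

    Candidates are SMCs on media sites lining the flow domain whose
    balloon-injury damage is at least the migration threshold; targets are
    current lumen/void sites adjacent to (or part of) the laceration left by
    plaque element deletion.
    """
    cs = state.cs
    flow = state.flow_mask()
    nbrs = cs.grid.neighbors
    lac_open = state.deleted_plaque_mask & flow   # laceration not yet healed
    touches_flow = np.zeros(cs.grid.n_sites, bool)
    touches_lac = np.zeros(cs.grid.n_sites, bool)
    for d in range(6):
        nb = nbrs[:, d]
        ok = nb >= 0
        touches_flow[ok] |= flow[nb[ok]]
        touches_lac[ok] |= lac_open[nb[ok]]
    cand = np.flatnonzero((cs.labels == MEDIA) & (state.agents.kind == SMC)
                          & touches_flow
                          & (state.damage >= rates.migration_threshold))
    targets = np.flatnonzero(flow & (touches_lac | lac_open))
    return cand, targets


def migration_step(state: PlaneState, rates: ABMRates,
                   rng: np.random.Generator) -> int:
    """One migration pass; returns the number of migrations applied.

    Each candidate fires with probability 1/d_min (site-spacing units) toward
    its nearest free target (ties to the lowest site index); its vacated
    lumen-lining site joins the lumen.  The pass halts when candidates or
    free targets run out.
    """
    cand, targets = find_migration_pairs(state, rates)
    if cand.size == 0 or targets.size == 0:
        return 0
    centers = state.cs.grid.centers
    spacing = state.cs.grid.spacing
    free = list(np.sort(targets))
    moved = 0
    for c in np.sort(cand):
        if not free:
            break
        d = np.linalg.norm(centers[free] - centers[c], axis=1) / spacing
        j = int(np.argmin(d))     # ties -> lowest site index (sorted list)
        d_min = max(d[j], 1.0)
        p = min(1.0 / d_min, 1.0)
        u = rng.random()
        if u >= p:
            continue
        tgt = free.pop(j)
        ag = state.agents
        state.cs.labels[tgt] = MEDIA
        ag.kind[tgt] = SMC
        ag.clock_cell[tgt] = ag.clock_cell[c]
        ag.clock_ecm[tgt] = ag.clock_ecm[c]
        ag.kind[c] = AGENT_NONE
        ag.clock_cell[c] = 0.0
        ag.clock_ecm[c] = 0.0
        state.cs.labels[c] = LUMEN
        state.log.add(state.t_hours, c, SMC, EV_MIGRATION, p, u)
        moved += 1
    return moved


# ---------------------------------------------------------------------------
# the 2-hour step

def step(state: PlaneState, din: np.ndarray, wssin: np.ndarray,
         rates: ABMRates, rng: np.random.Generator,
         dt_hours: float = 2.0) -> None:
    """Advance the plane by one time step.

    Order: migration pass (while laceration targets remain); clock advance;
    event draws for agents whose clocks wrapped (division tested on one
    uniform draw, apoptosis on a second draw only if division did not fire;
    production and degradation each on a single draw); events applied in
    randomized site order.
    """
    ag = state.agents
    if not (abs(ag.t_cell / dt_hours - round(ag.t_cell / dt_hours)) < 1e-9
            and abs(ag.t_ecm / dt_hours - round(ag.t_ecm / dt_hours)) < 1e-9):
        raise ValueError("dt must divide both cycle lengths")
    migration_step(state, rates, rng)

    cells = np.isin(ag.kind, _CELL_KINDS)
    ecm = np.isin(ag.kind, _ECM_KINDS)
    ag.clock_cell[cells] += dt_hours
    ag.clock_ecm[cells | ecm] += dt_hours
    wrap_cell = cells & (ag.clock_cell >= ag.t_cell - 1e-9)
    wrap_host = cells & (ag.clock_ecm >= ag.t_ecm - 1e-9)
    wrap_ecm = ecm & (ag.clock_ecm >= ag.t_ecm - 1e-9)
    ag.clock_cell[wrap_cell] -= ag.t_cell
    ag.clock_ecm[wrap_host | wrap_ecm] -= ag.t_ecm

    probs = event_probabilities(ag.kind, state.cs.labels, din, wssin, rates)
    events: list[tuple[int, int, int, float, float]] = []

    sites = np.flatnonzero(wrap_cell)
    if sites.size:
        # one draw per competing pair: division on the lower tail,
        # apoptosis on the upper tail (disjoint; unbiased when the two
        # probabilities are equal, division wins if they overlap)
        u1 = rng.random(sites.size)
        fire_div = u1 < probs["division"][sites]
        fire_apo = ~fire_div & (u1 > 1.0 - probs["apoptosis"][sites])
        for s, f_d, f_a, a in zip(sites, fire_div, fire_apo, u1):
            if f_d:
                events.append((int(s), EV_MITOSIS, int(ag.kind[s]),
                               probs["division"][s], float(a)))
            elif f_a:
                events.append((int(s), EV_APOPTOSIS, int(ag.kind[s]),
                               probs["apoptosis"][s], float(a)))

    hosts = np.flatnonzero(wrap_host)
    if hosts.size:
        u = rng.random(hosts.size)
        for s, uu in zip(hosts[u < probs["production"][hosts]],
                         u[u < probs["production"][hosts]]):
            events.append((int(s), EV_PRODUCTION, int(ag.kind[s]),
                           probs["production"][s], float(uu)))

    degr = np.flatnonzero(wrap_ecm)
    if degr.size:
        u = rng.random(degr.size)
        fired = u < probs["degradation"][degr]
        for s, uu in zip(degr[fired], u[fired]):
            events.append((int(s), EV_DEGRADATION, int(ag.kind[s]),
                           probs["degradation"][s], float(uu)))

    if events:
        order = rng.permutation(len(events))
        for idx in order:
            s, ev, kind, p, u = events[idx]
            if ag.kind[s] != kind:   # displaced by an earlier chain shift
                state.skipped_events += 1
                continue
            if ev == EV_MITOSIS:
                daughter = kind
            elif ev == EV_PRODUCTION:
                daughter = (COLLAGEN if rng.random() < rates.collagen_fraction
                            else ELASTIN)
                if state.cs.labels[s] == ADVENTITIA:
                    daughter = COLLAGEN
            else:
                daughter = AGENT_NONE
            if apply_event(state, s, ev, daughter):
                state.log.add(state.t_hours, s, kind, ev, p, u)
            else:
                state.skipped_events += 1
    state.t_hours += dt_hours


def smooth_interface(state: PlaneState, min_neighbors: int = 6) -> int:
    """Regularize the lumen-media interface once per simulated day.

    A media site with >= ``min_neighbors`` lumen neighbors dissolves into the
    lumen; a lumen site with that many media neighbors is annexed by the
    media (agent kind copied from its lowest-index media neighbor).  The
    default (6) touches only fully enclosed islands/pockets, which keeps the
    operation area-neutral in expectation; lower thresholds bias the
    interface inward.  Void sites are never touched, so laceration recovery
    is driven by the biology only.  Returns the number of relabelled sites.
    """
    cs = state.cs
    ag = state.agents
    nbrs = cs.grid.neighbors
    lum = cs.labels == LUMEN
    med = cs.labels == MEDIA
    n_lum = np.zeros(cs.grid.n_sites, np.int8)
    n_med = np.zeros(cs.grid.n_sites, np.int8)
    for d in range(6):
        nb = nbrs[:, d]
        ok = nb >= 0
        n_lum[ok] += lum[nb[ok]]
        n_med[ok] += med[nb[ok]]
    carve = np.flatnonzero(med & (n_lum >= min_neighbors))
    fill = np.flatnonzero(lum & (n_med >= min_neighbors))
    for s in carve:
        cs.labels[s] = LUMEN
        ag.kind[s] = AGENT_NONE
        state.log.add(state.t_hours, s, AGENT_NONE, EV_SMOOTH_CARVE, 1.0, 0.0)
    for s in fill:
        donors = [nb for nb in nbrs[s] if nb >= 0 and cs.labels[nb] == MEDIA
                  and ag.kind[nb] != AGENT_NONE]
        if not donors:
            continue
        cs.labels[s] = MEDIA
        ag.kind[s] = ag.kind[min(donors)]
        ag.clock_cell[s] = 0.0
        ag.clock_ecm[s] = 0.0
        state.log.add(state.t_hours, s, int(ag.kind[s]), EV_SMOOTH_FILL,
                      1.0, 0.0)
    return len(carve) + len(fill)


# ---------------------------------------------------------------------------
# per-plane time loop

@dataclass
class PlaneRunResult:
    """Daily time series of one plane run plus the final state."""

    plane_id: int
    days: np.ndarray
    lumen_area: np.ndarray        # lumen-site count x site area [mm^2]
    flow_area: np.ndarray         # lumen + void recesses [mm^2]
    contour_area: np.ndarray      # smoothed flow-boundary polygon [mm^2]
    contours: list
    composition: "object"         # pandas.DataFrame, one row per day
    void_fraction: np.ndarray
    state: PlaneState

    @property
    def log(self) -> EventLog:
        return self.state.log


def _cycle_rng(seed: int, cycle: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([int(seed) % (2 ** 31), cycle + 1])))


def init_plane_state(cs: CrossSection, damage_field: np.ndarray,
                     config, seed: int,
                     deleted_plaque_mask: np.ndarray | None = None) -> PlaneState:
    """Build the initial agent state for a (post-deletion) cross-section."""
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([int(seed) % (2 ** 31), 0])))
    agents = initialize_agents(
        cs, rng,
        smc_ecm_ratio=config.smc_ecm_ratio,
        collagen_elastin_ratio=config.collagen_elastin_ratio,
        fib_collagen_ratio=config.fib_collagen_ratio,
        t_cell=config.t_cell_hours, t_ecm=config.t_ecm_hours)
    deleted = cs.labels == VOID
    if deleted_plaque_mask is None:
        deleted_plaque_mask = deleted.copy()
    return PlaneState(cs=cs.copy(), agents=agents,
                      damage=np.asarray(damage_field, float).copy(),
                      deleted_mask=deleted.copy(),
                      deleted_plaque_mask=np.asarray(deleted_plaque_mask,
                                                     bool).copy())


def run_plane(cs: CrossSection, damage_field: np.ndarray,
              wss_source=None, config=None, seed: int = 0,
              duration_days: float | None = None,
              coupling_days: float | None = None,
              deleted_plaque_mask: np.ndarray | None = None,
              initial_state: PlaneState | None = None,
              start_day: float = 0.0) -> PlaneRunResult:
    """Simulate one plane for ``duration_days`` with monthly WSS coupling.

    ``wss_source`` may be a :class:`~restenosim.stimuli.WSSField` (used for
    the first coupling cycle, surrogate afterwards), a callable
    ``f(cs, contour) -> WSSField`` evaluated at every coupling boundary, or
    None for the built-in Poiseuille-style surrogate throughout.  The WSS
    field is frozen within a cycle; its sigmoid transform is re-mapped to the
    moving wall and re-propagated into the media once per simulated day.
    Checkpoints are daily.  Restartable: pass the final state of a previous
    call as ``initial_state`` with the matching ``start_day``.
    """
    import pandas as pd
    from scipy.spatial import cKDTree

    from .geometry import distance_to_lumen, lumen_contour, polygon_area, \
        smooth_contour
    from .params import SimulationConfig
    from .stimuli import wss_sigmoid, wss_surrogate, inflammation, WSSField

    config = config or SimulationConfig()
    duration = config.horizon_days if duration_days is None else duration_days
    coupling = config.coupling_days if coupling_days is None else coupling_days
    dt = config.dt_hours
    steps_per_day = int(round(24.0 / dt))

    if initial_state is None:
        state = init_plane_state(cs, damage_field, config, seed,
                                 deleted_plaque_mask)
        state.t_hours = start_day * 24.0
    else:
        state = initial_state

    frozen_pts = None
    frozen_dvals = None

    def refresh_wss(cycle: int):
        nonlocal frozen_pts, frozen_dvals
        try:
            contour = lumen_contour(state.cs, include_void=True)
        except ValueError:     # lumen closed: no flow, no shear stimulus
            frozen_pts, frozen_dvals = None, None
            return
        if isinstance(wss_source, WSSField) and cycle == 0:
            field = wss_source
        elif callable(wss_source):
            field = wss_source(state.cs, contour)
        else:
            field = wss_surrogate(contour, state.cs,
                                  config.flow_rate_ml_min,
                                  config.viscosity_pa_s)
        frozen_pts = state.cs.grid.centers[field.sites].copy()
        frozen_dvals = np.asarray(wss_sigmoid(field.wss, config.stimulus))

    def current_wssinput() -> np.ndarray:
        from .geometry import wall_sites
        dist_field = distance_to_lumen(state.cs)
        wall = wall_sites(state.cs)
        if wall.size == 0 or frozen_pts is None:
            return np.zeros(state.cs.grid.n_sites)
        tree = cKDTree(frozen_pts)
        _, nearest = tree.query(state.cs.grid.centers[wall])
        dvals = frozen_dvals[nearest]
        from .stimuli import propagate_wssinput
        return propagate_wssinput(dvals, wall, state.cs, config.stimulus,
                                  dist_field)

    def checkpoint(day):
        flow = state.flow_mask()
        lum = int((state.cs.labels == LUMEN).sum())
        area_site = state.cs.grid.site_area
        try:
            c = smooth_contour(lumen_contour(state.cs, include_void=True))
            carea = polygon_area(c)
        except ValueError:
            c, carea = None, float(flow.sum()) * area_site
        med = state.cs.labels == MEDIA
        adv = state.cs.labels == ADVENTITIA
        k = state.agents.kind
        rows.append({
            "day": day,
            "lumen_area": lum * area_site,
            "flow_area": float(flow.sum()) * area_site,
            "contour_area": carea,
            "void_fraction": state.void_fraction(),
            "media_smc": int(((k == SMC) & med).sum()),
            "media_collagen": int(((k == COLLAGEN) & med).sum()),
            "media_elastin": int(((k == ELASTIN) & med).sum()),
            "adv_fibroblast": int(((k == FIBROBLAST) & adv).sum()),
            "adv_collagen": int(((k == COLLAGEN) & adv).sum()),
        })
        contours.append(c)

    rows: list[dict] = []
    contours: list = []
    day0 = int(round(start_day))
    n_days = int(round(duration))
    cycle_len = int(round(coupling))
    rng = None
    cur_cycle = -1

    checkpoint(day0)
    for day in range(day0, day0 + n_days):
        cycle = day // cycle_len if cycle_len > 0 else 0
        if cycle != cur_cycle:
            cur_cycle = cycle
            rng = _cycle_rng(seed, cycle)
            refresh_wss(cycle)
        if int(state.flow_mask().sum()) < 10:   # lumen effectively closed
            checkpoint(day + 1)
            continue
        wssin = current_wssinput()
        for k in range(steps_per_day):
            t_days = day + k * dt / 24.0
            din = state.damage * float(inflammation(t_days, config.stimulus))
            step(state, din, wssin, config.rates, rng, dt)
        checkpoint(day + 1)

    comp = pd.DataFrame(rows)
    return PlaneRunResult(
        plane_id=state.cs.plane_id,
        days=comp["day"].to_numpy(float),
        lumen_area=comp["lumen_area"].to_numpy(),
        flow_area=comp["flow_area"].to_numpy(),
        contour_area=comp["contour_area"].to_numpy(),
        contours=contours,
        composition=comp,
        void_fraction=comp["void_fraction"].to_numpy(),
        state=state,
    )
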