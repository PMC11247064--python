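"""Agent initialization, event rules, growth mechanics, conservation."""
import numpy as np
import pytest

from restenosim.abm import (AGENT_NONE, COLLAGEN, ELASTIN, EV_APOPTOSIS,
                            EV_MIGRATION, EV_MITOSIS, EV_PRODUCTION,
                            FIBROBLAST, PLAQUE_MATRIX, SMC, apply_event,
                            event_probabilities, find_migration_pairs,
                            init_plane_state, initialize_agents,
                            migration_step, run_plane, step)
from restenosim.geometry import (ADVENTITIA, EXTERIOR, LUMEN, MEDIA, PLAQUE,
                                 VOID, CrossSection, build_hex_grid)
from restenosim.params import ABMRates, SimulationConfig


@pytest.fixture(scope="module")
def ring_section():
    """Concentric lumen/media/adventitia disc on a small grid."""
    g = build_hex_grid(80, 80, 0.0375)
    labels = np.full(g.n_sites, EXTERIOR, dtype=np.int8)
    rel = g.centers - g.centers[g.site_index(40, 40)]
    r = np.hypot(rel[:, 0], rel[:, 1])
    labels[r < 1.4] = ADVENTITIA
    labels[r < 1.1] = MEDIA
    labels[r < 0.7] = LUMEN
    return CrossSection(g, labels)


def make_state(cs, damage=None, seed=0, deleted=None):
    cfg = SimulationConfig()
    st = init_plane_state(
        cs, damage if damage is not None else np.zeros(cs.grid.n_sites),
        cfg, seed, deleted)
    return st


class TestInitialization:
    def test_media_composition(self, ring_section):
        rng = np.random.default_rng(0)
        ag = initialize_agents(ring_section, rng)
        media = ring_section.labels == MEDIA
        smc = ((ag.kind == SMC) & media).sum()
        ecm = (np.isin(ag.kind, (COLLAGEN, ELASTIN)) & media).sum()
        assert smc / ecm == pytest.approx(0.72, abs=0.06)

    def test_adventitia_composition(self, ring_section):
        rng = np.random.default_rng(1)
        ag = initialize_agents(ring_section, rng)
        adv = ring_section.labels == ADVENTITIA
        fib = ((ag.kind == FIBROBLAST) & adv).sum()
        col = ((ag.kind == COLLAGEN) & adv).sum()
        assert fib / col == pytest.approx(0.43, abs=0.06)

    def test_degenerate_all_smc(self, ring_section):
        rng = np.random.default_rng(2)
        ag = initialize_agents(ring_section, rng, smc_ecm_ratio=1e9)
        media = ring_section.labels == MEDIA
        assert np.all(ag.kind[media] == SMC)

    def test_clocks_desynchronized_within_cycle(self, ring_section):
        rng = np.random.default_rng(3)
        ag = initialize_agents(ring_section, rng)
        cells = np.isin(ag.kind, (SMC, FIBROBLAST))
        assert ag.clock_cell[cells].min() >= 0
        assert ag.clock_cell[cells].max() < 24.0
        assert ag.clock_cell[cells].std() > 3.0

    def test_one_agent_per_tissue_site(self, ring_section):
        rng = np.random.default_rng(4)
        ag = initialize_agents(ring_section, rng)
        tissue = np.isin(ring_section.labels, (MEDIA, ADVENTITIA, PLAQUE))
        assert np.all(ag.kind[tissue] != AGENT_NONE)
        assert np.all(ag.kind[~tissue] == AGENT_NONE)


class TestEventProbabilities:
    def test_baseline_media_smc(self):
        rates = ABMRates()
        p = event_probabilities(np.array([SMC]), np.array([MEDIA]),
                                np.zeros(1), np.zeros(1), rates)
        assert p["division"][0] == pytest.approx(0.05)
        assert p["apoptosis"][0] == pytest.approx(0.05)
        assert p["production"][0] == pytest.approx(0.008)

    def test_saturated_inputs(self):
        rates = ABMRates()
        p = event_probabilities(np.array([SMC]), np.array([MEDIA]),
                                np.ones(1), np.ones(1), rates)
        assert p["division"][0] == pytest.approx(0.05 + 0.11 + 0.66)

    def test_media_ecm_degradation_with_literature_beta(self):
        rates = ABMRates(beta_med=1.85)
        p = event_probabilities(np.array([COLLAGEN]), np.array([MEDIA]),
                                np.zeros(1), np.zeros(1), rates)
        assert p["degradation"][0] == pytest.approx(0.008 / 1.85)

    def test_adventitia_baseline(self):
        rates = ABMRates()
        p = event_probabilities(np.array([FIBROBLAST, COLLAGEN]),
                                np.array([ADVENTITIA, ADVENTITIA]),
                                np.ones(2), np.ones(2), rates)
        assert p["division"][0] == pytest.approx(0.05)   # stimuli ignored
        assert p["production"][0] == pytest.approx(0.008)
        assert p["degradation"][1] == pytest.approx(0.008 / 2.5)

    def test_plaque_inert(self):
        rates = ABMRates()
        p = event_probabilities(np.array([PLAQUE_MATRIX]), np.array([PLAQUE]),
                                np.ones(1), np.ones(1), rates)
        assert all(v[0] == 0.0 for v in p.values())

    def test_clamped_to_unit_interval(self):
        rates = ABMRates()
        p = event_probabilities(np.array([SMC]), np.array([MEDIA]),
                                np.full(1, 5.0), np.full(1, 5.0), rates)
        assert p["division"][0] == 1.0


class TestApplyEvent:
    def test_media_mitosis_takes_one_lumen_site(self, ring_section):
        state = make_state(ring_section)
        smc_sites = np.flatnonzero((state.agents.kind == SMC)
                                   & (state.cs.labels == MEDIA))
        before = state.cs.count(LUMEN)
        assert apply_event(state, int(smc_sites[0]), EV_MITOSIS, SMC)
        assert state.cs.count(LUMEN) == before - 1

    def test_media_apoptosis_frees_one_lumen_site(self, ring_section):
        state = make_state(ring_section)
        smc_sites = np.flatnonzero((state.agents.kind == SMC)
                                   & (state.cs.labels == MEDIA))
        before = state.cs.count(LUMEN)
        assert apply_event(state, int(smc_sites[0]), EV_APOPTOSIS)
        assert state.cs.count(LUMEN) == before + 1

    def test_mitosis_then_apoptosis_restores_lumen(self, ring_section):
        state = make_state(ring_section)
        smc_sites = np.flatnonzero((state.agents.kind == SMC)
                                   & (state.cs.labels == MEDIA))
        s = int(smc_sites[3])
        before = state.cs.count(LUMEN)
        apply_event(state, s, EV_MITOSIS, SMC)
        apply_event(state, s, EV_APOPTOSIS)
        assert state.cs.count(LUMEN) == before

    def test_adventitia_event_leaves_lumen_unchanged(self, ring_section):
        state = make_state(ring_section)
        fib = np.flatnonzero((state.agents.kind == FIBROBLAST)
                             & (state.cs.labels == ADVENTITIA))
        lumen_before = state.cs.count(LUMEN)
        adv_before = state.cs.count(ADVENTITIA)
        assert apply_event(state, int(fib[0]), EV_PRODUCTION, COLLAGEN)
        assert state.cs.count(LUMEN) == lumen_before
        assert state.cs.count(ADVENTITIA) == adv_before + 1

    def test_site_total_conserved(self, ring_section):
        state = make_state(ring_section)
        smc_sites = np.flatnonzero((state.agents.kind == SMC)
                                   & (state.cs.labels == MEDIA))
        n = state.cs.grid.n_sites
        for s in smc_sites[:5]:
            apply_event(state, int(s), EV_MITOSIS, SMC)
            counts = sum(state.cs.count(l) for l in range(6))
            assert counts == n


class TestMigration:
    @pytest.fixture()
    def lacerated_state(self, ring_section):
        """Ring with a deleted plaque notch and damaged wall SMCs."""
        cs = ring_section.copy()
        g = cs.grid
        rel = g.centers - g.centers[g.site_index(40, 40)]
        r = np.hypot(rel[:, 0], rel[:, 1])
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        notch = (np.abs(theta) < 0.3) & (r >= 0.7) & (r < 0.85)
        cs.labels[notch] = VOID
        damage = np.where((np.abs(theta) < 0.6) & (r >= 0.7) & (r < 0.9),
                          0.9, 0.0)
        state = make_state(cs, damage=damage, seed=5, deleted=notch)
        # ensure SMC candidates exist on the damaged wall
        wall_damaged = np.flatnonzero((cs.labels == MEDIA) & (damage >= 0.8))
        state.agents.kind[wall_damaged[:20]] = SMC
        return state

    def test_no_laceration_no_targets(self, ring_section):
        state = make_state(ring_section)
        cand, targets = find_migration_pairs(state, ABMRates())
        assert targets.size == 0

    def test_low_damage_no_candidates(self, ring_section):
        state = make_state(ring_section)
        state.deleted_plaque_mask[:] = state.cs.labels == VOID
        cand, _ = find_migration_pairs(state, ABMRates())
        assert cand.size == 0

    def test_candidates_and_targets_found(self, lacerated_state):
        cand, targets = find_migration_pairs(lacerated_state, ABMRates())
        assert cand.size > 0
        assert targets.size > 0

    def test_migration_moves_and_conserves(self, lacerated_state):
        state = lacerated_state
        rng = np.random.default_rng(0)
        media_before = state.cs.count(MEDIA)
        flow_before = state.cs.count(LUMEN) + state.cs.count(VOID)
        moved = migration_step(state, ABMRates(), rng)
        assert moved > 0
        assert state.cs.count(MEDIA) == media_before
        assert state.cs.count(LUMEN) + state.cs.count(VOID) == flow_before
        assert len(state.log) == moved
        assert all(e == EV_MIGRATION for e in state.log.event)

    def test_adjacent_candidate_always_fires(self, ring_section):
        """A candidate next to a free target (d_min = 1) migrates surely."""
        state = make_state(ring_section)
        g = state.cs.grid
        smc_wall = np.flatnonzero((state.cs.labels == MEDIA)
                                  & (state.agents.kind == SMC))
        s = next(int(x) for x in smc_wall
                 if any(nb >= 0 and state.cs.labels[nb] == LUMEN
                        for nb in g.neighbors[x]))
        target = next(int(nb) for nb in g.neighbors[s]
                      if nb >= 0 and state.cs.labels[nb] == LUMEN)
        state.damage[s] = 0.95
        state.deleted_plaque_mask[:] = False
        state.deleted_plaque_mask[target] = True
        moved = migration_step(state, ABMRates(), np.random.default_rng(1))
        assert moved >= 1
        assert state.cs.labels[target] == MEDIA
        assert state.agents.kind[target] == SMC


class TestStep:
    def test_zero_probabilities_only_advance_clocks(self, ring_section):
        rates = ABMRates(alpha1=0.0, alpha2=0.0, alpha3=0.0, alpha4=0.0,
                        alpha5=0.0, alpha6=0.0)
        state = make_state(ring_section, seed=6)
        kinds_before = state.agents.kind.copy()
        clocks_before = state.agents.clock_cell.copy()
        zero = np.zeros(state.cs.grid.n_sites)
        step(state, zero, zero, rates, np.random.default_rng(0), 2.0)
        assert np.array_equal(state.agents.kind, kinds_before)
        cells = np.isin(state.agents.kind, (SMC, FIBROBLAST))
        assert np.all(state.agents.clock_cell[cells]
                      != clocks_before[cells])

    def test_certain_division_once_per_cycle(self, ring_section):
        """p_division = 1, p_apoptosis = 0: every SMC divides once per 24 h."""
        rates = ABMRates(alpha1=0.0, alpha2=0.0, alpha3=1.0, alpha4=0.0,
                         alpha5=0.0, alpha6=0.0)
        state = make_state(ring_section, seed=7)
        n_smc = int(((state.agents.kind == SMC)
                     & (state.cs.labels == MEDIA)).sum())
        din = np.ones(state.cs.grid.n_sites)
        zero = np.zeros_like(din)
        rng = np.random.default_rng(0)
        for _ in range(12):   # one full cell cycle
            step(state, din, zero, rates, rng, 2.0)
        mitoses = sum(1 for e in state.log.event if e == EV_MITOSIS)
        skipped = state.skipped_events
        assert mitoses + skipped == pytest.approx(n_smc, rel=0.02)

    def test_dt_must_divide_cycles(self, ring_section):
        state = make_state(ring_section)
        zero = np.zeros(state.cs.grid.n_sites)
        with pytest.raises(ValueError):
            step(state, zero, zero, ABMRates(), np.random.default_rng(0), 5.0)


class TestRunPlaneContracts:
    def test_fixed_seed_reproducible(self, ring_section):
        cfg = SimulationConfig(n_rows=80, n_cols=80)
        zero = np.zeros(ring_section.grid.n_sites)
        a = run_plane(ring_section, zero, config=cfg, seed=9,
                      duration_days=3)
        b = run_plane(ring_section, zero, config=cfg, seed=9,
                      duration_days=3)
        assert a.state.log.signature() == b.state.log.signature()
        assert np.array_equal(a.state.cs.labels, b.state.cs.labels)

    def test_site_conservation_and_unit_lumen_steps(self, ring_section):
        cfg = SimulationConfig(n_rows=80, n_cols=80)
        zero = np.zeros(ring_section.grid.n_sites)
        res = run_plane(ring_section, zero, config=cfg, seed=4,
                        duration_days=3)
        state = res.state
        assert sum(state.cs.count(l) for l in range(6)) == \
            state.cs.grid.n_sites
        # replay the event log: media events move the flow count by -/+1,
        # adventitia events by 0
        df = state.log.to_dataframe()
        flow0 = int(((ring_section.labels == LUMEN)
                     | (ring_section.labels == VOID)).sum())
        delta = 0
        for _, row in df.iterrows():
            site = row["site"]
            if ring_section.labels[site] in (MEDIA, LUMEN, VOID):
                if row["event"] == "mitosis" or row["event"] == \
                        "ecm_production":
                    delta -= 1
                elif row["event"] in ("apoptosis", "ecm_degradation"):
                    delta += 1
        flow_now = int(state.flow_mask().sum())
        assert flow_now == flow0 + delta
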