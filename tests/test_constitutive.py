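"""Constitutive library: invariants, energies, damage evolution, deletion."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from restenosim import params
from restenosim.constitutive import (DamageState, DeformationState,
                                     damage_norm, damaged_sef,
                                     element_deletion, evolve_damage,
                                     fiber_energy, fiber_strains,
                                     isochoric_invariants, matrix_energy,
                                     plaque_damage_1d, reduction_factor,
                                     smoothstep_damage, undamaged_sef,
                                     uniaxial_stretch_state)


def equibiaxial_state(lam):
    C = np.diag([lam ** 2, lam ** 2, lam ** -4])
    return DeformationState.from_directions(C, [1, 0, 0], [0, 1, 0])


class TestInvariants:
    def test_identity(self):
        inv = isochoric_invariants(uniaxial_stretch_state(1.0))
        assert (inv.I1bar, inv.I4bar, inv.I6bar) == pytest.approx((3, 1, 1))

    def test_uniaxial_circumferential(self):
        inv = isochoric_invariants(uniaxial_stretch_state(1.2))
        assert inv.I1bar == pytest.approx(1.44 + 2 / 1.2)
        assert inv.I4bar == pytest.approx(1.44)
        assert inv.I6bar == pytest.approx(1 / 1.2)

    def test_equibiaxial(self):
        inv = isochoric_invariants(equibiaxial_state(1.1))
        assert inv.I1bar == pytest.approx(2 * 1.21 + 1.1 ** -4)

    def test_non_isochoric_rejected(self):
        with pytest.raises(ValueError):
            DeformationState.from_directions(np.diag([2.0, 1.0, 1.0]),
                                             [1, 0, 0], [0, 1, 0])


class TestFiberStrains:
    def test_reference_is_strain_free(self):
        from restenosim.constitutive import Invariants
        assert fiber_strains(Invariants(3, 1, 1), 0.17) == (0, 0)

    def test_aligned_families(self):
        from restenosim.constitutive import Invariants
        e4, e6 = fiber_strains(Invariants(3.1067, 1.44, 0.8333), 0.0)
        assert e4 == pytest.approx(0.44)
        assert e6 == pytest.approx(-0.1667, abs=1e-4)

    def test_isotropic_dispersion_limit(self):
        from restenosim.constitutive import Invariants
        inv = Invariants(3.2, 1.7, 0.6)
        e4, e6 = fiber_strains(inv, 1 / 3)
        assert e4 == pytest.approx((3.2 - 3) / 3)
        assert e6 == pytest.approx((3.2 - 3) / 3)

    def test_kappa_out_of_range(self):
        from restenosim.constitutive import Invariants
        with pytest.raises(ValueError):
            fiber_strains(Invariants(3, 1, 1), 0.5)


class TestEnergies:
    def test_matrix_energy_examples(self):
        assert matrix_energy(3.0, 0.183) == 0.0
        assert matrix_energy(3.5, 0.183) == pytest.approx(0.0915)
        assert matrix_energy(10.0, 0.0) == 0.0

    def test_fiber_energy_media(self):
        w1, w2 = fiber_energy(0.44, -0.2, params.MEDIA)
        assert w1 == pytest.approx(
            0.080 / (2 * 0.253) * (np.exp(0.253 * 0.44 ** 2) - 1), rel=1e-9)
        assert w2 == 0.0   # compressed family stores nothing

    def test_fiber_energy_quadratic_limit(self):
        p = params.LayerMaterialParams(c10=0.1, k1=0.2, k2=0.0, k3=0.2,
                                       k4=0.0)
        w1, _ = fiber_energy(0.3, 0.0, p)
        assert w1 == pytest.approx(0.5 * 0.2 * 0.09)

    def test_damage_norm(self):
        assert damage_norm(0.0) == 0.0
        assert damage_norm(0.0915) == pytest.approx(0.4278, abs=1e-4)
        assert damage_norm(0.5 * 0.497 ** 2) == pytest.approx(0.497)
        with pytest.raises(ValueError):
            damage_norm(-1e-3)


class TestDamageFunctions:
    def test_reduction_factor(self):
        assert reduction_factor(0.3, 0.497, 0.808) == 0.0
        assert reduction_factor(0.808, 0.497, 0.808) == 1.0
        assert reduction_factor(0.6525, 0.497, 0.808) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            reduction_factor(0.5, 0.8, 0.8)

    def test_smoothstep_endpoints_and_midpoint(self):
        assert smoothstep_damage(0.0) == 0.0
        assert smoothstep_damage(1.0) == 1.0
        assert smoothstep_damage(0.5) == pytest.approx(0.5)

    def test_smoothstep_flat_at_onset(self):
        eps = 1e-4
        assert smoothstep_damage(eps) / eps < 1e-6
        assert (1 - smoothstep_damage(1 - eps)) / eps < 1e-6

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_smoothstep_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert smoothstep_damage(lo) <= smoothstep_damage(hi) + 1e-12


class TestDamagedSEF:
    def test_no_damage_limit(self):
        state = uniaxial_stretch_state(1.3)
        total = damaged_sef(state, params.MEDIA, DamageState())
        assert total == pytest.approx(sum(undamaged_sef(state, params.MEDIA)))

    def test_full_damage(self):
        state = uniaxial_stretch_state(1.3)
        dmg = DamageState(d_m=1, d_fA1=1, d_fA2=1)
        assert damaged_sef(state, params.MEDIA, dmg) == pytest.approx(0.0)

    def test_partial_matrix_damage(self):
        p = params.LayerMaterialParams(c10=0.183, k1=0, k2=0.1, k3=0, k4=0.1)
        state = uniaxial_stretch_state(1.4)  # fibers off: matrix term only
        inv = isochoric_invariants(state)
        got = damaged_sef(state, p, DamageState(d_m=0.5))
        assert got == pytest.approx(0.5 * matrix_energy(inv.I1bar, 0.183))

    @given(st.floats(1.0, 2.5), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_damaged_never_exceeds_undamaged(self, lam, dm, d1, d2):
        state = uniaxial_stretch_state(lam)
        dmg = DamageState(d_m=dm, d_fA1=d1, d_fA2=d2)
        full = sum(undamaged_sef(state, params.MEDIA))
        assert damaged_sef(state, params.MEDIA, dmg) <= full + 1e-12


class TestEvolveDamage:
    def test_identity_history_stays_pristine(self):
        hist = [uniaxial_stretch_state(1.0)] * 5
        traj = evolve_damage(hist, params.MEDIA)
        assert all(d.d_m == 0 and d.d_fA1 == 0 and d.d_fA2 == 0
                   for d in traj)

    def test_ramp_crosses_onset_to_failure(self):
        lams = np.linspace(1.0, 2.6, 40)
        traj = evolve_damage([uniaxial_stretch_state(l) for l in lams],
                             params.MEDIA)
        dm = [t.d_m for t in traj]
        assert dm[0] == 0.0
        assert dm[-1] == 1.0
        assert all(b >= a for a, b in zip(dm, dm[1:]))

    def test_unloading_keeps_peak_damage(self):
        lams = list(np.linspace(1.0, 2.0, 15)) + list(np.linspace(2.0, 1.0, 15))
        traj = evolve_damage([uniaxial_stretch_state(l) for l in lams],
                             params.MEDIA)
        assert traj[-1].d_m == pytest.approx(traj[14].d_m)
        assert traj[-1].d_fA1 == pytest.approx(traj[14].d_fA1)

    def test_empty_history(self):
        assert evolve_damage([], params.MEDIA) == []

    def test_adventitia_never_damages(self):
        traj = evolve_damage([uniaxial_stretch_state(2.5)], params.ADVENTITIA)
        assert traj[-1].d_m == 0.0 and traj[-1].d_fA1 == 0.0

    @given(st.lists(st.floats(0.8, 2.8), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_irreversibility_over_random_histories(self, lams):
        traj = evolve_damage([uniaxial_stretch_state(l) for l in lams],
                             params.MEDIA)
        for field in ("d_m", "d_fA1", "d_fA2", "ximax_m", "ximax_fA1"):
            vals = [getattr(t, field) for t in traj]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestIsotropizationLimit:
    def test_kappa_third_direction_independent(self):
        """With full dispersion the fiber energy ignores fiber directions."""
        p = params.LayerMaterialParams(c10=0.1, k1=0.08, k2=0.25, k3=0.08,
                                       k4=0.25, kappa=1 / 3)
        state_a = uniaxial_stretch_state(1.4, axis=0)
        state_b = uniaxial_stretch_state(1.4, axis=2)
        _, wa1, wa2 = undamaged_sef(state_a, p)
        _, wb1, wb2 = undamaged_sef(state_b, p)
        assert wa1 == pytest.approx(wb1)
        assert wa2 == pytest.approx(wb2)


class TestPlaqueDamage:
    def test_no_yield_no_damage(self):
        assert plaque_damage_1d([1.0] * 10, params.PLAQUE) == 0.0

    def test_below_yield_stretch(self):
        assert plaque_damage_1d([1.0, 1.74], params.PLAQUE) == 0.0

    def test_far_beyond_yield_saturates(self):
        d = plaque_damage_1d([1.0, 60.0], params.PLAQUE, char_length=5.0)
        assert d == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_peak_stretch(self):
        ds = [plaque_damage_1d([1.0, l], params.PLAQUE, char_length=0.3)
              for l in (1.9, 2.3, 2.8, 3.5)]
        assert all(b >= a for a, b in zip(ds, ds[1:]))

    def test_invalid_stretch(self):
        with pytest.raises(ValueError):
            plaque_damage_1d([1.0, -0.5], params.PLAQUE)


class TestElementDeletion:
    def test_threshold_examples(self):
        mask = element_deletion(np.array([0.79, 0.80, 0.95]))
        assert mask.tolist() == [False, True, True]

    def test_degenerate_fields(self):
        assert not element_deletion(np.zeros(5)).any()
        assert element_deletion(np.ones(5)).all()

    @given(st.floats(0.1, 0.9), st.floats(0.1, 0.9))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(0)
        field = rng.random(50)
        lo, hi = sorted((t1, t2))
        assert set(np.flatnonzero(element_deletion(field, hi))) <= \
            set(np.flatnonzero(element_deletion(field, lo)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            element_deletion(np.array([1.2]))


class TestLayerParams:
    def test_table_values_loaded(self):
        assert params.MEDIA.c10 == 0.183
        assert params.MEDIA.XiF_fA2 == 2.179
        assert params.ADVENTITIA.Xi0_m is None
        assert params.PLAQUE.lambda_y == 1.75

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            params.LayerMaterialParams(c10=0.1, k1=0.1, k2=0.1, k3=0.1,
                                       k4=0.1, Xi0_m=0.8, XiF_m=0.5)
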