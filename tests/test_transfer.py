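"""Placental transfer model: schedules, kinetics, conservation, outcomes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placentig import transfer as tr
from placentig.parameters import TABLE1_RANGES, kon_from_kd, table1_midpoint
from placentig.transfer import (
    FcRSchedule,
    ReceptorVariant,
    fcr_schedule_value,
    fetal_maternal_ratio,
    placental_rhs,
    simulate_transfer,
    subclass_entropy,
    transfer_hierarchy,
)


class TestFcRSchedule:
    @pytest.mark.parametrize("t, expected", [
        (40.0, 3.3e-5),          # endpoint anchored at term
        (20.0, 3.3e-5 / 4),      # parabola at the midpoint
        (0.0, 0.0),              # zero at conception
        (41.5, 3.3e-5),          # clamped beyond term
    ])
    def test_parabolic_values(self, t, expected):
        sched = FcRSchedule(endpoint=3.3e-5)
        assert fcr_schedule_value(t, sched) == pytest.approx(expected)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            fcr_schedule_value(-1.0, FcRSchedule(endpoint=1e-5))

    @given(st.floats(0.0, 40.0), st.floats(0.0, 40.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_non_decreasing(self, t1, t2):
        sched = FcRSchedule(endpoint=2.5e-6)
        lo, hi = sorted([t1, t2])
        assert sched.value(lo) <= sched.value(hi) + 1e-30


class TestBindingRates:
    @pytest.mark.parametrize("kd, koff, expected", [
        (1.25e-8, 0.15, 1.2e7),   # FcRn-IgG1
        (5e-8, 0.15, 3e6),        # FcRn-IgG4
        (0.15, 0.15, 1.0),
    ])
    def test_kon_from_kd(self, kd, koff, expected):
        assert kon_from_kd(kd, koff) == pytest.approx(expected)

    @pytest.mark.parametrize("kd, koff", [(0, 0.15), (-1e-8, 0.15), (1e-8, 0)])
    def test_rejects_non_positive(self, kd, koff):
        with pytest.raises(ValueError):
            kon_from_kd(kd, koff)

    def test_table1_kon_recoverable(self, midpoint_params):
        np.testing.assert_allclose(
            midpoint_params.kon_fcrn,
            [1.2e7, 7.5e6, 0.15 / 3.3e-8, 3e6], rtol=1e-12)


class TestRhs:
    def test_empty_placenta_sees_only_uptake(self, midpoint_params):
        """From an all-zero state the only active flux is maternal->STB uptake."""
        d = placental_rhs(0.0, np.zeros(tr.N_STATE * 4), midpoint_params)
        d = d.reshape(tr.N_STATE, 4)
        p = midpoint_params
        np.testing.assert_allclose(d[0], p.k_up * p.igg0 / p.v_stb, rtol=1e-12)
        assert np.all(d[1:] == 0)

    def test_mass_balance_flux_audit(self, midpoint_params, rng):
        """Total IgG moles change only via maternal influx, lysosomal
        degradation, and fetal decay — audited against independently summed
        source/sink terms at random interior states."""
        p = midpoint_params
        for _ in range(5):
            y = rng.uniform(0, 1e-6, size=(tr.N_STATE, 4))
            y[1] *= 1e-2  # keep complexes below the scheduled receptor totals
            y[4] *= 1e-3
            y[5] *= 1e-2
            d = placental_rhs(20.0, y.ravel(), p).reshape(tr.N_STATE, 4)
            vols = np.array([p.v_stb, p.v_stb, p.v_str, p.v_ec, p.v_ec,
                             p.v_ec, p.v_f])
            total_mole_rate = (d * vols[:, None]).sum()
            influx = (p.k_up * p.igg0).sum()
            degradation = (p.k_deg * (y[0] + y[3])).sum()
            decay = (p.delta_ab * y[6] * p.v_f).sum()
            assert total_mole_rate == pytest.approx(
                influx - degradation - decay, rel=1e-9)

    def test_receptor_pools_conserved_along_trajectory(self, midpoint_params,
                                                       term_simulation):
        """Free + bound receptor equals the scheduled total at all times (the
        free pool is defined by subtraction, so bound may never exceed the
        schedule)."""
        sched = tr.receptor_schedules(midpoint_params)
        res = term_simulation
        for key, state in [("fcrn_stb", "stb_complex"),
                           ("fcrn_ec", "ec_fcrn_complex"),
                           ("fcgr2b_ec", "ec_fcgr2b_complex")]:
            total = sched[key].value(res.t)
            bound = res.state(state).sum(axis=0)
            assert np.all(bound <= total * (1 + 1e-9) + 1e-15)

    def test_negative_state_rejected(self, midpoint_params):
        y = np.zeros(tr.N_STATE * 4)
        y[0] = -1e-3
        with pytest.raises(ValueError):
            placental_rhs(1.0, y, midpoint_params)


class TestSimulation:
    def test_trajectory_non_negative(self, term_simulation):
        assert term_simulation.states.min() >= -1e-12

    def test_subclass_hierarchy_at_term(self, term_simulation):
        """Mid-range parameters predict IgG1 > IgG3 > IgG4 > IgG2 transfer."""
        assert transfer_hierarchy(term_simulation) == \
            ("IgG1", "IgG3", "IgG4", "IgG2")

    def test_no_uptake_no_fetal_igg(self, midpoint_params):
        res = simulate_transfer(midpoint_params.replace(k_up=1e-300))
        assert np.all(res.fetal <= 1e-16)

    def test_no_ec_receptors_no_fetal_igg(self, midpoint_params):
        res = simulate_transfer(
            midpoint_params.replace(fcrn_ec_end=0.0, fcgr2b_ec_end=0.0))
        assert np.all(res.fetal <= 1e-16)

    def test_variant_overrides_endpoints(self, midpoint_params):
        p1 = tr.apply_variant(midpoint_params, ReceptorVariant.EC_FCRN_ONLY)
        p2 = tr.apply_variant(midpoint_params, ReceptorVariant.EC_FCGR2B_ONLY)
        assert p1.fcgr2b_ec_end == 0 and p1.fcrn_ec_end > 0
        assert p2.fcrn_ec_end == 0 and p2.fcgr2b_ec_end > 0

    def test_monotone_dilution_in_fetal_volume(self, midpoint_params,
                                               term_simulation):
        """Increasing fetal blood volume strictly decreases term concentration."""
        bigger = simulate_transfer(midpoint_params.replace(
            v_f=midpoint_params.v_f * 1.3))
        assert np.all(bigger.fetal_at(40.0) < term_simulation.fetal_at(40.0))

    def test_invalid_span_rejected(self, midpoint_params):
        with pytest.raises(ValueError):
            simulate_transfer(midpoint_params, t_span=(0.0, 50.0))

    def test_rk4_oracle_agreement(self, midpoint_params, rng):
        """Adaptive stiff solution matches a fixed-step RK4 integration."""
        lo = np.array([TABLE1_RANGES[k][0] for k in TABLE1_RANGES])
        hi = np.array([TABLE1_RANGES[k][1] for k in TABLE1_RANGES])
        draw = lo + rng.uniform(size=11) * (hi - lo)
        p = midpoint_params.with_optimized(draw)
        res = simulate_transfer(p, t_span=(0.0, 10.0))
        y = _rk4(p, t_end=10.0, dt=1e-3)
        fetal = y.reshape(tr.N_STATE, 4)[6]
        np.testing.assert_allclose(res.fetal_at(10.0), fetal, rtol=1e-3)


def _rk4(p, t_end, dt):
    sp = tr.bulk_species(p)
    sch = tr.receptor_schedules(p)
    f = tr._rhs
    y = np.zeros(tr.N_STATE * 4)
    t = 0.0
    for _ in range(int(round(t_end / dt))):
        k1 = f(t, y, p, sp, sch)
        k2 = f(t + dt / 2, y + dt / 2 * k1, p, sp, sch)
        k3 = f(t + dt / 2, y + dt / 2 * k2, p, sp, sch)
        k4 = f(t + dt, y + dt * k3, p, sp, sch)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y


class TestOutcomes:
    def test_ratio_unity_when_fetal_equals_maternal(self, midpoint_params):
        res = _constant_result(midpoint_params, midpoint_params.igg0)
        np.testing.assert_allclose(fetal_maternal_ratio(res, 40.0), 1.0)

    def test_ratio_zero_at_conception(self, term_simulation):
        np.testing.assert_allclose(fetal_maternal_ratio(term_simulation, 0.0),
                                   0.0, atol=1e-15)

    def test_igg1_exceeds_igg2_ratio_at_term(self, term_simulation):
        r = fetal_maternal_ratio(term_simulation, 40.0)
        assert r[0] > r[1]

    def test_ratio_rejects_zero_maternal(self, midpoint_params):
        res = _constant_result(midpoint_params, np.zeros(4),
                               maternal=np.zeros(4))
        with pytest.raises(ZeroDivisionError):
            fetal_maternal_ratio(res, 40.0)

    @pytest.mark.parametrize("vec, expected", [
        ((1.0, 1.0, 1.0, 1.0), np.log(4)),
        ((5.0, 0.0, 0.0, 0.0), 0.0),
        ((2.0, 2.0, 0.0, 0.0), np.log(2)),
    ])
    def test_entropy_values(self, vec, expected):
        assert subclass_entropy(np.array(vec)) == pytest.approx(expected)

    def test_entropy_rejects_all_zero(self):
        with pytest.raises(ValueError):
            subclass_entropy(np.zeros(4))

    def test_entropy_scale_invariant(self):
        v = np.array([3.0, 1.0, 0.5, 0.1])
        assert subclass_entropy(v) == pytest.approx(subclass_entropy(10 * v))

    def test_tidy_frame_schema(self, term_simulation):
        frame = term_simulation.to_frame()
        assert set(frame.columns) == {"time_weeks", "compartment", "subclass",
                                      "concentration_M"}
        assert frame["subclass"].nunique() == 4
        assert frame["compartment"].nunique() == tr.N_STATE


def _constant_result(params, fetal_levels, maternal=None):
    t = np.linspace(0.0, 40.0, 5)
    states = np.zeros((tr.N_STATE, 4, len(t)))
    states[tr.STATE_NAMES.index("fetal"), :, :] = np.asarray(fetal_levels)[:, None]
    mat = params.igg0 if maternal is None else np.asarray(maternal)
    return tr.SimulationResult(t=t, states=states,
                               labels=("IgG1", "IgG2", "IgG3", "IgG4"),
                               params=params, maternal=lambda _: mat)
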