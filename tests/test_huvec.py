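"""In vitro HUVEC transcytosis: conservation, saturation, competition, QC."""

import numpy as np
import pytest

from placentig.huvec import (
    closed_form_complex,
    competition_curve,
    find_saturation_point,
    huvec_rhs,
    monolayer_permeability,
    simulate_transwell,
)
from placentig.parameters import HuvecParameters, mg_ml_to_molar


class TestRhs:
    def test_receptor_conservation_identity(self, huvec_params, rng):
        """d/dt (FcRn + C1 + C4) = 0 for any state (receptor is returned on
        both dissociation and transcytosis)."""
        for _ in range(10):
            y = rng.uniform(0, 2e-6, size=7)
            d = huvec_rhs(0.0, y, huvec_params)
            assert d[2] + d[3] + d[4] == pytest.approx(0.0, abs=1e-18)

    def test_ligand_conservation_identity(self, huvec_params, rng):
        """d/dt (IgG1 + C1 + IgG1T) = 0 and the IgG4 analogue."""
        for _ in range(10):
            y = rng.uniform(0, 2e-6, size=7)
            d = huvec_rhs(0.0, y, huvec_params)
            assert d[0] + d[3] + d[5] == pytest.approx(0.0, abs=1e-18)
            assert d[1] + d[4] + d[6] == pytest.approx(0.0, abs=1e-18)

    def test_conservation_along_trajectory(self, huvec_params):
        res = simulate_transwell(huvec_params, igg1_apical=0.1,
                                 igg4_apical=0.2)
        fcrn_total = res.states[2] + res.states[3] + res.states[4]
        np.testing.assert_allclose(fcrn_total, huvec_params.fcrn0, rtol=1e-9)
        igg4_total = res.states[1] + res.states[4] + res.states[6]
        np.testing.assert_allclose(igg4_total, mg_ml_to_molar(0.2), rtol=1e-9)

    def test_rk4_oracle_agreement(self, huvec_params):
        y0 = np.zeros(7)
        y0[1] = mg_ml_to_molar(0.3)
        y0[2] = huvec_params.fcrn0
        y, t, dt = y0.copy(), 0.0, 0.01
        for _ in range(int(120 / dt)):
            k1 = huvec_rhs(t, y, huvec_params)
            k2 = huvec_rhs(t + dt / 2, y + dt / 2 * k1, huvec_params)
            k3 = huvec_rhs(t + dt / 2, y + dt / 2 * k2, huvec_params)
            k4 = huvec_rhs(t + dt, y + dt * k3, huvec_params)
            y += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
        res = simulate_transwell(huvec_params, igg4_apical=0.3)
        np.testing.assert_allclose(res.at(120.0)[6], y[6], rtol=1e-3)


class TestTranswell:
    def test_zero_dose_zero_transcytosis(self, huvec_params):
        res = simulate_transwell(huvec_params)
        assert np.all(res.states[5:] == 0)

    def test_transcytosed_monotone_in_time(self, huvec_params):
        res = simulate_transwell(huvec_params, igg4_apical=0.25)
        assert np.all(np.diff(res.state("igg4_t")) >= -1e-18)

    def test_negative_dose_rejected(self, huvec_params):
        with pytest.raises(ValueError):
            simulate_transwell(huvec_params, igg4_apical=-0.1)


class TestClosedForm:
    def test_single_ligand_langmuir_limit(self, huvec_params):
        igg4 = 1e-7
        _, c4 = closed_form_complex(0.0, igg4, huvec_params)
        r = igg4 / huvec_params.kd_igg4
        assert c4 == pytest.approx(huvec_params.fcrn0 * r / (1 + r))

    def test_symmetric_when_affinities_equal(self, huvec_params):
        p = huvec_params.replace(kd_igg1=5e-8)
        c1, c4 = closed_form_complex(2e-7, 2e-7, p)
        assert c1 == pytest.approx(c4)

    def test_matches_quasi_steady_ode(self, huvec_params):
        """With transcytosis nearly off, the long-time ODE complex matches
        the equilibrium competition solution to <1%.  Free (not total) ligand
        enters the closed form."""
        p = huvec_params.replace(ktrans=1e-12)
        res = simulate_transwell(p, igg1_apical=0.05, igg4_apical=0.1,
                                 duration=5000, t_eval=[0, 5000])
        state = res.at(5000)
        c1, c4 = closed_form_complex(state[0], state[1], p)
        assert state[3] == pytest.approx(c1, rel=0.01)
        assert state[4] == pytest.approx(c4, rel=0.01)

    def test_c4_strictly_decreasing_in_igg1(self, huvec_params):
        igg1 = np.linspace(0, 3e-6, 20)
        c4 = [closed_form_complex(v, 1.3e-6, huvec_params)[1] for v in igg1]
        assert np.all(np.diff(c4) < 0)

    def test_igg1_excess_extinguishes_c4(self, huvec_params):
        _, c4 = closed_form_complex(1.0, 1.3e-6, huvec_params)
        assert c4 < 1e-3 * huvec_params.fcrn0


class TestSaturation:
    def test_saturation_near_receptor_stoichiometry(self, huvec_params):
        """Transcytosis saturates where apical IgG4 matches the FcRn pool:
        2200 nM, i.e. 0.33 mg/ml at 150 kDa."""
        sat = find_saturation_point(huvec_params)
        assert sat == pytest.approx(0.33, abs=0.05)
        assert mg_ml_to_molar(sat) == pytest.approx(huvec_params.fcrn0,
                                                    rel=0.1)

    def test_doubling_receptor_doubles_saturation_dose(self, huvec_params):
        sat1 = find_saturation_point(huvec_params)
        sat2 = find_saturation_point(
            huvec_params.replace(fcrn0=2 * huvec_params.fcrn0),
            dose_grid=np.arange(0.01, 2.01, 0.01))
        assert sat2 == pytest.approx(2 * sat1, rel=0.1)

    def test_missing_knee_reported(self, huvec_params):
        with pytest.raises(RuntimeError):
            find_saturation_point(huvec_params,
                                  dose_grid=np.arange(0.001, 0.02, 0.001))


class TestCompetition:
    @pytest.fixture(scope="class")
    def curve(self, huvec_params):
        return competition_curve(huvec_params)

    def test_igg1_free_point_matches_single_ligand(self, huvec_params, curve):
        solo = simulate_transwell(huvec_params, igg4_apical=0.2)
        assert curve["igg4_t_mg_ml"].iloc[0] == pytest.approx(
            solo.transcytosed_mg_ml(120.0)[1], rel=1e-9)

    def test_decline_requires_total_beyond_saturation(self, huvec_params,
                                                      curve):
        """IgG4 transcytosis is barely touched while IgG4+IgG1 stays below
        the receptor pool, and clearly suppressed once well beyond it."""
        base = curve["igg4_t_mg_ml"].iloc[0]
        below = curve[curve["igg1_mg_ml"] <= 0.06]      # total <= 0.26
        beyond = curve[curve["igg1_mg_ml"] >= 0.25]     # total >= 0.45
        assert np.all(below["igg4_t_mg_ml"] >= 0.95 * base)
        assert np.all(beyond["igg4_t_mg_ml"] <= 0.80 * base)

    def test_onset_flagged_before_saturation_total(self, curve):
        onset = curve.attrs["onset_igg1_mg_ml"]
        assert onset is not None
        assert 0.05 <= onset <= 0.13


class TestPermeability:
    def test_blank_equals_huvec_gives_100(self):
        perm, _ = monolayer_permeability(np.array([10.0]), 10.0)
        assert perm[0] == pytest.approx(100.0)

    def test_no_signal_gives_zero(self):
        perm, _ = monolayer_permeability(np.array([0.0]), 5.0)
        assert perm[0] == 0.0

    def test_three_sd_rule_flags_outlier(self):
        """Batch {10, 11, 9, 50}%: only the 50% sample is excluded."""
        perm, excluded = monolayer_permeability(
            np.array([10.0, 11.0, 9.0, 50.0]), 100.0)
        np.testing.assert_allclose(perm, [10, 11, 9, 50])
        assert list(excluded) == [False, False, False, True]

    def test_rejects_non_positive_blank(self):
        with pytest.raises(ValueError):
            monolayer_permeability(np.array([1.0]), 0.0)
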