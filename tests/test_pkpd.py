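"""Effect-site link and Emax concentration-occupancy models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petkin import synthetic as syn
from petkin.pkpd import (
    EffectSiteEmaxModel,
    EmaxModel,
    effect_site_conc,
    emax_occupancy,
)


def oral_cp(dose=300.0, ka=1.5, ke=0.15, v=2000.0, t=None):
    t = np.arange(0.0, 30.001, 0.25) if t is None else t
    A = 1000.0 * dose * ka / (v * (ka - ke))
    return t, A * (np.exp(-ke * t) - np.exp(-ka * t))


class TestEffectSite:
    def test_constant_input_closed_form(self):
        t = np.linspace(0, 12, 97)
        cp = np.full_like(t, 7.0)
        for ke0 in (0.1, 0.5, 2.0):
            ce = effect_site_conc(t, cp, ke0)
            expected = 7.0 * (1.0 - np.exp(-ke0 * t))
            assert np.allclose(ce, expected, rtol=1e-3, atol=1e-12)

    def test_fast_equilibration_tracks_plasma(self):
        t, cp = oral_cp()
        ce = effect_site_conc(t, cp, ke0=200.0)
        late = t > 0.5
        assert np.allclose(ce[late], cp[late], rtol=0.02)

    def test_matches_stiff_ode_oracle(self):
        """Independent oracle: scipy's implicit solver on the same ODE."""
        from scipy.integrate import solve_ivp

        t, cp = oral_cp()
        ke0 = 0.35
        sol = solve_ivp(
            lambda s, y: ke0 * (np.interp(s, t, cp) - y),
            (0.0, t[-1]),
            [0.0],
            method="LSODA",
            t_eval=t,
            rtol=1e-10,
            atol=1e-12,
        )
        ce = effect_site_conc(t, cp, ke0)
        scale = cp.max()
        assert np.max(np.abs(ce - sol.y[0])) / scale < 0.005

    def test_asymptotic_equality_for_convergent_input(self):
        t = np.linspace(0, 100, 2001)
        cp = 5.0 + 3.0 * np.exp(-0.5 * t)
        ce = effect_site_conc(t, cp, ke0=0.4)
        assert ce[-1] == pytest.approx(cp[-1], rel=1e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="ke0"):
            effect_site_conc([0.0, 1.0], [1.0, 1.0], 0.0)
        with pytest.raises(ValueError, match="increasing"):
            effect_site_conc([0.0, 2.0, 1.0], [1.0, 1.0, 1.0], 0.5)


class TestEmaxOccupancy:
    def test_half_maximal_identity(self):
        for ec50 in (0.5, 3.01, 5.52, 40.0):
            for gamma in (0.5, 0.758, 1.0, 2.0):
                assert emax_occupancy(ec50, ec50, gamma) == pytest.approx(50.0, abs=1e-12)

    def test_zero_concentration(self):
        assert emax_occupancy(0.0, 5.52, 0.758) == 0.0

    def test_printed_parameter_evaluation(self):
        # EC50 5.52 ng/mL, gamma 0.758 at C = 100 ng/mL -> ~90% occupancy
        assert emax_occupancy(100.0, 5.52, 0.758) == pytest.approx(90.0, abs=0.1)

    @given(
        ec50=st.floats(0.5, 50),
        gamma=st.floats(0.3, 3),
        scale=st.floats(0.1, 10),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_and_scale_invariant(self, ec50, gamma, scale):
        C = np.geomspace(0.01, 1000, 40)
        occ = emax_occupancy(C, ec50, gamma)
        assert np.all(np.diff(occ) >= -1e-12)
        assert np.all(occ <= 100.0 + 1e-9)
        rescaled = emax_occupancy(scale * C, scale * ec50, gamma)
        assert np.allclose(rescaled, occ, rtol=1e-9)


class TestEmaxModel:
    def test_plasma_mode_round_trip(self):
        C = np.geomspace(0.3, 100, 22)
        occ = emax_occupancy(C, 3.01, 1.0)
        fit = EmaxModel(C, occ, mode="plasma").fit()
        assert fit.gamma == 1.0
        assert fit.ec50 == pytest.approx(3.01, rel=0.01)

    def test_effect_site_mode_frees_gamma(self):
        C = np.geomspace(0.3, 300, 25)
        occ = emax_occupancy(C, 5.52, 0.758)
        fit = EmaxModel(C, occ, mode="effect_site").fit()
        assert fit.ec50 == pytest.approx(5.52, rel=0.01)
        assert fit.gamma == pytest.approx(0.758, rel=0.01)

    def test_monte_carlo_recovery_bands(self):
        """Seeded replicates with 5% proportional occupancy noise: the
        central 90% of estimates stay within 15% (EC50) and 20% (gamma)."""
        rng = np.random.default_rng(2024)
        C = np.geomspace(0.3, 300, 22)
        truth = emax_occupancy(C, 5.52, 0.758)
        ec50s, gammas = [], []
        for _ in range(100):
            occ = np.clip(truth * (1 + rng.normal(0, 0.05, len(C))), -10, 110)
            fit = EmaxModel(C, occ, mode="effect_site").fit()
            ec50s.append(fit.ec50)
            gammas.append(fit.gamma)
        lo_e, hi_e = np.percentile(ec50s, [5, 95])
        lo_g, hi_g = np.percentile(gammas, [5, 95])
        assert 5.52 * 0.85 <= lo_e and hi_e <= 5.52 * 1.15
        assert 0.758 * 0.8 <= lo_g and hi_g <= 0.758 * 1.2

    def test_flat_occupancy_is_flagged_degenerate(self):
        fit = EmaxModel([2.0, 2.0, 2.0], [50.0, 50.0, 50.0]).fit()
        assert any("degenerate" in f for f in fit.flags)
        assert fit.ec50 == pytest.approx(2.0, rel=0.05)

    def test_all_zero_occupancy_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            EmaxModel([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])

    def test_out_of_band_occupancies_rejected(self):
        with pytest.raises(ValueError, match="tolerated"):
            EmaxModel([1.0, 2.0, 3.0], [10.0, 50.0, 150.0])


def peak_trough_cohort(ke0=0.35, ec50=5.52, gamma=0.758, doses=(50, 100, 200, 300, 600)):
    cp_series, obs = {}, []
    for i, dose in enumerate(list(doses) + list(doses)):
        subject = f"P{i:02d}"
        t, cp = oral_cp(dose=dose)
        cp_series[subject] = (t, cp)
        ce = effect_site_conc(t, cp, ke0)
        for t_obs in (2.0, 24.0):  # peak and trough scan times
            occ = emax_occupancy(np.interp(t_obs, t, ce), ec50, gamma)
            obs.append((subject, t_obs, occ))
    return cp_series, obs


class TestEffectSiteEmaxModel:
    def test_joint_noiseless_recovery(self):
        cp_series, obs = peak_trough_cohort()
        fit = EffectSiteEmaxModel(cp_series, obs).fit()
        assert fit.ke0 == pytest.approx(0.35, rel=0.02)
        assert fit.ec50 == pytest.approx(5.52, rel=0.02)
        assert fit.gamma == pytest.approx(0.758, rel=0.02)

    def test_fast_ke0_limit_matches_plasma_mode(self):
        cp_series, obs = peak_trough_cohort(ke0=80.0, gamma=1.0)
        joint = EffectSiteEmaxModel(cp_series, obs).fit()
        C, occ = [], []
        for subject, t_obs, o in obs:
            t, cp = cp_series[subject]
            C.append(np.interp(t_obs, t, cp))
            occ.append(o)
        plasma = EmaxModel(C, occ, mode="plasma").fit()
        assert joint.ec50 == pytest.approx(plasma.ec50, rel=0.05)

    def test_hysteresis_trough_occupancy_exceeds_plasma_prediction(self):
        """With a slow effect site, trough occupancy outruns what the plasma
        concentration alone would predict (counter-clockwise hysteresis)."""
        ke0, ec50, gamma = 0.2, 5.52, 1.0
        t, cp = oral_cp(dose=300)
        ce = effect_site_conc(t, cp, ke0)
        cp24 = np.interp(24.0, t, cp)
        observed = emax_occupancy(np.interp(24.0, t, ce), ec50, gamma)
        plasma_predicted = emax_occupancy(cp24, ec50, gamma)
        assert observed > plasma_predicted

    def test_single_time_design_flagged_unidentifiable(self):
        cp_series, obs = peak_trough_cohort()
        peak_only = [o for o in obs if o[1] == 2.0]
        fit = EffectSiteEmaxModel(cp_series, peak_only).fit()
        assert any("unidentifiable" in f for f in fit.flags)

    def test_uncovered_observation_time_rejected(self):
        t, cp = oral_cp()
        with pytest.raises(ValueError, match="does not cover"):
            EffectSiteEmaxModel({"a": (t, cp)}, [("a", 50.0, 10.0), ("a", 2.0, 5.0), ("a", 4.0, 6.0)])
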