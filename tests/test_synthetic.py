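"""Synthetic generator: AIF shape, forward kinetics, noise, scenarios, PK."""

import numpy as np
import pytest
from scipy.integrate import trapezoid

from petkin import synthetic as syn
from petkin.data import InputFunction
from petkin.synthetic import (
    KineticGroundTruth,
    OccupancyScenario,
    PKScenario,
    add_noise,
    blocked_truth,
    simulate_aif,
    simulate_occupancy_study,
    simulate_pk_profile,
    simulate_tac,
)


class TestSimulateAIF:
    def test_starts_at_zero_and_is_continuous_at_peak(self):
        t = np.arange(0.0, 60.0, 0.05)
        aif = simulate_aif(t, peak_time=1.5, peak_value=30.0)
        assert aif.parent_plasma_conc[0] == 0.0
        i = np.searchsorted(t, 1.5)
        assert aif.parent_plasma_conc[i] == pytest.approx(30.0, rel=1e-6)

    def test_single_exponential_tail(self):
        t = np.arange(0.0, 100.0, 0.1)
        aif = simulate_aif(t, peak_time=1.0, peak_value=10.0,
                           decay_amplitudes=(1.0, 0.0, 0.0), decay_rates=(0.2, 0.05, 0.01))
        tail = t > 1.0
        expected = 10.0 * np.exp(-0.2 * (t[tail] - 1.0))
        assert np.allclose(aif.parent_plasma_conc[tail], expected, rtol=1e-12)

    def test_integral_matches_closed_form(self):
        # numeric quadrature out to a long horizon vs triangle + sum(A_i/r_i)
        t = np.arange(0.0, 4000.0, 0.05)
        amps, rates = (0.6, 0.3, 0.1), (0.5, 0.05, 0.008)
        aif = simulate_aif(t, peak_time=2.0, peak_value=20.0,
                           decay_amplitudes=amps, decay_rates=rates)
        numeric = trapezoid(aif.parent_plasma_conc, t)
        closed = syn.aif_closed_form_integral(2.0, 20.0, amps, rates)
        assert numeric == pytest.approx(closed, rel=1e-3)

    def test_invalid_inputs(self):
        t = np.arange(0.0, 10.0, 0.1)
        with pytest.raises(ValueError, match="peak_value"):
            simulate_aif(t, peak_value=0.0)
        with pytest.raises(ValueError, match="descending"):
            simulate_aif(t, decay_rates=(0.01, 0.05, 0.5))


class TestSimulateTac:
    def test_zero_aif_gives_zero_tac(self, frames):
        t = np.arange(0.0, 250.0, 0.5)
        aif = InputFunction(sample_time=t, parent_plasma_conc=np.zeros_like(t), f_P=0.5)
        truth = KineticGroundTruth("r", K1=0.5, k2=0.1, k3=0.05, k4=0.05)
        tac = simulate_tac(truth, aif, frames)
        assert np.all(tac.activity == 0)

    def test_1tc_matches_fine_grid_convolution_oracle(self, aif, frames):
        """k3=0 reduces to the 1TC model; check against an independent
        brute-force convolution on a 0.005-min grid."""
        truth = KineticGroundTruth("r", K1=0.5, k2=0.1, k3=0.0, k4=0.05)
        tac = simulate_tac(truth, aif, frames)
        dt = 0.005
        grid = np.arange(0.0, tac.end_time + dt, dt)
        cp = aif(grid)
        irf = 0.5 * np.exp(-0.1 * grid)
        # trapezoid-rule discrete convolution (cp[0] = 0 at injection)
        ct = (np.convolve(cp, irf)[: len(grid)] - 0.5 * cp[0] * irf - 0.5 * irf[0] * cp) * dt
        from scipy.integrate import cumulative_trapezoid

        cum = cumulative_trapezoid(ct, grid, initial=0.0)
        expected = (
            np.interp(tac.frame_end, grid, cum) - np.interp(tac.frame_start, grid, cum)
        ) / tac.frame_duration
        assert np.allclose(tac.activity, expected, rtol=1e-3)

    def test_equilibrium_ratio_reaches_vt(self):
        """A sustained constant input drives tissue/plasma to V_T = 10."""
        truth = KineticGroundTruth("r", K1=0.5, k2=0.1, k3=0.05, k4=0.05)
        t = np.arange(0.0, 2001.0, 1.0)
        aif = InputFunction(sample_time=t, parent_plasma_conc=np.full_like(t, 5.0), f_P=0.5)
        frames = (np.array([1980.0]), np.array([2000.0]))
        tac = simulate_tac(truth, aif, frames)
        assert truth.vt == pytest.approx(10.0)
        assert tac.activity[0] / 5.0 == pytest.approx(10.0, rel=0.01)

    def test_linearity_in_aif(self, truths, aif, frames):
        tac1 = simulate_tac(truths["putamen"], aif, frames)
        tac2 = simulate_tac(truths["putamen"], aif.scaled(2.0), frames)
        assert np.allclose(tac2.activity, 2.0 * tac1.activity, rtol=1e-12)

    def test_frames_beyond_aif_support_rejected(self, truths):
        t = np.arange(0.0, 50.0, 0.5)
        aif = simulate_aif(t)
        with pytest.raises(ValueError, match="does not cover"):
            simulate_tac(truths["putamen"], aif, (np.array([0.0]), np.array([60.0])))


class TestAddNoise:
    def test_zero_level_is_identity(self, putamen_tac):
        assert add_noise(putamen_tac, 0.0, seed=1) is putamen_tac

    def test_seed_determinism(self, putamen_tac):
        a = add_noise(putamen_tac, 0.1, seed=42)
        b = add_noise(putamen_tac, 0.1, seed=42)
        assert np.array_equal(a.activity, b.activity)
        c = add_noise(putamen_tac, 0.1, seed=43)
        assert not np.array_equal(a.activity, c.activity)

    def test_noise_is_mean_zero(self, putamen_tac):
        """Law of large numbers: per-frame mean relative deviation ~ 0."""
        reps = np.stack(
            [add_noise(putamen_tac, 0.05, seed=s).activity for s in range(1000)]
        )
        rel_dev = reps.mean(axis=0) / putamen_tac.activity - 1.0
        # MC error ~ sd/sqrt(1000); allow 4 sigma on the worst frame
        sd = 0.05 / np.sqrt(putamen_tac.frame_duration)
        assert np.all(np.abs(rel_dev) < 4 * sd / np.sqrt(1000))


class TestOccupancyScenario:
    def test_blocked_truth_arithmetic(self):
        # V_ND 1, baseline V_T 6, occupancy 0.5 -> blocked V_T 3.5
        truth = KineticGroundTruth("r", K1=0.3, k2=0.3, k3=0.1, k4=0.02)
        assert truth.vt == pytest.approx(6.0)
        assert blocked_truth(truth, 0.5).vt == pytest.approx(3.5)
        assert blocked_truth(truth, 1.0).vt == pytest.approx(truth.vnd)
        assert blocked_truth(truth, 0.0).vt == pytest.approx(truth.vt)
        with pytest.raises(ValueError, match="occupancy"):
            blocked_truth(truth, 1.2)

    def test_zero_occupancy_matches_baseline_after_dose_normalisation(self):
        sc = OccupancyScenario(
            n_subjects=1, noise_level=0.0, true_occupancy={"blocking_1": 0.0}, seed=7
        )
        recs = {r.condition: r for r in simulate_occupancy_study(sc)}
        for region in recs["baseline"].tacs:
            base = recs["baseline"].tacs[region]
            block = recs["blocking_1"].tacs[region]
            assert np.allclose(
                base.activity / base.injected_dose,
                block.activity / block.injected_dose,
                rtol=1e-10,
            )

    def test_bitwise_reproducibility(self):
        sc = OccupancyScenario(n_subjects=2, noise_level=0.05, seed=11)
        a = simulate_occupancy_study(sc)
        b = simulate_occupancy_study(sc)
        for ra, rb in zip(a, b):
            assert ra.subject_id == rb.subject_id and ra.condition == rb.condition
            for region in ra.tacs:
                assert np.array_equal(ra.tacs[region].activity, rb.tacs[region].activity)

    def test_second_blocking_scan_has_no_arterial_data(self):
        recs = simulate_occupancy_study(OccupancyScenario(n_subjects=1, seed=1))
        by_cond = {r.condition: r for r in recs}
        assert by_cond["baseline"].input_function is not None
        assert by_cond["blocking_1"].input_function is not None
        assert by_cond["blocking_2"].input_function is None

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            OccupancyScenario(true_occupancy={"blocking_1": 1.5})


class TestStudyLikeLandmarks:
    def test_putamen_suv_peak_and_cerebellar_washout(self, truths, aif, frames):
        put = simulate_tac(truths["putamen"], aif, frames).to_suv()
        cer = simulate_tac(truths["cerebellum"], aif, frames).to_suv()
        i = int(np.argmax(put.activity))
        assert put.activity[i] == pytest.approx(8.0, abs=1.0)
        assert 20.0 <= put.frame_mid[i] <= 45.0
        j = int(np.argmax(cer.activity))
        assert cer.frame_mid[j] <= 5.0  # fast cerebellar washout
        assert truths["cerebellum"].vt == pytest.approx(6.4, abs=0.05)
        assert truths["cerebellum"].vnd == pytest.approx(1.5, abs=0.01)


class TestPKProfiles:
    def test_plasma_starts_at_zero(self):
        prof = simulate_pk_profile(PKScenario())
        assert prof.plasma.iloc[0] == 0.0
        assert prof.effect_site.iloc[0] == 0.0

    def test_fast_equilibration_tracks_plasma(self):
        prof = simulate_pk_profile(PKScenario(ke0=500.0))
        late = prof.time_h > 1.0
        assert np.allclose(prof.effect_site[late], prof.plasma[late], rtol=0.01)

    def test_effect_site_peak_lags_plasma_peak(self):
        prof = simulate_pk_profile(PKScenario(ke0=0.35))
        t_cp = prof.time_h[prof.plasma.idxmax()]
        t_ce = prof.time_h[prof.effect_site.idxmax()]
        assert t_ce > t_cp

    def test_degenerate_rates_rejected(self):
        with pytest.raises(ValueError, match="ka == ke"):
            PKScenario(ka=0.2, ke=0.2)
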