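"""Transport-limited SPR kinetics: forward model, corrections, global fit."""

import math

import numpy as np
import pytest

from decorakin.spr import (
    ASSOCIATION,
    DISSOCIATION,
    KineticParams,
    PhaseSchedule,
    Sensorgram,
    SensorgramSet,
    TransportLimitedBindingModel,
    compute_kd,
    correct_capture_drift,
    double_reference,
    expected_mass_fraction,
    fit_dissociation_koff,
    fit_global,
    simulate_sensorgram,
)
from decorakin.spr import _association_response, _dissociation_response
from decorakin.synthetic import NoiseSpec, gen_sensorgram_series

from oracles import langmuir_association


class TestForwardModel:
    def test_langmuir_limit_matches_closed_form(self, schedule):
        """With k_t = inf the association phase is the textbook Langmuir exponential."""
        kin = KineticParams(1.8e8, 2e-4, 100.0)
        sg = simulate_sensorgram(kin, 5e-9, schedule)
        am = sg.mask(ASSOCIATION)
        t = sg.time[am] - schedule.baseline_duration
        expected = langmuir_association(kin.k_on, kin.k_off, kin.r_max, 5e-9, t)
        np.testing.assert_allclose(sg.response[am], expected, rtol=1e-12)

    @pytest.mark.parametrize("k_t", [6.5e8, 1e10])
    @pytest.mark.parametrize("conc", [0.312e-9, 20e-9])
    def test_analytic_solution_matches_ode_integration(self, k_t, conc, schedule):
        """Lambert-W closed form and LSODA integrate the same trajectory."""
        kin = KineticParams(1.8e8, 2e-4, 100.0, k_t)
        a = simulate_sensorgram(kin, conc, schedule, method="analytic")
        o = simulate_sensorgram(kin, conc, schedule, method="ode")
        np.testing.assert_allclose(a.response, o.response, atol=1e-4)

    def test_dissociation_700s_loss(self):
        """Pure-exponential 700-s dissociation at k_off 2e-4 loses 1-e^-0.14 ~ 13.1%;
        any finite transport coefficient (rebinding) loses strictly less."""
        ideal = KineticParams(1.8e8, 2e-4, 100.0)
        loss_ideal = 1.0 - _dissociation_response(ideal, 100.0, np.array([700.0]))[0] / 100.0
        assert loss_ideal == pytest.approx(1.0 - math.exp(-0.14), rel=1e-12)
        assert loss_ideal == pytest.approx(0.131, abs=0.001)
        for k_t in (1e8, 6.5e8, 1e10, 1e12):
            limited = KineticParams(1.8e8, 2e-4, 100.0, k_t)
            loss = 1.0 - _dissociation_response(limited, 100.0, np.array([700.0]))[0] / 100.0
            assert loss < loss_ideal

    def test_large_kt_converges_to_langmuir(self, schedule):
        """sup-norm below 0.1 RU once k_t >= 1e6 * k_on * R_max."""
        ideal = KineticParams(1.8e8, 2e-4, 100.0)
        big = KineticParams(1.8e8, 2e-4, 100.0, 1e6 * 1.8e8 * 100.0)
        a = simulate_sensorgram(ideal, 5e-9, schedule)
        b = simulate_sensorgram(big, 5e-9, schedule)
        assert np.abs(a.response - b.response).max() < 0.1

    def test_equilibrium_independent_of_transport(self):
        """R_eq = R_max C / (C + K_D) whatever k_t: transport shifts kinetics only."""
        long = np.array([20000.0])
        for k_t in (6.5e8, 1e10, math.inf):
            kin = KineticParams(1.8e8, 2e-4, 100.0, k_t)
            for conc in (0.05e-9, 1e-9):
                r_eq = kin.r_max * conc / (conc + kin.kd)
                got = _association_response(kin, conc, long)[0]
                assert got == pytest.approx(r_eq, rel=1e-6)

    def test_association_monotone_in_concentration(self, study_kinetics, schedule):
        """At every association time point the response is non-decreasing in C."""
        concs = [0.312e-9, 0.625e-9, 1.25e-9, 2.5e-9, 5e-9, 10e-9, 20e-9]
        traces = [simulate_sensorgram(study_kinetics, c, schedule) for c in concs]
        am = traces[0].mask(ASSOCIATION)
        stacked = np.vstack([sg.response[am] for sg in traces])
        assert np.all(np.diff(stacked, axis=0) >= -1e-9)

    def test_zero_concentration_stays_at_zero(self, study_kinetics, schedule):
        sg = simulate_sensorgram(study_kinetics, 0.0, schedule)
        assert np.all(sg.response == 0.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(-1.0, 2e-4, 100.0)
        with pytest.raises(ValueError):
            KineticParams(1e8, 2e-4, 100.0, k_t=0.0)
        with pytest.raises(ValueError):
            PhaseSchedule(association_duration=0.0)


class TestReferencing:
    def _flat(self, sg, value=0.0):
        return Sensorgram(sg.time.copy(), np.full_like(sg.response, value), 0.0, sg.phase.copy())

    def test_zero_references_rezero_raw(self, study_kinetics, schedule):
        sg = simulate_sensorgram(study_kinetics, 5e-9, schedule)
        sg.response = sg.response + 7.0  # instrument offset
        out = double_reference(sg, self._flat(sg), self._flat(sg))
        baseline = out.response[out.mask("baseline")]
        np.testing.assert_allclose(baseline.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.response, sg.response - 7.0, atol=1e-9)

    def test_exact_cancellation(self, study_kinetics, schedule):
        a = simulate_sensorgram(study_kinetics, 5e-9, schedule)
        b = simulate_sensorgram(study_kinetics, 1e-9, schedule)
        raw = Sensorgram(a.time.copy(), a.response + b.response, 5e-9, a.phase.copy())
        out = double_reference(raw, a, b)
        np.testing.assert_allclose(out.response, 0.0, atol=1e-9)

    def test_bulk_jump_removed(self, study_kinetics, schedule):
        """A 10-RU bulk shift present in both raw and buffer blank cancels."""
        sg = simulate_sensorgram(study_kinetics, 5e-9, schedule)
        jump = np.where(sg.mask(ASSOCIATION), 10.0, 0.0)
        raw = Sensorgram(sg.time.copy(), sg.response + jump, 5e-9, sg.phase.copy())
        buffer_ref = Sensorgram(sg.time.copy(), jump, 0.0, sg.phase.copy())
        out = double_reference(raw, self._flat(sg), buffer_ref)
        np.testing.assert_allclose(out.response, sg.response, atol=1e-9)

    def test_non_overlapping_time_ranges_rejected(self, study_kinetics, schedule):
        sg = simulate_sensorgram(study_kinetics, 5e-9, schedule)
        short = Sensorgram(sg.time[: sg.time.size // 2], sg.response[: sg.time.size // 2], 0.0, sg.phase[: sg.time.size // 2])
        with pytest.raises(ValueError, match="cover"):
            double_reference(sg, short, short)


class TestCaptureDrift:
    def test_zero_capture_koff_is_identity(self, study_kinetics, schedule):
        sg = simulate_sensorgram(study_kinetics, 5e-9, schedule)
        out = correct_capture_drift(sg, 0.0)
        np.testing.assert_array_equal(out.response, sg.response)

    def test_product_of_exponentials_recovered(self, schedule):
        """A trace decaying as e^-(a+b)t corrected with capture rate a leaves e^-bt."""
        a_rate, b_rate = 5e-4, 2e-4
        kin = KineticParams(1.8e8, a_rate + b_rate, 100.0)
        sg = simulate_sensorgram(kin, 20e-9, schedule)
        out = correct_capture_drift(sg, a_rate)
        dm = sg.mask(DISSOCIATION)
        t = sg.time[dm] - sg.dissociation_start
        r0 = sg.response[dm][0]
        np.testing.assert_allclose(out.response[dm], r0 * np.exp(-b_rate * t), rtol=1e-9)

    def test_refit_after_correction_recovers_ligand_koff(self, schedule):
        """Simulate, corrupt with capture decay, correct, refit: k_off within 5%."""
        kin = KineticParams(1.8e8, 2e-4, 1000.0)
        sgs = []
        rng = np.random.default_rng(7)
        capture = 1e-4
        for conc in (5e-9, 10e-9, 20e-9):
            sg = simulate_sensorgram(kin, conc, schedule)
            dm = sg.mask(DISSOCIATION)
            t = sg.time[dm] - sg.dissociation_start
            sg.response[dm] *= np.exp(-capture * t)
            sg.response += rng.normal(0, 0.5, sg.response.size)
            sgs.append(correct_capture_drift(sg, capture))
        est = fit_dissociation_koff(SensorgramSet(sgs))
        assert est.value == pytest.approx(2e-4, rel=0.05)

    def test_noise_amplifying_correction_flagged(self, study_kinetics, schedule):
        sg = simulate_sensorgram(study_kinetics, 5e-9, schedule)
        with pytest.warns(UserWarning, match="10x"):
            correct_capture_drift(sg, 0.01)


class TestDissociationFit:
    def test_noise_free_recovery_machine_precision(self, schedule):
        kin = KineticParams(1.8e8, 2e-4, 100.0)
        sgs = SensorgramSet([simulate_sensorgram(kin, c, schedule) for c in (5e-9, 20e-9)])
        est = fit_dissociation_koff(sgs)
        assert est.value == pytest.approx(2e-4, rel=1e-8)

    def test_noisy_eight_curve_average_within_ten_percent(self, schedule):
        kin = KineticParams(1.8e8, 2e-4, 1000.0)
        rng = np.random.default_rng(3)
        sgs = []
        for _ in range(8):
            sg = simulate_sensorgram(kin, 20e-9, schedule)
            sg.response = sg.response + rng.normal(0, 0.5, sg.response.size)
            sgs.append(sg)
        est = fit_dissociation_koff(SensorgramSet(sgs))
        assert est.value == pytest.approx(2e-4, rel=0.10)

    def test_flat_trace_triggers_lower_bound(self, schedule):
        kin = KineticParams(1.8e8, 0.0, 100.0)
        sg = simulate_sensorgram(kin, 20e-9, schedule)
        with pytest.warns(UserWarning, match="lower bound"):
            est = fit_dissociation_koff(SensorgramSet([sg]))
        assert est.value == 0.0


class TestGlobalFit:
    def test_noise_free_fit_reproduces_table_kd(self, schedule):
        """k_on 1.8e8 with k_off fixed at 2e-4 gives K_D = 1.11 pM."""
        kin = KineticParams(1.8e8, 2e-4, 100.0, 6.5e8)
        sgs = gen_sensorgram_series(kin, schedule=schedule, noise=NoiseSpec(sd=0.0))
        fit = fit_global(sgs, koff_fixed=2e-4, n_starts=4, seed=0)
        assert fit.k_on == pytest.approx(1.8e8, rel=1e-4)
        assert fit.kd == pytest.approx(fit.k_off / fit.k_on, rel=0)  # exact invariant
        assert fit.kd * 1e12 == pytest.approx(1.11, abs=0.005)
        assert fit.kd_stderr is None  # k_off forced: no K_D error, by convention

    def test_kinetics_limited_data_reports_kt_unbounded(self, schedule):
        sgs = gen_sensorgram_series(
            KineticParams(1.8e8, 2e-4, 100.0), schedule=schedule, noise=NoiseSpec(sd=0.0)
        )
        fit = fit_global(sgs, koff_fixed=2e-4, n_starts=4, seed=0)
        assert fit.k_t_unbounded
        assert math.isinf(fit.k_t)

    def test_single_low_concentration_rejected(self, study_kinetics, schedule):
        sg = simulate_sensorgram(study_kinetics, 0.05e-12, schedule)
        with pytest.raises(ValueError, match="unidentifiable"):
            TransportLimitedBindingModel([sg])

    def test_summary_mentions_key_quantities(self, schedule):
        kin = KineticParams(1.8e8, 2e-4, 100.0, 6.5e8)
        sgs = gen_sensorgram_series(kin, concentrations=(1e-9, 10e-9), schedule=schedule, noise=NoiseSpec(sd=0.0))
        text = fit_global(sgs, n_starts=2, seed=0).summary()
        for token in ("k_on", "K_D", "R_max", "pM"):
            assert token in text


class TestArithmetic:
    @pytest.mark.parametrize(
        "kon_1e6, kd_pm",
        [
            (180.0, "1.11"),
            (111.0, "1.80"),
            (47.6, "4.20"),
            (9.01, "22.2"),
            (362.0, "0.55"),
            (866.0, "0.23"),
            (120.0, "1.67"),
            (84.7, "2.36"),
            (0.417, "480"),
            (61.1, "3.27"),
            (19.5, "10.3"),
        ],
    )
    def test_kd_from_printed_kon_and_fixed_koff(self, kon_1e6, kd_pm):
        """K_D = k_off/k_on reproduces each tabulated affinity at printed precision."""
        kd = compute_kd(kon_1e6 * 1e6, 2e-4) * 1e12
        ndigits = len(kd_pm.split(".")[1]) if "." in kd_pm else 0
        assert round(kd, ndigits) == pytest.approx(float(kd_pm))

    def test_kd_limits_and_validation(self):
        assert compute_kd(1e8, 0.0) == 0.0
        with pytest.raises(ValueError):
            compute_kd(0.0, 2e-4)

    def test_mass_fraction_full_decoration(self):
        """120 copies of an 18.3 kDa ligand on a 26 MDa particle: +8.4%."""
        assert round(expected_mass_fraction(120, 18.3e3, 26e6), 1) == 8.4
        assert expected_mass_fraction(0, 18.3e3, 26e6) == 0.0
        assert expected_mass_fraction(120, 17.3e3, 26e6) == pytest.approx(7.98, abs=0.005)
        with pytest.raises(ValueError):
            expected_mass_fraction(120, -1.0, 26e6)
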