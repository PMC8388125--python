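"""Global fitting, Monte Carlo uncertainty, dead time, model comparison."""

import numpy as np
import pytest

from slpkinetics import (
    FitSpec,
    GlobalKineticModel,
    KineticTrace,
    RateParametersModel1,
    SignalResponse,
    compare_models,
    estimate_dead_time,
    fit_competition,
    fit_global,
    loglog_correlation,
    monte_carlo_ci,
    rates_from_kd_kapp,
)
from slpkinetics.fitting import ConvergenceError
from slpkinetics.mechanisms import InvalidParameterError, kapp_from_rates
from slpkinetics.synthdata import (
    ExperimentDesign,
    generate_kinetic_dataset,
    plate_reader_design,
    stopped_flow_design,
)

RESP = SignalResponse(r_free=0.05, r_bound=0.25)


def make_model1_traces(kapp=2.57e4, noise=0.0, seed=0, replicates=1):
    design = plate_reader_design(
        {"kapp": kapp},
        protein_concentrations=[0.2e-6, 1e-6, 5e-6, 25e-6],
        noise_sd=noise,
        replicates=replicates,
        seed=seed,
    )
    traces, _ = generate_kinetic_dataset(design)
    return traces


class TestFitGlobal:
    def test_noiseless_model1_exact_recovery(self):
        traces = make_model1_traces()
        spec = FitSpec(mechanism="model1", response=RESP)
        fit = fit_global(spec, traces, n_starts=2, seed=0)
        assert fit.params["kapp"] == pytest.approx(2.57e4, rel=1e-4)
        assert fit.params["r_bound"] == pytest.approx(0.25, abs=1e-6)
        assert fit.rss < 1e-12
        assert fit.converged

    def test_trace_order_invariance(self):
        traces = make_model1_traces(noise=0.005, seed=3)
        spec = FitSpec(mechanism="model1", response=RESP)
        forward = fit_global(spec, traces, n_starts=1)
        backward = fit_global(spec, traces[::-1], n_starts=1)
        assert forward.params["kapp"] == pytest.approx(
            backward.params["kapp"], rel=1e-6
        )

    def test_signal_scale_invariance(self):
        # fitting in mP units (1000x) must give the same rate constant
        traces = make_model1_traces(noise=0.005, seed=5)
        scaled = [t.with_signal(t.signal * 1000.0) for t in traces]
        fit_frac = fit_global(FitSpec("model1", RESP), traces, n_starts=1)
        resp_mp = SignalResponse(r_free=50.0, r_bound=250.0)
        fit_mp = fit_global(FitSpec("model1", resp_mp), scaled, n_starts=1)
        assert fit_mp.params["kapp"] == pytest.approx(
            fit_frac.params["kapp"], rel=1e-6
        )

    def test_noiseless_model2_recovery(self):
        truth = rates_from_kd_kapp(kd=9.99e-9, kapp=1.39e8, k2=10.0)
        design = stopped_flow_design(
            {"k1": truth.k1, "k_minus1": truth.k_minus1, "k2": truth.k2},
            noise_sd=0.0,
            replicates=1,
            n_points=120,
        )
        traces, _ = generate_kinetic_dataset(design)
        spec = FitSpec(mechanism="model2", response=design.response)
        fit = fit_global(spec, traces, n_starts=1)
        assert fit.params["k1"] == pytest.approx(truth.k1, rel=1e-3)
        assert fit.params["k_minus1"] == pytest.approx(truth.k_minus1, rel=1e-2)
        assert fit.params["k2"] == pytest.approx(truth.k2, rel=1e-3)
        assert fit.derived["kd"] == pytest.approx(9.99e-9, rel=1e-2)
        assert fit.derived["kapp"] == pytest.approx(1.39e8, rel=1e-3)

    def test_model1_on_saturating_two_step_data_overestimates(self):
        # at concentrations >> Kd the one-step fit inflates the apparent
        # rate constant relative to the generator's low-concentration limit
        truth = rates_from_kd_kapp(kd=9.99e-9, kapp=1.39e8, k2=10.0)
        kapp_true = kapp_from_rates(truth)
        design = stopped_flow_design(
            {"k1": truth.k1, "k_minus1": truth.k_minus1, "k2": truth.k2},
            noise_sd=0.002,
            replicates=1,
            n_points=100,
            seed=11,
        )
        traces, _ = generate_kinetic_dataset(design)
        fit1 = fit_global(FitSpec("model1", design.response), traces, n_starts=2, seed=0)
        assert fit1.params["kapp"] > kapp_true

    def test_unidentifiable_two_step_flagged(self):
        # all traces far below Kd: k1 and k_minus1 are not separable
        truth = {"k1": 1e6, "k_minus1": 100.0, "k2": 10.0}  # Kd = 100 uM
        design = ExperimentDesign(
            mechanism="model2",
            true_params=truth,
            conditions=((1e-9, 1e-9, 0.0), (2e-9, 2e-9, 0.0)),
            t_end=2e4,
            n_points=60,
            spacing="log",
            t_start=1.0,
            replicates=1,
            noise_sd=0.0005,
            response=RESP,
            signal_type="fp",
            seed=2,
        )
        traces, _ = generate_kinetic_dataset(design)
        fit = fit_global(FitSpec("model2", RESP), traces, n_starts=1)
        assert fit.identifiability_warning

    def test_substrate_scale_recovered(self):
        # generate with substrate quantified 30% low, fit the scale factor
        design = plate_reader_design(
            {"kapp": 4.29e5},
            protein_concentrations=[15e-9, 50e-9, 150e-9, 450e-9, 900e-9],
            substrate_total=20e-9,
            t_end=600.0,
            n_points=121,
            noise_sd=0.0,
            replicates=1,
        )
        traces, _ = generate_kinetic_dataset(design)
        mislabeled = [
            KineticTrace(
                times=t.times,
                signal=t.signal,
                protein_total=t.protein_total,
                substrate_total=t.substrate_total / 1.3,
                signal_type=t.signal_type,
                replicate_id=t.replicate_id,
            )
            for t in traces
        ]
        spec = FitSpec("model1", RESP, fit_substrate_scale=True)
        fit = fit_global(spec, mislabeled, n_starts=2, seed=0)
        assert fit.params["s_scale"] == pytest.approx(1.3, rel=1e-2)
        assert fit.params["kapp"] == pytest.approx(4.29e5, rel=1e-2)

    def test_empty_traces_rejected(self):
        with pytest.raises(InvalidParameterError):
            GlobalKineticModel([], spec=FitSpec("model1", RESP))


class TestFitCompetition:
    def _design(self, kapp_I, seed=0, noise=0.005):
        from slpkinetics.synthdata import competition_design

        return competition_design(
            {"kapp_S": 2.57e4, "kapp_I": kapp_I},
            competitor_concentrations=[0.0, 0.125e-6, 0.25e-6, 0.5e-6, 1e-6],
            noise_sd=noise,
            seed=seed,
        )

    def test_identical_competitor_gives_unity_ratio(self):
        design = self._design(kapp_I=2.57e4, seed=9)
        traces, _ = generate_kinetic_dataset(design)
        spec = FitSpec("competition", design.response, fixed={"kapp_S": 2.57e4})
        fit = fit_competition(spec, traces, n_starts=2, seed=1)
        assert fit.params["kapp_I"] / 2.57e4 == pytest.approx(1.0, rel=0.05)

    def test_requires_fixed_probe_rate(self):
        with pytest.raises(InvalidParameterError):
            FitSpec("competition", RESP)

    def test_zero_competitor_prediction_reduces_to_model1(self):
        from slpkinetics.mechanisms import model1_product

        design = self._design(kapp_I=1.53e3, seed=10, noise=0.003)
        traces, _ = generate_kinetic_dataset(design)
        spec = FitSpec("competition", design.response, fixed={"kapp_S": 2.57e4})
        fit = fit_competition(spec, traces, n_starts=2, seed=1)
        # on the zero-competitor control the fitted competition model must
        # coincide with the one-step model at the same parameters
        r_free = design.response.r_free
        r_bound = fit.params["r_bound"]
        for trace in (t for t in traces if t.competitor_total == 0.0):
            frac = model1_product(
                2.57e4, trace.protein_total, trace.substrate_total, trace.times
            ) / trace.substrate_total
            expected = r_free + (r_bound - r_free) * frac
            assert np.allclose(fit.predict(trace), expected, atol=1e-8)


class TestMonteCarlo:
    def test_zero_noise_collapses_ci(self):
        traces = make_model1_traces()
        fit = fit_global(FitSpec("model1", RESP), traces, n_starts=1)
        mc = monte_carlo_ci(fit, n_iterations=20, seed=1)
        lo, hi = mc.ci95["kapp"]
        assert (hi - lo) / fit.params["kapp"] < 1e-4

    def test_seed_reproducibility(self):
        traces = make_model1_traces(noise=0.005, seed=7)
        fit = fit_global(FitSpec("model1", RESP), traces, n_starts=1)
        a = monte_carlo_ci(fit, n_iterations=30, seed=42)
        b = monte_carlo_ci(fit, n_iterations=30, seed=42)
        assert a.ci95["kapp"] == b.ci95["kapp"]
        assert np.array_equal(a.mc_samples["kapp"], b.mc_samples["kapp"])
        c = monte_carlo_ci(fit, n_iterations=30, seed=43)
        assert a.ci95["kapp"] != c.ci95["kapp"]

    def test_ci_ordered_and_contains_estimate(self):
        traces = make_model1_traces(noise=0.005, seed=8)
        fit = fit_global(FitSpec("model1", RESP), traces, n_starts=1)
        mc = monte_carlo_ci(fit, n_iterations=60, seed=3)
        lo, hi = mc.ci95["kapp"]
        assert lo < hi
        assert lo < fit.params["kapp"] < hi

    def test_requires_converged_fit(self):
        traces = make_model1_traces()
        fit = fit_global(FitSpec("model1", RESP), traces, n_starts=1)
        object.__setattr__ if False else setattr(fit, "converged", False)
        with pytest.raises(ConvergenceError):
            monte_carlo_ci(fit, n_iterations=5, seed=0)


class TestDeadTime:
    def _decay(self, k=100.0, truncate=0.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(truncate, 0.06, 120)
        y = np.exp(-k * t) + rng.normal(0, noise, t.size)
        return KineticTrace(
            times=t - t[0],
            signal=y,
            protein_total=1e-6,
            substrate_total=1e-6,
        )

    def test_untruncated_trace_gives_zero(self):
        trace = self._decay(truncate=0.0)
        assert estimate_dead_time(trace, expected_amplitude=1.0) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_three_ms_truncation_recovered(self):
        trace = self._decay(k=100.0, truncate=3e-3, noise=0.01, seed=12)
        dt = estimate_dead_time(trace, expected_amplitude=1.0)
        assert dt == pytest.approx(3e-3, rel=0.10)

    def test_amplitude_free_variant_rejected(self):
        trace = self._decay(truncate=3e-3)
        with pytest.raises(InvalidParameterError):
            estimate_dead_time(trace)

    def test_non_exponential_trace_rejected(self):
        t = np.linspace(0, 1, 50)
        trace = KineticTrace(
            times=t,
            signal=1.0 / (1.0 + 20 * t) ** 0.2 + 0.5 * np.sin(8 * t) * 0.3 + 0.5,
            protein_total=1e-6,
            substrate_total=1e-6,
        )
        with pytest.raises(RuntimeError):
            estimate_dead_time(trace, expected_amplitude=1.5)


class TestLogLogCorrelation:
    def test_exact_line_recovered(self):
        ka = np.geomspace(1e3, 1e8, 8)
        kapp = 10**1.5 * ka**1.0
        fit = loglog_correlation(kapp, ka)
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_band_contains_noisy_truth(self):
        rng = np.random.default_rng(0)
        ka = np.geomspace(1e3, 1e8, 10)
        kapp = 10 ** (1.0 + 1.0 * np.log10(ka) + rng.normal(0, 0.2, ka.size))
        fit = loglog_correlation(kapp, ka)
        true_line = 1.0 + 1.0 * fit.band_log_ka
        inside = (fit.band_lower <= true_line) & (true_line <= fit.band_upper)
        assert inside.mean() > 0.5

    def test_small_or_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            loglog_correlation([1e4, 1e5], [1e5, 1e6])
        with pytest.raises(InvalidParameterError):
            loglog_correlation([1e4, -1e5, 1e6], [1e5, 1e6, 1e7])


class TestCompareModels:
    def test_identical_fits_zero_delta(self):
        traces = make_model1_traces(noise=0.005, seed=2)
        fit = fit_global(FitSpec("model1", RESP), traces, n_starts=1)
        cmp = compare_models(fit, fit)
        assert cmp.delta_aicc == pytest.approx(0.0)
        assert cmp.preferred == "indistinguishable"

    def test_two_step_preferred_on_saturating_two_step_data(self):
        truth = rates_from_kd_kapp(kd=9.99e-9, kapp=1.39e8, k2=10.0)
        design = stopped_flow_design(
            {"k1": truth.k1, "k_minus1": truth.k_minus1, "k2": truth.k2},
            noise_sd=0.002,
            replicates=1,
            n_points=100,
            seed=21,
        )
        traces, _ = generate_kinetic_dataset(design)
        fit1 = fit_global(FitSpec("model1", design.response), traces, n_starts=2, seed=0)
        fit2 = fit_global(FitSpec("model2", design.response), traces, n_starts=2, seed=0)
        cmp = compare_models(fit1, fit2)
        assert cmp.preferred == "b"
        assert cmp.rss_ratio > 1.0
        # the one-step misfit leaves systematic runs in the residuals
        assert cmp.runs_test_p < 0.01

    def test_one_step_not_disfavored_on_one_step_data(self):
        traces = make_model1_traces(noise=0.005, seed=13)
        fit1 = fit_global(FitSpec("model1", RESP), traces, n_starts=1)
        fit2 = fit_global(FitSpec("model2", RESP), traces, n_starts=2, seed=1)
        cmp = compare_models(fit1, fit2)
        assert cmp.delta_aicc < 2.0

    def test_mismatched_data_rejected(self):
        a = fit_global(FitSpec("model1", RESP), make_model1_traces(noise=0.005, seed=1), n_starts=1)
        b = fit_global(FitSpec("model1", RESP), make_model1_traces(noise=0.005, seed=2), n_starts=1)
        with pytest.raises(InvalidParameterError):
            compare_models(a, b)
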