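import math

import numpy as np
import pandas as pd
import pytest

from memswitch.bulk_models import (
    accumulation_rate,
    fit_accumulation,
    fit_degradation,
    mean_constant_production,
    mean_linear_production,
    mean_model_curve,
    model1_closed_form,
)
from memswitch.kinetics import (
    MEMORY_SWITCH,
    MODEL1,
    InductionProtocol,
    KineticParams,
    PromoterModelSpec,
)
from memswitch.synthetic_data import SyntheticScenario, generate_qpcr_dataset


def _series(t, y):
    return pd.DataFrame({
        "condition": "control", "induction": 1, "time_min": t,
        "replicate": 1, "mrna_per_cell": y,
    })


class TestClosedForms:
    def test_constant_production_values(self):
        assert mean_constant_production(12, 100, 0, 0) == 0
        assert mean_constant_production(12, 100, 0, 100) == pytest.approx(
            1200 * (1 - math.exp(-1)), rel=1e-12
        )
        # steady state P*tau
        assert mean_constant_production(12, 100, 0, 1e5) == pytest.approx(1200)

    def test_linear_production_values(self):
        # pure decay when a = 0
        assert mean_linear_production(0.0, 200, 50, 200) == pytest.approx(
            50 * math.exp(-1)
        )
        val = mean_linear_production(0.06, 600, 0, 240)
        expected = 36 * (240 - 600 * (1 - math.exp(-0.4)))
        assert val == pytest.approx(expected, rel=1e-12)

    def test_linear_production_taylor_limit(self):
        # t << tau: m ~ m0 + a t^2 / 2
        val = mean_linear_production(0.01, 10_000, 5.0, 2.0)
        assert val == pytest.approx(5.0 + 0.01 * 4 / 2, rel=1e-3)

    @pytest.mark.parametrize("fn,args", [
        (mean_constant_production, (3.0, 150.0, 20.0)),
        (mean_linear_production, (0.02, 150.0, 20.0)),
    ])
    def test_closed_forms_satisfy_their_odes(self, fn, args):
        rate, tau, m0 = args
        t = np.linspace(1.0, 500.0, 40)
        h = 1e-4
        m = fn(rate, tau, m0, t)
        dm = (fn(rate, tau, m0, t + h) - fn(rate, tau, m0, t - h)) / (2 * h)
        production = rate if fn is mean_constant_production else rate * t
        resid = dm - (production - m / tau)
        assert np.max(np.abs(resid)) < 1e-6


class TestMeanModelCurve:
    def test_model1_matches_closed_form(self):
        params = KineticParams(k_A=5.1e-3, k_pol=2.0)
        t = np.linspace(0, 240, 25)
        numeric = mean_model_curve(PromoterModelSpec(MODEL1), params,
                                   600.0, 6, t)
        analytic = model1_closed_form(5.1e-3, 2.0, 600.0, 6, t)
        assert np.allclose(numeric, analytic, rtol=1e-6, atol=1e-8)

    def test_memory_switch_without_memory_equals_model1(self):
        params = KineticParams(k_C=0.0, k_polB=0.0, k_polL=0.7, k_polH=4.5,
                               k_pol=0.7)
        t = np.linspace(0, 240, 10)
        mem = mean_model_curve(PromoterModelSpec(MEMORY_SWITCH), params,
                               600.0, 6, t)
        m1 = mean_model_curve(PromoterModelSpec(MODEL1), params, 600.0, 6, t)
        assert np.allclose(mem, m1, rtol=1e-9, atol=1e-9)

    def test_no_hormone_flat_decay(self):
        params = KineticParams(k_polB=0.0, k_polL=0.0, k_polH=0.0, k_A=0.0,
                               k_C=0.0)
        t = np.linspace(0, 600, 7)
        curve = mean_model_curve(PromoterModelSpec(MEMORY_SWITCH), params,
                                 300.0, 6, t, m0=90.0)
        assert np.allclose(curve, 90.0 * np.exp(-t / 300.0), rtol=1e-6)

    def test_locus_count_scales_production(self):
        params = KineticParams()
        t = np.array([240.0])
        m6 = mean_model_curve(PromoterModelSpec(MEMORY_SWITCH), params,
                              600.0, 6, t)
        m1 = mean_model_curve(PromoterModelSpec(MEMORY_SWITCH), params,
                              600.0, 1, t)
        assert m6[0] == pytest.approx(6 * m1[0], rel=1e-6)


class TestFitDegradation:
    def test_noiseless_recovery(self):
        t = np.arange(0, 270, 30.0)
        fit = fit_degradation(_series(t, 400 * np.exp(-t / 120)))
        assert fit.lifetime_tau == pytest.approx(120.0, rel=1e-6)
        assert fit.m0 == pytest.approx(400.0, rel=1e-6)
        assert fit.warning is None

    def test_constant_series_flagged(self):
        t = np.arange(0, 270, 30.0)
        fit = fit_degradation(_series(t, np.full(t.size, 55.0)))
        assert fit.warning is not None
        assert fit.lifetime_tau >= 1e6

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_degradation(_series([0, 30, 60], [9, 8, 7]))


class TestFitAccumulation:
    def test_noiseless_constant_production_exact(self):
        t = np.arange(0, 270, 30.0)
        y = mean_constant_production(4.2, 600.0, 0.0, t)
        fit = fit_accumulation("constant", _series(t, y), tau=600.0)
        assert fit.params["P_cell"] == pytest.approx(4.2, rel=1e-6)
        lo, hi = fit.ci95["P_cell"]
        assert lo <= 4.2 <= hi

    def test_model1_recovery_at_published_values(self):
        # median over independent synthetic datasets: the estimator is
        # unbiased and its spread is within the reported uncertainty
        estimates = []
        for seed in range(100, 105):
            sc = SyntheticScenario(
                spec=PromoterModelSpec(MODEL1),
                params=KineticParams(k_A=5.1e-3, k_pol=2.0),
                protocol=InductionProtocol.single_induction(240.0),
                qpcr_noise_cv=0.02, seed=seed,
            )
            data, _ = generate_qpcr_dataset(sc)
            fit = fit_accumulation(MODEL1, data, tau=sc.tau)
            estimates.append(fit.params["k_pol"])
        assert np.median(estimates) == pytest.approx(2.0, abs=0.2)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            fit_accumulation("cubic", _series([0, 1], [0, 1]), tau=600.0)


class TestAccumulationRate:
    def test_constant_model_steady_state(self):
        t = np.arange(0, 270, 30.0)
        y = mean_constant_production(6.0, 100.0, 0.0, t)
        fit = fit_accumulation("constant", _series(t, y), tau=100.0)
        rates = accumulation_rate(fit, [5000.0])
        assert rates["accumulation_rate"].iloc[0] == pytest.approx(0.0,
                                                                   abs=1e-6)
        assert rates["transcription_rate_per_locus"].iloc[0] == (
            pytest.approx(1.0, rel=1e-6)
        )

    def test_linear_model_per_locus_rate(self):
        t = np.arange(0, 270, 30.0)
        y = mean_linear_production(0.05, 600.0, 0.0, t)
        fit = fit_accumulation("linear", _series(t, y), tau=600.0)
        rates = accumulation_rate(fit, [240.0])
        # a*t/n_loci = 0.05*240/6 = 2 mRNA/min per locus
        assert rates["transcription_rate_per_locus"].iloc[0] == (
            pytest.approx(2.0, rel=1e-4)
        )
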