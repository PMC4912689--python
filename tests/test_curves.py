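import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from alascan.curves import (
    OneSiteCompetition,
    ThreeParamLogistic,
    cheng_prusoff,
    competition1,
    fit_competition,
    fit_logistic,
    logistic3,
)
from alascan.datamodel import FitStatus

CONC8 = np.logspace(-11, -5, 8)


class TestThreeParamLogistic:
    def test_recovers_noiseless_parameters_to_1e6(self):
        y = logistic3(CONC8, pec50=8.0, top=100.0, bottom=0.0)
        est = ThreeParamLogistic().fit(CONC8.reshape(-1, 1), y)
        assert est.converged_
        assert est.pec50_ == pytest.approx(8.0, abs=1e-6)
        assert est.top_ == pytest.approx(100.0, abs=1e-4)
        assert est.bottom_ == pytest.approx(0.0, abs=1e-4)

    def test_curve_at_ec50_is_midpoint(self):
        # analytic midpoint of the 3PL: Y(EC50) = (Top + Bottom) / 2
        y = logistic3(np.array([1e-8]), pec50=8.0, top=80.0, bottom=20.0)
        assert y[0] == pytest.approx(50.0, abs=1e-12)

    def test_simulated_refit_recovers_pec50(self):
        rng = np.random.default_rng(42)
        conc = np.logspace(-11, -5, 9)
        per_exp = {}
        for e in range(1, 6):
            mean = logistic3(conc, pec50=7.5, top=85.0, bottom=5.0)
            per_exp[e] = mean * (1 + rng.normal(0, 0.05, conc.size))
        rows = [(e, 1, c, v) for e, ys in per_exp.items() for c, v in zip(conc, ys)]
        df = pd.DataFrame(rows, columns=["experiment_id", "replicate_id",
                                         "concentration", "response"])
        fit = fit_logistic(df)
        assert fit.status is FitStatus.ok and fit.n_experiments == 5
        assert fit.pec50 == pytest.approx(7.5, abs=0.1)

    def test_response_rescaling_leaves_pec50_invariant(self):
        y = logistic3(CONC8, pec50=7.8, top=90.0, bottom=10.0)
        a = ThreeParamLogistic().fit(CONC8.reshape(-1, 1), y)
        b = ThreeParamLogistic().fit(CONC8.reshape(-1, 1), 3.0 * y)
        assert b.pec50_ == pytest.approx(a.pec50_, abs=1e-6)
        assert b.top_ == pytest.approx(3.0 * a.top_, rel=1e-6)
        assert b.bottom_ == pytest.approx(3.0 * a.bottom_, abs=1e-3)

    def test_predictions_monotone_and_bounded(self):
        y = logistic3(CONC8, pec50=8.2, top=100.0, bottom=0.0)
        est = ThreeParamLogistic().fit(CONC8.reshape(-1, 1), y)
        grid = np.logspace(-12, -4, 50).reshape(-1, 1)
        pred = est.predict(grid)
        assert np.all(np.diff(pred) >= -1e-9)
        assert np.all(pred >= min(est.bottom_, est.top_) - 1e-9)
        assert np.all(pred <= max(est.bottom_, est.top_) + 1e-9)

    def test_flat_curve_reports_no_response(self):
        rng = np.random.default_rng(0)
        rows = []
        for e in (1, 2, 3):
            for c in CONC8:
                for rep in (1, 2):
                    rows.append((e, rep, c, 1.0 + rng.normal(0, 0.5)))
        df = pd.DataFrame(rows, columns=["experiment_id", "replicate_id",
                                         "concentration", "response"])
        fit = fit_logistic(df)
        assert fit.status is FitStatus.no_response
        assert np.isnan(fit.pec50)

    def test_needs_five_distinct_concentrations(self):
        conc = np.array([1e-9, 1e-8, 1e-7, 1e-6])
        y = logistic3(conc, 8.0, 100.0, 0.0)
        with pytest.raises(ValueError, match="5 distinct"):
            ThreeParamLogistic().fit(conc.reshape(-1, 1), y)

    def test_sklearn_estimator_contract(self):
        est = ThreeParamLogistic(fix_bottom=0.0, n_starts=5)
        params = est.get_params()
        assert params["fix_bottom"] == 0.0 and params["n_starts"] == 5
        cloned = clone(est)
        assert cloned.get_params() == params


class TestChengPrusoff:
    def test_correction_vanishes_for_trace_tracer(self):
        # tracer at 1/1000 of its Kd: pKi and pIC50 coincide
        assert cheng_prusoff(8.2, 1e-12, 1e-9) == pytest.approx(8.2, abs=5e-4)

    def test_tracer_at_kd_gives_half_ic50(self):
        assert cheng_prusoff(8.0, 1e-9, 1e-9) == pytest.approx(8.0 + np.log10(2.0))

    def test_rejects_nonpositive_tracer(self):
        with pytest.raises(ValueError):
            cheng_prusoff(8.0, 0.0, 1e-9)


class TestCompetition:
    def _records(self, pic50, seed, noise=0.05, n_exp=5):
        rng = np.random.default_rng(seed)
        logc = np.linspace(-11, -6, 10)
        rows = []
        for e in range(1, n_exp + 1):
            mean = competition1(logc, pic50, top=100.0, bottom=0.0)
            obs = mean + rng.normal(0, noise * 100.0, logc.size)
            rows.extend((e, lc, v) for lc, v in zip(logc, obs))
        return pd.DataFrame(rows, columns=["experiment_id", "log_conc",
                                           "specific_binding"])

    def test_pki_is_pic50_plus_fixed_correction(self):
        # tracer at half its Kd: correction is exactly log10(1.5) = 0.176
        df = self._records(pic50=8.2, seed=7)
        fit = fit_competition(df, tracer_kd=1e-9, tracer_conc=5e-10)
        assert fit.status is FitStatus.ok
        assert fit.pki - fit.pic50 == pytest.approx(0.17609, abs=1e-5)
        assert fit.pic50 == pytest.approx(8.2, abs=0.1)
        assert fit.pki <= fit.pic50 + np.log10(2.0) + 1e-12

    def test_no_displacement_flagged_no_binding(self):
        rng = np.random.default_rng(1)
        logc = np.linspace(-11, -6, 10)
        rows = [(e, lc, 100.0 + rng.normal(0, 3.0))
                for e in (1, 2, 3) for lc in logc]
        df = pd.DataFrame(rows, columns=["experiment_id", "log_conc",
                                         "specific_binding"])
        fit = fit_competition(df, 1e-9, 5e-10)
        assert fit.status is FitStatus.no_binding

    def test_one_site_estimator_recovers_midpoint(self):
        logc = np.linspace(-11, -6, 10)
        y = competition1(logc, 8.0, 100.0, 0.0)
        est = OneSiteCompetition().fit(logc.reshape(-1, 1), y)
        assert est.pic50_ == pytest.approx(8.0, abs=1e-6)
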