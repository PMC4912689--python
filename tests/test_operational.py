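import numpy as np
import pandas as pd
import pytest

from alascan.curves import ThreeParamLogistic
from alascan.datamodel import FitStatus, OperationalFit
from alascan.operational import (
    OperationalModel,
    correct_tau,
    fit_operational,
    operational_response,
)
from alascan.simulate import NoiseModel, generate_panel, wild_type_truth

CONC = np.concatenate([[0.0], np.logspace(-11, -5, 10)])


class TestOperationalModel:
    def test_plateau_at_tau_1_is_half_window(self):
        # plateau = Bottom + (Em - Bottom) * tau / (tau + 1); tau = 1 halves it
        y = operational_response(np.array([1e3]), log_tau=0.0, log_ka=-7.0,
                                 em=100.0, bottom=20.0)
        assert y[0] == pytest.approx(60.0, abs=1e-6)

    def test_noiseless_recovery_and_derived_pec50(self):
        y = operational_response(CONC, log_tau=0.7, log_ka=-7.0, em=100.0, bottom=0.0)
        est = OperationalModel(log_ka=-7.0, bottom=0.0)
        est.fit(CONC.reshape(-1, 1), y)
        assert est.log_tau_ == pytest.approx(0.7, abs=1e-5)
        assert est.em_ == pytest.approx(100.0, abs=1e-3)
        fit = OperationalFit(log_tau=est.log_tau_, log_ka=est.log_ka_)
        assert fit.derived_pec50 == pytest.approx(7.0 + np.log10(10**0.7 + 1), abs=1e-5)

    def test_free_ka_noiseless_recovery(self):
        y = operational_response(CONC, log_tau=0.3, log_ka=-7.5, em=100.0, bottom=0.0)
        est = OperationalModel(em=100.0, bottom=0.0)  # Em anchored, K_A free
        est.fit(CONC.reshape(-1, 1), y)
        assert est.log_tau_ == pytest.approx(0.3, abs=1e-4)
        assert est.log_ka_ == pytest.approx(-7.5, abs=1e-4)

    def test_pec50_consistency_with_logistic_fit(self):
        # 3PL and operational fits of the same noiseless data must agree on EC50
        for log_tau in (-0.3, 0.5, 1.2):
            y = operational_response(CONC, log_tau, -7.5, 100.0, 0.0)
            om = OperationalModel(log_ka=-7.5, bottom=0.0).fit(CONC.reshape(-1, 1), y)
            lg = ThreeParamLogistic(fix_bottom=0.0).fit(CONC.reshape(-1, 1), y)
            derived = -om.log_ka_ + np.log10(10.0 ** om.log_tau_ + 1.0)
            assert abs(lg.pec50_ - derived) < 0.05

    def test_unit_rescaling_scales_em_only(self):
        y = operational_response(CONC, 0.5, -7.0, 100.0, 0.0)
        a = OperationalModel(log_ka=-7.0, bottom=0.0).fit(CONC.reshape(-1, 1), y)
        b = OperationalModel(log_ka=-7.0, bottom=0.0).fit(CONC.reshape(-1, 1), 2.5 * y)
        assert b.log_tau_ == pytest.approx(a.log_tau_, abs=1e-6)
        assert b.em_ == pytest.approx(2.5 * a.em_, rel=1e-6)


class TestFitOperationalPanel:
    def test_simulated_refit_recovers_log_tau(self, wt_camp_dataset, true_binding):
        fits = fit_operational(wt_camp_dataset.response, binding=true_binding,
                               noise_floor=5.0)
        truth = wt_camp_dataset.truth.functional.set_index("ligand_id")["log_tau"]
        for lig, fit in fits.items():
            assert fit.status is FitStatus.ka_fixed
            assert fit.log_tau == pytest.approx(truth[lig], abs=0.15)
            assert fit.n_experiments == 5
            assert fit.sem_log_ka == 0.0

    def test_flat_ligand_reported_no_response(self, true_binding):
        rng = np.random.default_rng(5)
        rows = []
        for e in (1, 2, 3, 4):
            for c in CONC:
                rows.append(("WT", "GLP-1", "iCa", e, 1, c,
                             operational_response(np.array([c]), 0.5, -8.0,
                                                  100.0, 0.0)[0]
                             * (1 + rng.normal(0, 0.05))))
                rows.append(("WT", "oxyntomodulin", "iCa", e, 1, c,
                             rng.normal(0, 0.5)))
        df = pd.DataFrame(rows, columns=["construct_id", "ligand_id", "pathway_id",
                                         "experiment_id", "replicate_id",
                                         "concentration", "response"])
        fits = fit_operational(df, binding=true_binding, noise_floor=5.0)
        assert fits["oxyntomodulin"].status is FitStatus.no_response
        assert fits["GLP-1"].status is FitStatus.ka_fixed

    def test_anchored_ka_uncertainty_propagates_into_tau_sem(self, wt_camp_dataset):
        from alascan.curves import fit_competition
        fitted = {l: fit_competition(g, 1e-9, 5e-10)
                  for l, g in wt_camp_dataset.binding.groupby("ligand_id")}
        fits = fit_operational(wt_camp_dataset.response, binding=fitted,
                               noise_floor=5.0)
        for fit in fits.values():
            assert fit.sem_log_tau_sys > 0
            assert fit.sem_log_tau >= fit.sem_log_tau_sys


class TestCorrectTau:
    def _fit(self, log_tau=0.40, sem=0.05):
        pe = pd.DataFrame({"experiment_id": [1, 2, 3],
                           "log_tau": [log_tau - 0.1, log_tau, log_tau + 0.1]})
        return OperationalFit(log_tau=log_tau, sem_log_tau=sem, status=FitStatus.ok,
                              per_experiment=pe)

    def test_full_expression_is_identity(self):
        corr = correct_tau(self._fit(), {"expression_fraction": 1.0, "sem": 0.0},
                           {"expression_fraction": 1.0, "sem": 0.0})
        assert corr.log_tau_c == pytest.approx(0.40)
        assert corr.sem_log_tau_c == pytest.approx(0.05)

    def test_half_expression_adds_log10_two(self):
        corr = correct_tau(self._fit(), {"expression_fraction": 0.5, "sem": 0.0},
                           {"expression_fraction": 1.0, "sem": 0.0})
        assert corr.log_tau_c == pytest.approx(0.40 + np.log10(2.0), abs=1e-12)

    def test_delta_method_sem_propagation(self):
        # hand-computed oracle: sqrt(0.05^2 + (0.08 / (0.80 * ln 10))^2)
        corr = correct_tau(self._fit(sem=0.05),
                           {"expression_fraction": 0.80, "sem": 0.08},
                           {"expression_fraction": 1.0, "sem": 0.0})
        assert corr.sem_log_tau_c == pytest.approx(0.0662278, abs=1e-6)
        assert corr.sem_log_tau_c >= 0.05

    def test_not_determined_expression_gives_reason(self):
        corr = correct_tau(self._fit(), {"expression_fraction": np.nan,
                                         "sem": np.nan, "status": "not_determined"},
                           {"expression_fraction": 1.0, "sem": 0.0})
        assert corr.status is FitStatus.not_determined
        assert "expression" in corr.reason
        assert np.isnan(corr.log_tau_c)

    def test_expression_compensation_recovers_intrinsic_tau(self):
        # a construct identical to WT except 40% surface expression: corrected
        # efficacy must return to the wild-type value
        import warnings
        from alascan.simulate import _build_truth, LIGANDS
        truth = _build_truth("t", {"WT": {}, "X1A": {"expression": 0.4}},
                             ("GLP-1",), ("cAMP",))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = generate_panel(truth, NoiseModel(seed=3))
        from alascan.pipeline import analyze
        from alascan.datamodel import RunConfig
        res = analyze(ds.response, ds.binding, ds.expression, RunConfig())
        tab = res.operational.set_index("construct_id")
        assert abs(tab.loc["X1A", "log_tau"] - tab.loc["WT", "log_tau"]) > 0.25
        assert abs(tab.loc["X1A", "log_tau_c"] - tab.loc["WT", "log_tau_c"]) < 0.15
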