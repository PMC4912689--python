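import warnings

import numpy as np
import pandas as pd
import pytest

from alascan.operational import operational_response
from alascan.simulate import (
    LIGANDS,
    NoiseModel,
    TruthPanel,
    default_grid,
    generate_panel,
    scenario_library,
    wild_type_truth,
)


class TestNoiseModel:
    def test_defaults_match_study_design(self):
        nm = NoiseModel()
        assert nm.n_experiments in range(4, 7)
        assert nm.n_duplicates == 2
        assert nm.cv == 0.05

    def test_rejects_negative_cv(self):
        with pytest.raises(ValueError):
            NoiseModel(cv=-0.1)


class TestGeneratePanel:
    def test_noiseless_tables_equal_model_means(self):
        truth = wild_type_truth(pathways=("cAMP",))
        ds = generate_panel(truth, NoiseModel(cv=0.0, experiment_effect_sd=0.0,
                                              expression_rel_sem=0.0,
                                              binding_sd=0.0, seed=0))
        t = truth.functional.set_index("ligand_id")
        for lig, g in ds.response.groupby("ligand_id"):
            expected = operational_response(
                g["concentration"].to_numpy(), t.loc[lig, "log_tau"],
                t.loc[lig, "log_ka"], t.loc[lig, "em"], t.loc[lig, "bottom"])
            assert np.allclose(g["response"].to_numpy(), expected, atol=1e-12)

    def test_same_seed_gives_byte_identical_csvs(self, tmp_path):
        truth = wild_type_truth(pathways=("cAMP",))
        a = generate_panel(truth, NoiseModel(seed=11))
        b = generate_panel(truth, NoiseModel(seed=11))
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for key in ("response", "binding", "expression"):
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_different_seeds_differ(self):
        truth = wild_type_truth(pathways=("cAMP",))
        a = generate_panel(truth, NoiseModel(seed=1))
        b = generate_panel(truth, NoiseModel(seed=2))
        assert not np.allclose(a.response["response"], b.response["response"])

    def test_replication_structure(self):
        truth = wild_type_truth(pathways=("cAMP",))
        ds = generate_panel(truth, NoiseModel(seed=0))
        counts = ds.response.groupby(["ligand_id", "experiment_id"])["replicate_id"]
        assert set(ds.response["experiment_id"]) == {1, 2, 3, 4, 5}
        assert set(ds.response["replicate_id"]) == {1, 2}
        # basal wells present for every curve
        assert (ds.response["concentration"] == 0).groupby(
            ds.response["ligand_id"]).sum().min() > 0

    def test_uncovered_ec50_warns(self):
        truth = wild_type_truth(pathways=("cAMP",))
        with pytest.warns(UserWarning, match="does not cover"):
            generate_panel(truth, NoiseModel(seed=0),
                           grid=np.logspace(-13, -10, 8))

    def test_small_grid_rejected(self):
        truth = wild_type_truth(pathways=("cAMP",))
        with pytest.raises(ValueError, match="6 distinct"):
            generate_panel(truth, NoiseModel(seed=0), grid=np.logspace(-9, -6, 4))

    def test_truth_round_trips_through_json(self, tmp_path):
        truth = scenario_library()["efficacy_ladder"]
        back = TruthPanel.from_dict(truth.to_dict())
        pd.testing.assert_frame_equal(back.functional, truth.functional)
        pd.testing.assert_frame_equal(back.binding, truth.binding)


class TestScenarioLibrary:
    def test_every_scenario_has_wild_type_and_finite_truths(self):
        lib = scenario_library()
        assert set(lib) >= {"baseline", "oxyntomodulin_bias", "efficacy_ladder",
                            "affinity_ladder", "expression_deficit",
                            "enhanced_efficacy", "dead_surface", "full_panel"}
        for truth in lib.values():
            assert "WT" in set(truth.constructs["construct_id"])
            assert np.isfinite(truth.functional["log_tau"]).all()
            assert np.isfinite(truth.binding["pki"]).all()

    def test_bias_truth_encodes_ten_fold_perk_bias(self):
        truth = scenario_library()["oxyntomodulin_bias"]
        f = truth.functional.set_index(["ligand_id", "pathway_id"])
        tc = f["log_tau"] - f["log_ka"]
        dd = ((tc[("oxyntomodulin", "pERK")] - tc[("GLP-1", "pERK")])
              - (tc[("oxyntomodulin", "cAMP")] - tc[("GLP-1", "cAMP")]))
        assert dd == pytest.approx(1.0)

    def test_dead_surface_construct_not_determined(self):
        truth = scenario_library()["dead_surface"]
        row = truth.expression.set_index("construct_id").loc["W306A"]
        assert row["status"] == "not_determined"
        ds = generate_panel(truth, NoiseModel(seed=4))
        # no receptor: flat functional response and no displacement
        w = ds.response[ds.response.construct_id == "W306A"]
        assert w["response"].abs().max() < 1e-9
        b = ds.binding[ds.binding.construct_id == "W306A"]
        assert b["specific_binding"].abs().max() < 25.0

    def test_expression_deficit_scales_observed_tau_only(self):
        truth = scenario_library()["expression_deficit"]
        ds = generate_panel(truth, NoiseModel(cv=0.0, experiment_effect_sd=0.0,
                                              expression_rel_sem=0.0,
                                              binding_sd=0.0, seed=0))
        top = ds.response.groupby("construct_id")["response"].max()
        # 30% expression scales observed efficacy: the top-dose responses
        # must match the model evaluated at tau and 0.3*tau exactly
        t = truth.functional.set_index(["construct_id", "ligand_id"])
        a = operational_response(np.array([1e-6]),
                                 t.loc[("N300A", "GLP-1"), "log_tau"] + np.log10(0.3),
                                 t.loc[("N300A", "GLP-1"), "log_ka"], 100.0, 0.0)[0]
        b = operational_response(np.array([1e-6]),
                                 t.loc[("WT", "GLP-1"), "log_tau"],
                                 t.loc[("WT", "GLP-1"), "log_ka"], 100.0, 0.0)[0]
        assert top["N300A"] / top["WT"] == pytest.approx(a / b, abs=1e-9)
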