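"""Simulation-based validation studies of the whole pipeline.

Each function runs an end-to-end experiment against the synthetic-data
generator's known ground truth and reports summary metrics: parameter
recovery at the study's replication level, the tau_c expression-correction
contract, the calibration of Dunnett's test, and recovery of the built-in
biased-agonism truth. The test suite and the reproduction script both call
these, so the numbers they print always come from a fresh computation.

All seeds are derived deterministically from the single ``seed`` argument.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional

import numpy as np
from scipy import stats

from .compare import dunnett_mc, dunnett_test
from .curves import ThreeParamLogistic
from .datamodel import RunConfig
from .operational import OperationalModel, operational_response
from .pipeline import analyze
from .simulate import NoiseModel, generate_panel, scenario_library, wild_type_truth

__all__ = [
    "operational_selfconsistency",
    "parameter_recovery",
    "tau_c_contract",
    "dunnett_agreement",
    "familywise_error_rate",
    "bias_recovery",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def operational_selfconsistency(grid: Optional[np.ndarray] = None) -> Dict[str, float]:
    """Noiseless self-consistency of the operational model fit.

    Fits exact model curves over a grid of (log tau, log K_A) truths and
    reports the largest deviations from the analytic identities
    pEC50 = -logK_A + log10(tau + 1) (checked against an independent
    three-parameter logistic fit of the same data) and
    plateau = Bottom + (Em - Bottom) * tau / (tau + 1).
    """
    conc = np.concatenate([[0.0], np.logspace(-12, -6, 12)])
    max_pec50_err = 0.0
    max_plateau_err = 0.0
    for log_tau in (-0.5, 0.0, 0.7, 1.5):
        for log_ka in (-8.5, -7.5, -7.0):
            y = operational_response(conc, log_tau, log_ka, 100.0, 0.0)
            om = OperationalModel(log_ka=log_ka, bottom=0.0)
            om.fit(conc.reshape(-1, 1), y)
            lg = ThreeParamLogistic(fix_bottom=0.0)
            lg.fit(conc.reshape(-1, 1), y)
            derived = -om.log_ka_ + np.log10(10.0 ** om.log_tau_ + 1.0)
            max_pec50_err = max(max_pec50_err, abs(lg.pec50_ - derived))
            tau = 10.0 ** om.log_tau_
            plateau_pred = float(om.predict(np.array([[1e3]]))[0])  # saturating dose
            plateau_formula = om.bottom_ + (om.em_ - om.bottom_) * tau / (tau + 1.0)
            max_plateau_err = max(max_plateau_err, abs(plateau_pred - plateau_formula))
    return {"max_pec50_consistency_err": float(max_pec50_err),
            "max_plateau_identity_err": float(max_plateau_err)}


def parameter_recovery(n_seeds: int = 100, seed: int = 0) -> Dict[str, float]:
    """Simulate-and-refit recovery at the study design.

    Wild-type cAMP panels (three ligands, five independent experiments in
    duplicate, 5% CV) are generated and pushed through the full pipeline;
    reports the median absolute error of log tau and of pKi over all
    ligands and seeds.
    """
    truth = wild_type_truth(pathways=("cAMP",))
    true_tau = truth.functional.set_index(["ligand_id", "pathway_id"])["log_tau"]
    true_pki = truth.binding.set_index("ligand_id")["pki"]
    cfg = RunConfig()
    tau_err, pki_err = [], []
    for s in _child_seeds(seed, n_seeds):
        ds = generate_panel(truth, NoiseModel(seed=int(s)))
        res = analyze(ds.response, ds.binding, ds.expression, cfg)
        for r in res.operational.itertuples():
            if r.status in ("ok", "ka_fixed") and np.isfinite(r.log_tau):
                tau_err.append(abs(r.log_tau - true_tau[(r.ligand_id, r.pathway_id)]))
        for r in res.affinity.itertuples():
            if r.status == "ok":
                pki_err.append(abs(r.pki - true_pki[r.ligand_id]))
    return {"log_tau_median_abs_err": float(np.median(tau_err)),
            "pki_median_abs_err": float(np.median(pki_err)),
            "n_seeds": int(n_seeds)}


def tau_c_contract(n_seeds: int = 200, seed: int = 0) -> Dict[str, float]:
    """The defining property of the expression correction.

    An expression-only mutant (30% of wild-type surface expression,
    intrinsic tau unchanged) must be statistically indistinguishable from
    wild-type after correction — its log tau_c difference CI (t critical,
    propagated SEM) contains zero — while its *uncorrected* log tau is
    significantly reduced. Reports both fractions over simulated studies.
    """
    truth = scenario_library()["expression_deficit"]
    cfg = RunConfig()
    covered, raw_reduced = [], []
    for s in _child_seeds(seed, n_seeds):
        ds = generate_panel(truth, NoiseModel(seed=int(s)))
        res = analyze(ds.response, ds.binding, ds.expression, cfg)
        row = res.deltas[(res.deltas.construct_id == "N300A")
                         & (res.deltas.ligand_id == "GLP-1")
                         & (res.deltas.measure == "log_tau_c[cAMP]")].iloc[0]
        tcrit = stats.t.ppf(0.975, row.n_mut + row.n_wt - 2)
        covered.append(abs(row.delta) <= tcrit * row.sem_delta)
        wt_fit = res.operational_fits[("WT", "GLP-1", "cAMP")]
        mut_fit = res.operational_fits[("N300A", "GLP-1", "cAMP")]
        t = stats.ttest_ind(mut_fit.per_experiment["log_tau"],
                            wt_fit.per_experiment["log_tau"], alternative="less")
        raw_reduced.append(t.pvalue < cfg.alpha)
    return {"tau_c_within_wt_ci_frac": float(np.mean(covered)),
            "raw_tau_reduced_frac": float(np.mean(raw_reduced)),
            "n_seeds": int(n_seeds)}


#: fixed unbalanced-looking fixture for the analytic-vs-Monte-Carlo check
DUNNETT_FIXTURE = {
    "control": [10.1, 9.8, 10.3, 9.9],
    "mut1": [9.2, 9.6, 9.4, 9.0],
    "mut2": [10.0, 10.4, 9.7, 10.2],
    "mut3": [8.9, 9.1, 9.5, 9.3],
}


def dunnett_agreement(n_draws: int = 1_000_000, seed: int = 0) -> Dict[str, float]:
    """Largest |analytic - Monte-Carlo| adjusted p over the fixed fixture."""
    control = DUNNETT_FIXTURE["control"]
    groups = {k: v for k, v in DUNNETT_FIXTURE.items() if k != "control"}
    p_analytic, _ = dunnett_test(groups, control)
    p_mc = dunnett_mc(groups, control, n_draws=n_draws, seed=seed)
    diff = (p_analytic - p_mc).abs().max()
    return {"dunnett_mc_max_abs_diff": float(diff), "n_draws": int(n_draws)}


def familywise_error_rate(n_panels: int = 1000, k: int = 3, n: int = 5,
                          alpha: float = 0.05, seed: int = 0) -> Dict[str, float]:
    """Fraction of all-null panels with any Dunnett-significant mutant."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_panels):
        control = rng.standard_normal(n)
        groups = {f"g{i}": rng.standard_normal(n) for i in range(k)}
        pvals, _ = dunnett_test(groups, control)
        hits += int((pvals < alpha).any())
    return {"familywise_error_rate": hits / n_panels,
            "bound": alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_panels),
            "n_panels": int(n_panels)}


def bias_recovery(n_seeds: int = 100, seed: int = 0) -> Dict[str, float]:
    """Recovery of the built-in oxyntomodulin pERK bias (truth: +1.0 log).

    Reports the mean recovered DeltaDelta log(tau/K_A) toward pERK and the
    fraction of seeds in which its sign is positive.
    """
    truth = scenario_library()["oxyntomodulin_bias"]
    cfg = RunConfig()
    dd = []
    for s in _child_seeds(seed, n_seeds):
        ds = generate_panel(truth, NoiseModel(seed=int(s)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = analyze(ds.response, ds.binding, ds.expression, cfg)
        row = res.bias[(res.bias.ligand_id == "oxyntomodulin")
                       & (res.bias.pathway_id == "pERK")].iloc[0]
        dd.append(row.ddelta_log_tka)
    dd = np.asarray(dd)
    return {"ddelta_log_tka_mean": float(dd.mean()),
            "sign_positive_frac": float((dd > 0).mean()),
            "n_seeds": int(n_seeds)}
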