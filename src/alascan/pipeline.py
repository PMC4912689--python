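"""End-to-end analysis: tables in, comparison/bias/heat tables out.

The stages mirror the study's analysis: competition-binding fits give pKi;
operational-model fits (K_A anchored to binding under the default policy)
give log tau per pathway; tau is corrected to measured cell-surface
expression (tau_c); per-experiment values feed one-way ANOVA with Dunnett's
post-test against the wild-type; significant effects are binned into heat
categories; and the wild-type ligand panel yields DeltaDelta log(tau/K_A)
bias factors against the reference ligand and pathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import bias as bias_mod
from .compare import classify_heat_table, delta_vs_wildtype
from .curves import fit_competition, fit_logistic
from .datamodel import AffinityEstimate, FitStatus, OperationalFit, RunConfig
from .operational import correct_tau, fit_operational

__all__ = ["AnalysisResult", "analyze", "compute_bias"]

#: absolute response-window floor, in % of the wild-type system maximum:
#: curves spanning less than this are reported as no_response
NOISE_FLOOR = 5.0


@dataclass
class AnalysisResult:
    affinity: pd.DataFrame = field(default_factory=pd.DataFrame)
    operational: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_experiment: pd.DataFrame = field(default_factory=pd.DataFrame)
    deltas: pd.DataFrame = field(default_factory=pd.DataFrame)
    heat: pd.DataFrame = field(default_factory=pd.DataFrame)
    bias: pd.DataFrame = field(default_factory=pd.DataFrame)
    web: dict = field(default_factory=dict)
    affinity_fits: dict = field(default_factory=dict)
    operational_fits: dict = field(default_factory=dict)


def _expression_row(expression: pd.DataFrame, construct: str) -> Mapping:
    rows = expression.loc[expression["construct_id"] == construct]
    if rows.empty:
        return {"expression_fraction": np.nan, "sem": np.nan, "status": "not_determined"}
    return rows.iloc[0].to_dict()


def _log10_sem(x: float, sem: float) -> float:
    return sem / (x * math.log(10.0))


def analyze(response: pd.DataFrame, binding: pd.DataFrame,
            expression: pd.DataFrame, config: Optional[RunConfig] = None,
            include_logistic: bool = False) -> AnalysisResult:
    """Run the full pipeline on validated input tables.

    Parameters
    ----------
    response, binding, expression : validated input tables
        (see :mod:`alascan.io` for the schemas).
    config : analysis configuration; defaults encode the study design.
    include_logistic : also fit three-parameter logistic curves and add
        pEC50 / log10 Emax comparison families (slower; off by default).
    """
    config = config or RunConfig()
    result = AnalysisResult()
    wt = config.wild_type_id

    # ---- competition binding -> pKi ------------------------------------
    aff_fits: Dict[Tuple[str, str], AffinityEstimate] = {}
    aff_rows = []
    for (construct, ligand), g in binding.groupby(["construct_id", "ligand_id"]):
        fit = fit_competition(g, config.tracer_kd, config.tracer_conc)
        aff_fits[(construct, ligand)] = fit
        aff_rows.append(dict(construct_id=construct, ligand_id=ligand,
                             pic50=fit.pic50, pki=fit.pki, sem_pki=fit.sem_pki,
                             n_experiments=fit.n_experiments, status=fit.status.value))
    result.affinity = pd.DataFrame(aff_rows)
    result.affinity_fits = aff_fits

    # ---- operational model -> log tau, tau_c ---------------------------
    wt_expr = _expression_row(expression, wt)
    op_rows, pe_rows = [], []
    extra_sem: Dict[Tuple[str, str, str], float] = {}
    op_fits: Dict[Tuple[str, str, str], OperationalFit] = {}
    for (construct, pathway), g in response.groupby(["construct_id", "pathway_id"]):
        lig_binding = {l: aff_fits.get((construct, l)) for l in g["ligand_id"].unique()}
        lig_binding = {l: a for l, a in lig_binding.items() if a is not None}
        fits = fit_operational(
            g, ka_policy=config.ka_policy, em_policy=config.em_policy,
            binding=lig_binding, fix_bottom=config.fix_bottom,
            average_duplicates=config.average_duplicates, noise_floor=NOISE_FLOOR)
        expr = _expression_row(expression, construct)
        for ligand, fit in fits.items():
            op_fits[(construct, ligand, pathway)] = fit
            corr = correct_tau(fit, expr, wt_expr)
            measure = f"log_tau_c[{pathway}]"
            op_rows.append(dict(
                construct_id=construct, ligand_id=ligand, pathway_id=pathway,
                log_tau=fit.log_tau, sem_log_tau=fit.sem_log_tau,
                log_ka=fit.log_ka, sem_log_ka=fit.sem_log_ka,
                cov_log_tau_log_ka=fit.cov_log_tau_log_ka,
                log_tau_c=corr.log_tau_c, sem_log_tau_c=corr.sem_log_tau_c,
                em=fit.em, bottom=fit.bottom, n_experiments=fit.n_experiments,
                status=(corr.status.value
                        if corr.status is not FitStatus.ok else fit.status.value)))
            if corr.per_experiment is not None:
                for r in corr.per_experiment.itertuples():
                    pe_rows.append(dict(construct_id=construct, ligand_id=ligand,
                                        measure=measure,
                                        experiment_id=r.experiment_id,
                                        value=r.log_tau_c))
    result.operational = pd.DataFrame(op_rows)
    result.operational_fits = op_fits

    # error components shared across experiments (the expression ratio and
    # the anchored-K_A terms of mutant and wild-type) do not show up in the
    # per-experiment scatter; feed them into the delta SEM separately
    for (construct, ligand, pathway), fit in op_fits.items():
        if construct == wt:
            continue
        expr = _expression_row(expression, construct)
        e, se = expr.get("expression_fraction"), expr.get("sem", 0.0)
        w, sw = wt_expr.get("expression_fraction"), wt_expr.get("sem", 0.0)
        if not (np.isfinite(e) and np.isfinite(w)):
            continue
        expr_term = math.hypot(_log10_sem(float(e), float(se or 0.0)),
                               _log10_sem(float(w), float(sw or 0.0)))
        wt_fit = op_fits.get((wt, ligand, pathway))
        wt_sys = wt_fit.sem_log_tau_sys if wt_fit is not None else 0.0
        extra_sem[(construct, ligand, f"log_tau_c[{pathway}]")] = float(np.sqrt(
            expr_term**2 + fit.sem_log_tau_sys**2 + wt_sys**2))

    # ---- per-experiment value frame ------------------------------------
    for (construct, ligand), fit in aff_fits.items():
        if fit.per_experiment is not None:
            for r in fit.per_experiment.itertuples():
                pe_rows.append(dict(construct_id=construct, ligand_id=ligand,
                                    measure="pKi", experiment_id=r.experiment_id,
                                    value=r.pki))
    if include_logistic:
        for (construct, ligand, pathway), g in response.groupby(
                ["construct_id", "ligand_id", "pathway_id"]):
            lfit = fit_logistic(g, fix_bottom=config.fix_bottom,
                                average_duplicates=config.average_duplicates,
                                noise_floor=NOISE_FLOOR)
            if lfit.per_experiment is None:
                continue
            for r in lfit.per_experiment.itertuples():
                pe_rows.append(dict(construct_id=construct, ligand_id=ligand,
                                    measure=f"pEC50[{pathway}]",
                                    experiment_id=r.experiment_id, value=r.pec50))
                if r.top > 0:
                    pe_rows.append(dict(construct_id=construct, ligand_id=ligand,
                                        measure=f"log10_emax[{pathway}]",
                                        experiment_id=r.experiment_id,
                                        value=np.log10(r.top)))
    per_experiment = pd.DataFrame(
        pe_rows, columns=["construct_id", "ligand_id", "measure",
                          "experiment_id", "value"])
    result.per_experiment = per_experiment

    # ---- mutant vs wild-type -------------------------------------------
    if not per_experiment.empty and wt in set(per_experiment["construct_id"]):
        deltas = delta_vs_wildtype(per_experiment, wt, alpha=config.alpha,
                                   extra_sem=extra_sem)
        # mutants whose curve never rose above noise: floor annotation
        floor_rows = []
        for (construct, ligand, pathway), fit in op_fits.items():
            if construct == wt or fit.status is not FitStatus.no_response:
                continue
            measure = f"log_tau_c[{pathway}]"
            already = (not deltas.empty
                       and ((deltas["construct_id"] == construct)
                            & (deltas["ligand_id"] == ligand)
                            & (deltas["measure"] == measure)).any())
            if not already:
                floor_rows.append(dict(
                    construct_id=construct, ligand_id=ligand, measure=measure,
                    delta=np.nan, sem_delta=np.nan, anova_p=np.nan, p_adj=np.nan,
                    significant=True, fold_change=np.nan, direction="reduced",
                    n_mut=0, n_wt=0, status="not_determined"))
        if floor_rows:
            deltas = pd.concat([deltas, pd.DataFrame(floor_rows)], ignore_index=True)
        result.deltas = deltas
        if not deltas.empty:
            heat = _classify_with_floor(deltas, op_fits, config, wt)
            # constructs with no measurable surface expression cannot be
            # floor-annotated: nothing was assayed, so they stay N.D.
            nd_constructs = set(
                expression.loc[expression.get("status", "ok") == "not_determined",
                               "construct_id"])
            if nd_constructs:
                mask = (heat["construct_id"].isin(nd_constructs)
                        & heat["measure"].str.startswith("log_tau_c["))
                heat.loc[mask, "category"] = "not_determined"
                heat.loc[mask, "category_code"] = -1
            result.heat = heat

    # ---- bias (wild-type ligand panel) ---------------------------------
    wt_ops = result.operational[
        (result.operational["construct_id"] == wt)
        & result.operational["status"].isin(["ok", "ka_fixed"])]
    if not wt_ops.empty:
        try:
            result.bias = compute_bias(wt_ops, config)
            result.web = bias_mod.web_of_bias(result.bias)
        except bias_mod.MissingReferenceError:
            pass
    return result


def _wt_window_ok(op_fits, config: RunConfig, wt: str, ligand: str, pathway: str) -> bool:
    """Can an undetectable mutant response be called a >30-fold loss?

    A curve is undetectable when its window falls below the noise floor,
    which bounds its tau at tau_floor = floor / (Em - floor). The floor
    annotation is justified when the wild-type tau exceeds the top fold bin
    times that bound.
    """
    fit = op_fits.get((wt, ligand, pathway))
    if fit is None or not np.isfinite(fit.log_tau) or not np.isfinite(fit.em):
        return False
    if fit.em <= NOISE_FLOOR:
        return False
    tau_floor = NOISE_FLOOR / (fit.em - NOISE_FLOOR)
    top_bin = max(config.fold_bins)
    return 10.0 ** fit.log_tau / tau_floor >= top_bin


def _classify_with_floor(deltas: pd.DataFrame, op_fits, config: RunConfig,
                         wt: str) -> pd.DataFrame:
    rows = []
    for _, chunk in deltas.groupby(["ligand_id", "measure"], sort=False):
        measure = chunk["measure"].iloc[0]
        ligand = chunk["ligand_id"].iloc[0]
        window_ok = True
        if measure.startswith("log_tau_c["):
            pathway = measure[len("log_tau_c["):-1]
            window_ok = _wt_window_ok(op_fits, config, wt, ligand, pathway)
        rows.append(classify_heat_table(chunk, bins=config.fold_bins,
                                        wt_window_ok=window_ok))
    return pd.concat(rows, ignore_index=True)


def compute_bias(operational: pd.DataFrame, config: RunConfig,
                 pathway_backgrounds: Optional[Mapping[str, str]] = None,
                 assert_matched_expression: bool = False,
                 use_corrected_tau: bool = True) -> pd.DataFrame:
    """Transduction coefficients and bias factors for one construct's panel.

    ``operational`` is the fitted table restricted to a single construct.
    Cross-pathway DeltaDelta values are only meaningful when all pathways
    were assayed in the same cell background; if ``pathway_backgrounds``
    declares more than one background, the computation refuses unless the
    caller asserts matched receptor expression.

    ``use_corrected_tau=False`` substitutes raw log tau for log tau_c
    (sensitivity mode).
    """
    if pathway_backgrounds:
        backgrounds = {pathway_backgrounds.get(p) for p in operational["pathway_id"].unique()}
        if len(backgrounds) > 1 and not assert_matched_expression:
            raise ValueError(
                "pathways were assayed in different cell backgrounds "
                f"({sorted(b for b in backgrounds if b)}); cross-pathway bias factors "
                "require matched receptor expression — pass "
                "assert_matched_expression=True to proceed")
    table = operational.copy()
    if not use_corrected_tau:
        table["log_tau_c"] = table["log_tau"]
        table["sem_log_tau_c"] = table["sem_log_tau"]
    tc = bias_mod.transduction_coefficients(table)
    return bias_mod.bias_factors(tc, config.reference_ligand_id,
                                 config.reference_pathway_id)
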