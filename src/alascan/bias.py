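"""Biased-agonism quantification via transduction coefficients.

The transduction coefficient log(tau/K_A) = log tau_c - log K_A is a
system-independent composite of efficacy and functional affinity. Bias is
quantified by double normalization:

    Delta log(tau/K_A)      = value(ligand) - value(reference ligand), within a pathway
    DeltaDelta log(tau/K_A) = Delta(pathway) - Delta(reference pathway), within a ligand

A nonzero DeltaDelta means the ligand redistributes its signaling between
pathways relative to the reference ligand; 10**DeltaDelta is the bias
factor plotted on the spokes of a "web of bias" radar chart. The double
normalization cancels both system bias (cell background, receptor number)
and observation bias (assay amplification), which is also what makes the
quantity invariant to pathway-wide response rescaling.

SEMs are propagated in quadrature; the tau-K_A covariance of a joint fit
enters the coefficient's variance as var(tau) + var(K_A) - 2 cov.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["transduction_coefficients", "bias_factors", "web_of_bias",
           "bias_difference_test"]


class MissingReferenceError(KeyError):
    """A reference ligand or pathway cell required for normalization is absent."""


def transduction_coefficients(fits: pd.DataFrame) -> pd.DataFrame:
    """Compute log(tau/K_A) per ligand x pathway from fitted parameters.

    ``fits`` needs columns ``ligand_id, pathway_id, log_tau_c,
    sem_log_tau_c, log_ka, sem_log_ka, cov_log_tau_log_ka, status``; rows
    whose status is not ``ok``/``ka_fixed`` are dropped and listed in the
    frame's ``attrs["skipped"]``.
    """
    ok = fits["status"].isin(["ok", "ka_fixed"])
    skipped = fits.loc[~ok, ["ligand_id", "pathway_id", "status"]]
    use = fits.loc[ok].copy()
    var = (use["sem_log_tau_c"].fillna(0.0) ** 2
           + use["sem_log_ka"].fillna(0.0) ** 2
           - 2.0 * use["cov_log_tau_log_ka"].fillna(0.0))
    out = pd.DataFrame({
        "ligand_id": use["ligand_id"],
        "pathway_id": use["pathway_id"],
        "log_tau_over_ka": use["log_tau_c"] - use["log_ka"],
        "sem": np.sqrt(np.clip(var, 0.0, np.inf)),
    }).reset_index(drop=True)
    out.attrs["skipped"] = skipped.to_dict("records")
    return out


def bias_factors(tc: pd.DataFrame, reference_ligand: str,
                 reference_pathway: str) -> pd.DataFrame:
    """Normalize transduction coefficients to a reference ligand and pathway.

    Returns one row per ligand x pathway with ``delta_log_tka`` (vs the
    reference ligand within the pathway), ``ddelta_log_tka`` (vs the
    reference pathway within the ligand) and quadrature SEMs. Reference
    rows are exact zeros by construction: the reference ligand's delta
    carries the SEM of its own replicates, and every ligand's ddelta at the
    reference pathway is 0.
    """
    tc = tc.set_index(["ligand_id", "pathway_id"], drop=False)
    if tc.index.has_duplicates:
        raise ValueError("one transduction coefficient per ligand x pathway expected")
    pathways = tc["pathway_id"].unique().tolist()
    ligands = tc["ligand_id"].unique().tolist()
    for p in pathways:
        if (reference_ligand, p) not in tc.index:
            raise MissingReferenceError(
                f"reference ligand {reference_ligand!r} not measured at pathway {p!r}")
    for l in ligands:
        if (l, reference_pathway) not in tc.index:
            raise MissingReferenceError(
                f"ligand {l!r} not measured at reference pathway {reference_pathway!r}")

    rows = []
    for l in ligands:
        for p in pathways:
            if (l, p) not in tc.index:
                continue
            r = tc.loc[(l, p)]
            ref_l = tc.loc[(reference_ligand, p)]
            if l == reference_ligand:
                delta, sem_delta = 0.0, float(r["sem"])
            else:
                delta = float(r["log_tau_over_ka"] - ref_l["log_tau_over_ka"])
                sem_delta = float(np.hypot(r["sem"], ref_l["sem"]))
            rows.append(dict(ligand_id=l, pathway_id=p,
                             log_tau_over_ka=float(r["log_tau_over_ka"]),
                             delta_log_tka=delta, sem_delta=sem_delta))
    out = pd.DataFrame(rows).set_index(["ligand_id", "pathway_id"], drop=False)
    dd, sdd = [], []
    for _, r in out.iterrows():
        ref_p = out.loc[(r["ligand_id"], reference_pathway)]
        if r["pathway_id"] == reference_pathway:
            dd.append(0.0)
            sdd.append(float(r["sem_delta"]))
        else:
            dd.append(float(r["delta_log_tka"] - ref_p["delta_log_tka"]))
            sdd.append(float(np.hypot(r["sem_delta"], ref_p["sem_delta"])))
    out["ddelta_log_tka"] = dd
    out["sem_ddelta"] = sdd
    out["reference_ligand_id"] = reference_ligand
    out["reference_pathway_id"] = reference_pathway
    return out.reset_index(drop=True)


def web_of_bias(bias: pd.DataFrame, pathway_order: Optional[Sequence[str]] = None) -> dict:
    """Radar-plot payload: one polygon per ligand, one spoke per pathway.

    Spoke values are the bias factors 10**DeltaDelta log(tau/K_A), meant to
    be drawn on a logarithmic radial scale.
    """
    if pathway_order is None:
        pathway_order = list(dict.fromkeys(bias["pathway_id"]))
    polygons = {}
    for ligand, g in bias.groupby("ligand_id", sort=False):
        g = g.set_index("pathway_id")
        polygons[str(ligand)] = [
            float(10.0 ** g.loc[p, "ddelta_log_tka"]) if p in g.index else None
            for p in pathway_order
        ]
    return {
        "spokes": list(pathway_order),
        "scale": "log",
        "reference_ligand_id": str(bias["reference_ligand_id"].iloc[0]),
        "reference_pathway_id": str(bias["reference_pathway_id"].iloc[0]),
        "bias_factors": polygons,
    }


def bias_difference_test(bias: pd.DataFrame, ligand_a: str, ligand_b: str,
                         pathway: str, n_a: int, n_b: int) -> dict:
    """Two-sided Welch t-test on DeltaDelta log(tau/K_A) between two ligands.

    Uses the propagated SEMs and Welch-Satterthwaite degrees of freedom
    computed from the experiment counts ``n_a``/``n_b``.
    """
    g = bias.set_index(["ligand_id", "pathway_id"])
    a = g.loc[(ligand_a, pathway)]
    b = g.loc[(ligand_b, pathway)]
    diff = float(a["ddelta_log_tka"] - b["ddelta_log_tka"])
    se = float(np.hypot(a["sem_ddelta"], b["sem_ddelta"]))
    va, vb = float(a["sem_ddelta"]) ** 2, float(b["sem_ddelta"]) ** 2
    if se == 0:
        return {"difference": diff, "se": 0.0, "t": np.inf, "df": np.nan, "p": 0.0}
    df = (va + vb) ** 2 / (va**2 / max(n_a - 1, 1) + vb**2 / max(n_b - 1, 1))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"difference": diff, "se": se, "t": float(t), "df": float(df), "p": float(p)}
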