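"""Operational-model (Black-Leff) efficacy estimation and expression correction.

The model, with transducer slope fixed to 1:

    Y = Bottom + (Em - Bottom) / (1 + (10**logK_A + 10**log[A]) / 10**(log tau + log[A]))

where Bottom is the response in the absence of ligand, Em the maximal
stimulation the system can produce, K_A the functional agonist-receptor
dissociation constant, and tau the operational efficacy (coupling capacity
of the agonist-occupied receptor, proportional to receptor density).

Identifiability note: for a single agonist curve this model is an exact
reparameterization of the three-parameter logistic
(Top = Bottom + (Em - Bottom) * tau/(tau+1), EC50 = K_A/(tau+1)), so Em,
tau and K_A lie on a one-dimensional likelihood ridge and cannot all be
estimated from functional data alone. The default policy therefore anchors
logK_A to the binding-derived affinity (-pKi) — the standard practice for
agonists whose functional and binding affinities agree — which makes tau and
Em per-curve identifiable. A free-K_A mode (``ka_policy="fit"``) is kept for
sensitivity analyses; its per-parameter estimates are ridge-limited and are
flagged accordingly.

tau estimates are subsequently normalized to measured relative cell-surface
expression, giving tau_c = tau / (expression / expression_WT); errors are
propagated from both the tau fit and the expression measurement.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .curves import _average_duplicates, _duplicate_noise_sd, _pool
from .datamodel import AffinityEstimate, CorrectedEfficacy, FitStatus, OperationalFit

__all__ = [
    "operational_response",
    "OperationalModel",
    "fit_operational",
    "correct_tau",
]

LOG_TAU_BOUNDS = (-3.0, 4.0)
LOG_KA_BOUNDS = (-12.0, -4.0)


def operational_response(conc, log_tau: float, log_ka: float,
                         em: float, bottom: float) -> np.ndarray:
    """Evaluate the operational model on molar concentration; conc == 0 -> Bottom."""
    conc = np.asarray(conc, dtype=float)
    out = np.full(conc.shape, float(bottom))
    pos = conc > 0
    a = conc[pos]
    occ = (10.0 ** log_ka + a) / (10.0 ** log_tau * a)
    out[pos] = bottom + (em - bottom) / (1.0 + occ)
    return out


class OperationalModel(RegressorMixin, BaseEstimator):
    """Single-curve operational-model regressor (scikit-learn interface).

    Any of ``log_ka``, ``em``, ``bottom`` may be fixed by passing a float;
    ``None`` leaves the parameter free. ``log_tau`` is always estimated.
    With all three free the problem is ridge-degenerate (see module
    docstring); the estimator still returns the least-squares point reached
    from data-driven starts, with ``ridge_limited_`` set to True.
    """

    def __init__(self, log_ka: Optional[float] = None, em: Optional[float] = None,
                 bottom: Optional[float] = None, n_starts: int = 3):
        self.log_ka = log_ka
        self.em = em
        self.bottom = bottom
        self.n_starts = n_starts

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=4)
        conc = X[:, 0]
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0")
        free = ["log_tau"]
        if self.log_ka is None:
            free.append("log_ka")
        if self.em is None:
            free.append("em")
        if self.bottom is None:
            free.append("bottom")

        ymin, ymax = float(np.min(y)), float(np.max(y))
        span = ymax - ymin if ymax > ymin else 1.0

        def unpack(theta):
            v = dict(zip(free, theta))
            return (v["log_tau"], v.get("log_ka", self.log_ka),
                    v.get("em", self.em), v.get("bottom", self.bottom))

        def residual(theta):
            return operational_response(conc, *unpack(theta)) - y

        pos = conc > 0
        logc = np.log10(conc[pos])
        half = ymin + 0.5 * span
        crossing = logc[np.argmin(np.abs(y[pos] - half))]

        lo, hi, starts0 = [], [], {}
        for name in free:
            if name == "log_tau":
                lo.append(LOG_TAU_BOUNDS[0]); hi.append(LOG_TAU_BOUNDS[1])
                starts0[name] = 0.5
            elif name == "log_ka":
                lo.append(LOG_KA_BOUNDS[0]); hi.append(LOG_KA_BOUNDS[1])
                starts0[name] = float(np.clip(crossing + 0.5, *LOG_KA_BOUNDS))
            elif name == "em":
                lo.append(ymin); hi.append(ymax + 4 * span)
                starts0[name] = ymax * 1.1 if ymax > 0 else ymax + 0.1 * span
            else:
                lo.append(ymin - span); hi.append(ymax)
                starts0[name] = ymin
        bounds = (np.array(lo), np.array(hi))

        best = None
        for s in np.linspace(-1.0, 1.0, max(int(self.n_starts), 1)):
            x0 = np.array([starts0[n] + (s if n == "log_tau" else 0.0) for n in free])
            x0 = np.clip(x0, bounds[0], bounds[1])
            try:
                sol = least_squares(residual, x0, bounds=bounds, method="trf")
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            self.converged_ = False
            self.log_tau_ = self.log_ka_ = self.em_ = self.bottom_ = np.nan
            return self

        self.log_tau_, self.log_ka_, self.em_, self.bottom_ = unpack(best.x)
        n_par = len(free)
        dof = max(y.size - n_par, 1)
        s2 = 2.0 * best.cost / dof
        cov = np.linalg.pinv(best.jac.T @ best.jac) * s2
        se = dict(zip(free, np.sqrt(np.clip(np.diag(cov), 0, np.inf))))
        self.sem_log_tau_ = float(se.get("log_tau", np.nan))
        self.sem_log_ka_ = float(se.get("log_ka", 0.0))
        if "log_ka" in free:
            i, j = free.index("log_tau"), free.index("log_ka")
            self.cov_log_tau_log_ka_ = float(cov[i, j])
        else:
            self.cov_log_tau_log_ka_ = 0.0
        self.converged_ = bool(best.success)
        self.ridge_limited_ = {"log_ka", "em"}.issubset(free)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "log_tau_")
        X = check_array(X)
        return operational_response(X[:, 0], self.log_tau_, self.log_ka_,
                                    self.em_, self.bottom_)


# --------------------------------------------------------------------------
# panel fitting: all ligands of one construct x pathway
# --------------------------------------------------------------------------

def _fit_experiment_joint(groups: Dict[str, pd.DataFrame], ka_fixed: Dict[str, Optional[float]],
                          em_policy: str, fix_bottom: Optional[float]):
    """Joint least-squares over the ligands of one experiment.

    With ``em_policy="shared_per_pathway"`` a single (Em, Bottom) pair is
    shared by every ligand; ``"per_curve"`` gives each ligand its own.
    Returns per-ligand parameter dicts or None on failure.
    """
    ligands = sorted(groups)
    names = []  # flat parameter vector layout
    if em_policy == "shared_per_pathway":
        names.append(("em", None))
        if fix_bottom is None:
            names.append(("bottom", None))
    for lig in ligands:
        names.append(("log_tau", lig))
        if ka_fixed[lig] is None:
            names.append(("log_ka", lig))
        if em_policy == "per_curve":
            names.append(("em", lig))
            if fix_bottom is None:
                names.append(("bottom", lig))

    ally = np.concatenate([groups[l]["response"].to_numpy() for l in ligands])
    ymin, ymax = float(ally.min()), float(ally.max())
    span = ymax - ymin if ymax > ymin else 1.0

    def split(theta):
        v = dict(zip(names, theta))
        out = {}
        for lig in ligands:
            em = v.get(("em", lig), v.get(("em", None)))
            bottom = fix_bottom if fix_bottom is not None else \
                v.get(("bottom", lig), v.get(("bottom", None)))
            ka = ka_fixed[lig] if ka_fixed[lig] is not None else v[("log_ka", lig)]
            out[lig] = (v[("log_tau", lig)], ka, em, bottom)
        return out

    def residual(theta):
        params = split(theta)
        res = []
        for lig in ligands:
            g = groups[lig]
            res.append(operational_response(g["concentration"].to_numpy(), *params[lig])
                       - g["response"].to_numpy())
        return np.concatenate(res)

    lo, hi, x0 = [], [], []
    for kind, lig in names:
        if kind == "log_tau":
            lo.append(LOG_TAU_BOUNDS[0]); hi.append(LOG_TAU_BOUNDS[1]); x0.append(0.5)
        elif kind == "log_ka":
            g = groups[lig]
            pos = g["concentration"] > 0
            logc = np.log10(g.loc[pos, "concentration"].to_numpy())
            yv = g.loc[pos, "response"].to_numpy()
            half = ymin + 0.5 * (yv.max() - ymin if yv.max() > ymin else span)
            crossing = logc[np.argmin(np.abs(yv - half))]
            lo.append(LOG_KA_BOUNDS[0]); hi.append(LOG_KA_BOUNDS[1])
            x0.append(float(np.clip(crossing + 0.5, *LOG_KA_BOUNDS)))
        elif kind == "em":
            lo.append(ymin); hi.append(ymax + 4 * span)
            x0.append(ymax * 1.1 if ymax > 0 else ymax + 0.1 * span)
        else:  # bottom
            lo.append(ymin - span); hi.append(ymax)
            x0.append(ymin)
    bounds = (np.array(lo), np.array(hi))
    x0 = np.clip(np.array(x0), bounds[0], bounds[1])

    best = None
    for shift in (0.0, -1.0, 1.0):
        start = x0.copy()
        for i, (kind, _) in enumerate(names):
            if kind == "log_tau":
                start[i] = np.clip(start[i] + shift, *LOG_TAU_BOUNDS)
        try:
            sol = least_squares(residual, start, bounds=bounds, method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return None

    dof = max(ally.size - len(names), 1)
    s2 = 2.0 * best.cost / dof
    cov = np.linalg.pinv(best.jac.T @ best.jac) * s2
    params = split(best.x)
    idx = {nm: i for i, nm in enumerate(names)}
    result = {}
    for lig in ligands:
        log_tau, ka, em, bottom = params[lig]
        i_tau = idx[("log_tau", lig)]
        cov_tk = 0.0
        if ("log_ka", lig) in idx:
            cov_tk = float(cov[i_tau, idx[("log_ka", lig)]])
        result[lig] = {
            "log_tau": float(log_tau), "log_ka": float(ka),
            "em": float(em), "bottom": float(bottom),
            "cov_log_tau_log_ka": cov_tk,
            "at_tau_bound": bool(log_tau >= LOG_TAU_BOUNDS[1] - 0.05),
            "success": bool(best.success),
        }
    return result


def fit_operational(curves: pd.DataFrame, *, ka_policy: str = "fix_to_binding",
                    em_policy: str = "shared_per_pathway",
                    binding: Optional[Mapping[str, AffinityEstimate]] = None,
                    fix_bottom: Optional[float] = None,
                    average_duplicates: bool = True,
                    noise_floor: Optional[float] = None) -> Dict[str, OperationalFit]:
    """Fit the operational model to all ligands of one construct x pathway.

    ``curves`` is a tidy frame with columns ``ligand_id, experiment_id,
    replicate_id, concentration, response`` restricted to a single construct
    and pathway. Each independent experiment is fitted jointly across
    ligands (Em/Bottom shared under the default policy) and parameters are
    pooled as mean +/- SEM over experiments.

    With ``ka_policy="fix_to_binding"``, logK_A of each ligand is fixed to
    ``-binding[ligand].pki``; ligands without a usable affinity estimate
    fall back to a free K_A. Flat curves (response window below the noise
    floor) are reported as ``no_response`` and excluded from the joint fit.
    """
    if ka_policy not in {"fit", "fix_to_binding"}:
        raise ValueError(f"unknown ka_policy {ka_policy!r}")
    binding = binding or {}
    fits: Dict[str, OperationalFit] = {}
    meta = curves[["construct_id", "pathway_id"]].iloc[0] if len(curves) else None

    # response-window screen per ligand
    active = {}
    for lig, g in curves.groupby("ligand_id"):
        dup_sd = _duplicate_noise_sd(g, "concentration", "response")
        floor = noise_floor
        if floor is None:
            floor = 4.0 * dup_sd if np.isfinite(dup_sd) and dup_sd > 0 else 5.0
        spans = []
        per_exp = {}
        for exp_id, ge in g.groupby("experiment_id"):
            if average_duplicates:
                ge = _average_duplicates(ge, "concentration", "response")
            spans.append(ge["response"].max() - ge["response"].min())
            per_exp[exp_id] = ge
        if not spans or np.median(spans) < floor:
            fits[lig] = OperationalFit(
                construct_id=str(meta["construct_id"]) if meta is not None else "",
                ligand_id=lig,
                pathway_id=str(meta["pathway_id"]) if meta is not None else "",
                status=FitStatus.no_response, n_experiments=len(per_exp))
        else:
            active[lig] = per_exp

    if not active:
        return fits

    ka_fixed: Dict[str, Optional[float]] = {}
    for lig in active:
        ka_fixed[lig] = None
        if ka_policy == "fix_to_binding":
            aff = binding.get(lig)
            if aff is not None and aff.status is FitStatus.ok and np.isfinite(aff.pki):
                ka_fixed[lig] = -float(aff.pki)

    exp_ids = sorted({e for per_exp in active.values() for e in per_exp})
    rows: Dict[str, list] = {lig: [] for lig in active}
    for exp_id in exp_ids:
        groups = {lig: per_exp[exp_id] for lig, per_exp in active.items()
                  if exp_id in per_exp}
        if not groups:
            continue
        res = _fit_experiment_joint(groups, {l: ka_fixed[l] for l in groups},
                                    em_policy, fix_bottom)
        if res is None:
            continue
        for lig, p in res.items():
            p["experiment_id"] = exp_id
            rows[lig].append(p)

    for lig, recs in rows.items():
        per_exp = pd.DataFrame(recs)
        construct = str(meta["construct_id"]) if meta is not None else ""
        pathway = str(meta["pathway_id"]) if meta is not None else ""
        if per_exp.empty:
            fits[lig] = OperationalFit(construct_id=construct, ligand_id=lig,
                                       pathway_id=pathway,
                                       status=FitStatus.not_converged)
            continue
        log_tau, sem_log_tau = _pool(per_exp["log_tau"])
        log_ka, sem_log_ka = _pool(per_exp["log_ka"])
        em, _ = _pool(per_exp["em"])
        bottom, _ = _pool(per_exp["bottom"])
        n = len(per_exp)
        sem_sys = 0.0
        if ka_fixed[lig] is not None:
            status = FitStatus.ka_fixed
            sem_log_ka = 0.0
            cov = 0.0
            # the anchored K_A carries the binding fit's uncertainty into
            # log tau with sensitivity dlog(tau)/dlog(K_A) = (tau+1)/tau;
            # it is common to every experiment, so it adds to the pooled SEM
            # rather than to the per-experiment scatter
            aff = binding.get(lig)
            if aff is not None and np.isfinite(aff.sem_pki) and np.isfinite(log_tau):
                tau = 10.0 ** log_tau
                sem_sys = (tau + 1.0) / tau * float(aff.sem_pki)
                sem_log_tau = float(np.hypot(sem_log_tau, sem_sys)) \
                    if np.isfinite(sem_log_tau) else sem_sys
        else:
            status = FitStatus.ok
            # covariance of the pooled means across experiments
            if n > 1:
                cov = float(np.cov(per_exp["log_tau"], per_exp["log_ka"])[0, 1] / n)
            else:
                cov = float(per_exp["cov_log_tau_log_ka"].iloc[0])
        if per_exp["at_tau_bound"].all():
            status = FitStatus.not_converged
        fits[lig] = OperationalFit(
            construct_id=construct, ligand_id=lig, pathway_id=pathway,
            log_tau=log_tau, log_ka=log_ka, em=em, bottom=bottom,
            sem_log_tau=sem_log_tau, sem_log_tau_sys=sem_sys,
            sem_log_ka=sem_log_ka,
            cov_log_tau_log_ka=cov, n_experiments=n, status=status,
            per_experiment=per_exp,
        )
    return fits


# --------------------------------------------------------------------------
# expression correction
# --------------------------------------------------------------------------

def _log10_sem(x: float, sem: float) -> float:
    """Delta-method conversion of an arithmetic SEM to the log10 scale."""
    return sem / (x * math.log(10.0))


def correct_tau(fit: OperationalFit, expr: Mapping, wt_expr: Mapping) -> CorrectedEfficacy:
    """Normalize log tau to relative cell-surface expression.

    log tau_c = log tau - log10(expr / expr_WT); lower expression than
    wild-type therefore *raises* the corrected efficacy, isolating intrinsic
    coupling from receptor number. SEMs of the expression fractions are
    moved to the log10 scale by the delta method and combined with the tau
    SEM in quadrature (independence assumed).

    ``expr`` / ``wt_expr`` need keys ``expression_fraction``, ``sem`` and
    optionally ``status``.
    """
    if str(expr.get("status", "ok")) == "not_determined" or \
            not np.isfinite(expr.get("expression_fraction", np.nan)):
        return CorrectedEfficacy(status=FitStatus.not_determined,
                                 reason="no measurable cell-surface expression")
    if fit.status in (FitStatus.no_response, FitStatus.not_converged):
        return CorrectedEfficacy(status=fit.status,
                                 reason=f"tau fit status {fit.status.value}")

    e, se = float(expr["expression_fraction"]), float(expr.get("sem", 0.0) or 0.0)
    w, sw = float(wt_expr["expression_fraction"]), float(wt_expr.get("sem", 0.0) or 0.0)
    if e <= 0 or w <= 0:
        raise ValueError("expression fractions must be positive")
    shift = math.log10(e / w)
    sem_ratio = math.hypot(_log10_sem(e, se), _log10_sem(w, sw))
    sem_tau = fit.sem_log_tau if np.isfinite(fit.sem_log_tau) else 0.0
    per_exp = None
    if fit.per_experiment is not None:
        per_exp = fit.per_experiment[["experiment_id", "log_tau"]].copy()
        per_exp["log_tau_c"] = per_exp["log_tau"] - shift
    return CorrectedEfficacy(
        log_tau_c=fit.log_tau - shift,
        sem_log_tau_c=math.hypot(sem_tau, sem_ratio),
        expression_fraction_used=e / w,
        status=FitStatus.ok,
        per_experiment=per_exp,
    )
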