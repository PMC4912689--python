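"""Concentration-response and competition-binding curve fitting.

Two scikit-learn style estimators do the single-curve work:

* :class:`ThreeParamLogistic` — the three-parameter logistic
  ``Y = Bottom + (Top - Bottom) / (1 + 10**(logEC50 - log10[A]))`` with the
  Hill slope fixed to 1, fitted on molar concentrations,
* :class:`OneSiteCompetition` — one-site competition binding
  ``B = Bottom + (Top - Bottom) / (1 + 10**(log[A] - logIC50))`` fitted on
  log10 molar competitor concentrations.

The module-level :func:`fit_logistic` and :func:`fit_competition` wrap them
for the study design: each independent experiment is fitted separately
(technical duplicates averaged first) and parameters are pooled as
mean +/- SEM across experiments. :func:`fit_competition` converts pIC50 to
pKi with the Cheng-Prusoff correction.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .datamodel import AffinityEstimate, FitStatus, LogisticFit

__all__ = [
    "ThreeParamLogistic",
    "OneSiteCompetition",
    "fit_logistic",
    "fit_competition",
    "cheng_prusoff",
]


def logistic3(conc: np.ndarray, pec50: float, top: float, bottom: float) -> np.ndarray:
    """Three-parameter logistic on molar concentration; conc == 0 -> bottom."""
    conc = np.asarray(conc, dtype=float)
    out = np.full(conc.shape, float(bottom))
    pos = conc > 0
    # fraction occupied: A / (A + EC50), written via logs for stability
    x = np.log10(conc[pos])
    frac = 1.0 / (1.0 + 10.0 ** (-pec50 - x))
    out[pos] = bottom + (top - bottom) * frac
    return out


def competition1(log_conc: np.ndarray, pic50: float, top: float, bottom: float) -> np.ndarray:
    """One-site competition curve on log10 molar competitor concentration."""
    log_conc = np.asarray(log_conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (log_conc + pic50))


def cheng_prusoff(pic50: float, tracer_conc: float, tracer_kd: float) -> float:
    """pKi from pIC50: pKi = pIC50 + log10(1 + [tracer]/Kd_tracer).

    Ki = IC50 / (1 + L/Kd) <= IC50, so on the -log10 molar scale the
    correction term log10(1 + L/Kd) >= 0 is *added* to pIC50; it vanishes
    in the limit of a vanishing tracer concentration.
    """
    if tracer_conc <= 0 or tracer_kd <= 0:
        raise ValueError("tracer concentration and Kd must be positive")
    return float(pic50 + np.log10(1.0 + tracer_conc / tracer_kd))


def _multistart_lsq(residual, x0_list, bounds):
    best = None
    for x0 in x0_list:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = least_squares(residual, x0, bounds=bounds, method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _asymptotic_se(sol, n_obs: int) -> np.ndarray:
    """Standard errors from the Gauss-Newton covariance J'J^-1 * s2."""
    n_par = sol.x.size
    dof = max(n_obs - n_par, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(n_par, np.nan)


class ThreeParamLogistic(RegressorMixin, BaseEstimator):
    """Three-parameter logistic regression of response on molar concentration.

    Parameters
    ----------
    fix_bottom, fix_top : float, optional
        Fix an asymptote instead of estimating it (e.g. bottom=0 for
        baseline-subtracted assays).
    n_starts : int
        Number of starting points for the bounded least-squares search.
        Starts are data driven (bottom = min response, top = max response,
        pEC50 at the half-span crossing) with log-spaced perturbations of
        the pEC50 start; ties break on the lowest residual sum of squares.

    Attributes
    ----------
    pec50_, top_, bottom_ : fitted parameters
    sem_pec50_, sem_top_, sem_bottom_ : asymptotic standard errors
    converged_ : bool
    extrapolated_ : True when pEC50 falls > 1 log unit outside the tested range
    """

    def __init__(self, fix_bottom: Optional[float] = None,
                 fix_top: Optional[float] = None, n_starts: int = 3):
        self.fix_bottom = fix_bottom
        self.fix_top = fix_top
        self.n_starts = n_starts

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=4)
        conc = X[:, 0]
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0 (0 marks a basal well)")
        pos = conc > 0
        if np.unique(conc[pos]).size < 5:
            raise ValueError("need >= 5 distinct non-zero concentrations per curve")
        logc = np.log10(conc[pos])
        lo, hi = logc.min(), logc.max()

        free = []  # parameter order: [pec50, top?, bottom?]
        free.append("pec50")
        if self.fix_top is None:
            free.append("top")
        if self.fix_bottom is None:
            free.append("bottom")

        ymin, ymax = float(np.min(y)), float(np.max(y))
        span = ymax - ymin if ymax > ymin else 1.0

        def unpack(theta):
            vals = dict(zip(free, theta))
            top = vals.get("top", self.fix_top)
            bottom = vals.get("bottom", self.fix_bottom)
            return vals["pec50"], top, bottom

        def residual(theta):
            pec50, top, bottom = unpack(theta)
            return logistic3(conc, pec50, top, bottom) - y

        # data-driven pEC50 start: first tested log conc whose response crosses half-span
        order = np.argsort(logc)
        yy = y[pos][order]
        half = ymin + 0.5 * span
        crossing = logc[order][np.argmin(np.abs(yy - half))]
        pec50_0 = -crossing

        bounds_lo, bounds_hi = [], []
        for name in free:
            if name == "pec50":
                bounds_lo.append(-hi - 3.0)
                bounds_hi.append(-lo + 3.0)
            elif name == "top":
                bounds_lo.append(ymin - span)
                bounds_hi.append(ymax + 2 * span)
            else:
                bounds_lo.append(ymin - span)
                bounds_hi.append(ymax + span)
        bounds = (np.array(bounds_lo), np.array(bounds_hi))

        shifts = np.linspace(-1.0, 1.0, max(int(self.n_starts), 1))
        starts = []
        for s in shifts:
            x0 = []
            for name in free:
                if name == "pec50":
                    x0.append(pec50_0 + s)
                elif name == "top":
                    x0.append(ymax)
                else:
                    x0.append(ymin)
            starts.append(np.array(x0, dtype=float))

        sol = _multistart_lsq(residual, starts, bounds)
        if sol is None:
            self.converged_ = False
            self.pec50_ = self.top_ = self.bottom_ = np.nan
            self.sem_pec50_ = self.sem_top_ = self.sem_bottom_ = np.nan
            self.extrapolated_ = False
            return self

        pec50, top, bottom = unpack(sol.x)
        se = dict(zip(free, _asymptotic_se(sol, y.size)))
        self.pec50_, self.top_, self.bottom_ = float(pec50), float(top), float(bottom)
        self.sem_pec50_ = float(se.get("pec50", np.nan))
        self.sem_top_ = float(se["top"]) if "top" in se else 0.0
        self.sem_bottom_ = float(se["bottom"]) if "bottom" in se else 0.0
        self.converged_ = bool(sol.success)
        self.extrapolated_ = not (-hi - 1.0 <= self.pec50_ <= -lo + 1.0)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "pec50_")
        X = check_array(X)
        return logistic3(X[:, 0], self.pec50_, self.top_, self.bottom_)


class OneSiteCompetition(RegressorMixin, BaseEstimator):
    """One-site competition binding regression on log10 molar concentration.

    Same estimator surface as :class:`ThreeParamLogistic`; the fitted
    midpoint attribute is ``pic50_``. ``top_`` is the upper plateau (no
    competitor) and ``bottom_`` the fully displaced level.
    """

    def __init__(self, fix_bottom: Optional[float] = None,
                 fix_top: Optional[float] = None, n_starts: int = 3):
        self.fix_bottom = fix_bottom
        self.fix_top = fix_top
        self.n_starts = n_starts

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=4)
        logc = X[:, 0]
        lo, hi = float(np.min(logc)), float(np.max(logc))
        ymin, ymax = float(np.min(y)), float(np.max(y))
        span = ymax - ymin if ymax > ymin else 1.0

        free = ["pic50"]
        if self.fix_top is None:
            free.append("top")
        if self.fix_bottom is None:
            free.append("bottom")

        def unpack(theta):
            vals = dict(zip(free, theta))
            return (vals["pic50"], vals.get("top", self.fix_top),
                    vals.get("bottom", self.fix_bottom))

        def residual(theta):
            pic50, top, bottom = unpack(theta)
            return competition1(logc, pic50, top, bottom) - y

        order = np.argsort(logc)
        half = ymin + 0.5 * span
        crossing = logc[order][np.argmin(np.abs(y[order] - half))]

        bounds_lo, bounds_hi = [], []
        for name in free:
            if name == "pic50":
                bounds_lo.append(-hi - 3.0)
                bounds_hi.append(-lo + 3.0)
            elif name == "top":
                bounds_lo.append(ymin - span)
                bounds_hi.append(ymax + span)
            else:
                bounds_lo.append(ymin - span)
                bounds_hi.append(ymax + span)
        bounds = (np.array(bounds_lo), np.array(bounds_hi))

        starts = []
        for s in np.linspace(-1.0, 1.0, max(int(self.n_starts), 1)):
            x0 = []
            for name in free:
                if name == "pic50":
                    x0.append(-crossing + s)
                elif name == "top":
                    x0.append(ymax)
                else:
                    x0.append(ymin)
            starts.append(np.array(x0, dtype=float))

        sol = _multistart_lsq(residual, starts, bounds)
        if sol is None:
            self.converged_ = False
            self.pic50_ = self.top_ = self.bottom_ = np.nan
            self.sem_pic50_ = np.nan
            return self
        pic50, top, bottom = unpack(sol.x)
        se = dict(zip(free, _asymptotic_se(sol, y.size)))
        self.pic50_, self.top_, self.bottom_ = float(pic50), float(top), float(bottom)
        self.sem_pic50_ = float(se.get("pic50", np.nan))
        self.converged_ = bool(sol.success)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "pic50_")
        X = check_array(X)
        return competition1(X[:, 0], self.pic50_, self.top_, self.bottom_)


# --------------------------------------------------------------------------
# per-experiment pooling
# --------------------------------------------------------------------------

def _average_duplicates(df: pd.DataFrame, xcol: str, ycol: str) -> pd.DataFrame:
    return (df.groupby(xcol, as_index=False)[ycol].mean())


def _duplicate_noise_sd(df: pd.DataFrame, xcol: str, ycol: str) -> float:
    """Measurement noise estimated from technical-duplicate spread."""
    sds = df.groupby([xcol])[ycol].std(ddof=1).dropna()
    if len(sds) == 0:
        return np.nan
    return float(np.sqrt(np.mean(sds**2)))


def _pool(values: np.ndarray) -> Tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    if n == 0:
        return np.nan, np.nan
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return mean, sem


def fit_logistic(records: pd.DataFrame, fix_bottom: Optional[float] = None,
                 fix_top: Optional[float] = None, average_duplicates: bool = True,
                 noise_floor: Optional[float] = None) -> LogisticFit:
    """Fit one concentration-response curve pooled over independent experiments.

    ``records`` holds the rows of a single construct x ligand x pathway
    (columns ``experiment_id, replicate_id, concentration, response``). Each
    experiment is fitted separately; parameters are reported as
    mean +/- SEM over experiments, matching a design of four to six
    independent experiments conducted in duplicate.

    A curve whose response window is smaller than the noise floor is given
    status ``no_response`` with absent parameters. By default the floor is
    4x the technical-duplicate noise SD (fallback 5 assay units when no
    duplicates are present).
    """
    rows = []
    spans = []
    dup_sd = _duplicate_noise_sd(records, "concentration", "response")
    for exp_id, g in records.groupby("experiment_id"):
        if average_duplicates:
            g = _average_duplicates(g, "concentration", "response")
        spans.append(g["response"].max() - g["response"].min())
        rows.append((exp_id, g))

    floor = noise_floor
    if floor is None:
        floor = 4.0 * dup_sd if np.isfinite(dup_sd) and dup_sd > 0 else 5.0
    window = float(np.median(spans)) if spans else 0.0
    if window < floor:
        return LogisticFit(status=FitStatus.no_response, n_experiments=len(rows))

    per_exp = []
    for exp_id, g in rows:
        est = ThreeParamLogistic(fix_bottom=fix_bottom, fix_top=fix_top)
        try:
            est.fit(g[["concentration"]].to_numpy(), g["response"].to_numpy())
        except ValueError:
            continue
        if not est.converged_:
            continue
        per_exp.append({"experiment_id": exp_id, "pec50": est.pec50_,
                        "top": est.top_, "bottom": est.bottom_,
                        "extrapolated": est.extrapolated_})
    per_exp = pd.DataFrame(per_exp)
    if per_exp.empty:
        return LogisticFit(status=FitStatus.not_converged, n_experiments=0)

    pec50, sem_pec50 = _pool(per_exp["pec50"])
    top, sem_top = _pool(per_exp["top"])
    bottom, sem_bottom = _pool(per_exp["bottom"])
    return LogisticFit(
        pec50=pec50, top=top, bottom=bottom,
        sem_pec50=sem_pec50, sem_top=sem_top, sem_bottom=sem_bottom,
        n_experiments=len(per_exp), converged=True,
        extrapolated=bool(per_exp["extrapolated"].any()),
        status=FitStatus.ok, per_experiment=per_exp,
    )


def fit_competition(records: pd.DataFrame, tracer_kd: float, tracer_conc: float,
                    min_displacement: float = 20.0) -> AffinityEstimate:
    """Fit one competition-binding curve and derive pKi (Cheng-Prusoff).

    ``records`` holds the rows of a single construct x ligand
    (columns ``experiment_id, log_conc, specific_binding``; binding in % of
    maximal specific binding of the tracer). Displacement below
    ``min_displacement`` percentage points over the tested range yields
    status ``no_binding``.
    """
    spans = []
    groups = []
    for exp_id, g in records.groupby("experiment_id"):
        gm = _average_duplicates(g, "log_conc", "specific_binding")
        spans.append(gm["specific_binding"].max() - gm["specific_binding"].min())
        groups.append((exp_id, gm))
    if not groups or np.median(spans) < min_displacement:
        return AffinityEstimate(status=FitStatus.no_binding, n_experiments=len(groups))

    correction = np.log10(1.0 + tracer_conc / tracer_kd)
    per_exp = []
    for exp_id, g in groups:
        est = OneSiteCompetition()
        try:
            est.fit(g[["log_conc"]].to_numpy(), g["specific_binding"].to_numpy())
        except ValueError:
            continue
        if not est.converged_:
            continue
        per_exp.append({"experiment_id": exp_id, "pic50": est.pic50_,
                        "pki": est.pic50_ + correction})
    per_exp = pd.DataFrame(per_exp)
    if per_exp.empty:
        return AffinityEstimate(status=FitStatus.not_converged, n_experiments=0)

    pic50, _ = _pool(per_exp["pic50"])
    pki, sem_pki = _pool(per_exp["pki"])
    return AffinityEstimate(pic50=pic50, pki=pki, sem_pki=sem_pki,
                            n_experiments=len(per_exp), status=FitStatus.ok,
                            per_experiment=per_exp)
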