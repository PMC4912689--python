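"""Mutant-versus-wild-type comparison and heat classification.

Per-experiment parameter values (pKi, log tau_c, pEC50, log10 Emax) are
compared to the wild-type by one-way ANOVA followed by Dunnett's
many-to-one post-test, and significant effects are binned into the
fold-change heat categories used for the structural maps:
3-5x (yellow), 5-10x (pale orange), 10-30x (orange), >30x (red),
with enhanced effects and assessed-but-unchanged residues (teal) kept
separate.

All measures enter on a log10 scale so that ``delta`` is a log10 difference
and ``fold_change = 10**|delta|`` uniformly (Emax values are log10-ed by the
caller). A negative delta means impaired function.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import HeatCategory

__all__ = ["dunnett_test", "dunnett_mc", "delta_vs_wildtype", "classify_heat",
           "classify_heat_table"]

DEFAULT_FOLD_BINS = (3.0, 5.0, 10.0, 30.0)


def dunnett_test(groups: Mapping[str, Sequence[float]], control: Sequence[float],
                 alternative: str = "two-sided") -> Tuple[pd.Series, list]:
    """Dunnett's many-to-one comparisons of each group against a control.

    Adjusted two-sided p-values come from the equicorrelated multivariate-t
    distribution of the max-|t| statistic under a pooled-variance one-way
    layout (correlation 1/2 at equal n; exact pairwise correlations for
    unequal n). Groups with fewer than 2 values are excluded and reported.

    Returns
    -------
    (pvalues, excluded)
        ``pvalues`` indexed by group name; ``excluded`` lists the names of
        groups that could not be tested.
    """
    control = np.asarray(control, dtype=float)
    if control.size < 2:
        raise ValueError("control group needs >= 2 values")
    names, samples, excluded = [], [], []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            excluded.append(name)
            continue
        names.append(name)
        samples.append(vals)
    if not names:
        return pd.Series(dtype=float), excluded
    res = stats.dunnett(*samples, control=control, alternative=alternative)
    return pd.Series(res.pvalue, index=names), excluded


def dunnett_mc(groups: Mapping[str, Sequence[float]], control: Sequence[float],
               n_draws: int = 1_000_000, seed: int = 0) -> pd.Series:
    """Monte-Carlo many-to-one adjusted p-values (max-|t| reference).

    Simulates the exact null distribution of the vector of Dunnett t
    statistics — group means are independent normals with variance 1/n_i and
    the pooled variance is an independent chi-square on the one-way residual
    degrees of freedom — and returns, per group, the probability that the
    *largest* absolute statistic exceeds the observed one. Serves both as an
    independent cross-check of the analytic test and as a fallback for
    unbalanced layouts.
    """
    rng = np.random.default_rng(seed)
    control = np.asarray(control, dtype=float)
    names = list(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    k = len(samples)
    ns = np.array([s.size for s in samples])
    n0 = control.size
    df = int(ns.sum() + n0 - (k + 1))
    sse = sum(((s - s.mean()) ** 2).sum() for s in samples) \
        + ((control - control.mean()) ** 2).sum()
    s2 = sse / df
    t_obs = np.array([
        (s.mean() - control.mean()) / np.sqrt(s2 * (1.0 / n + 1.0 / n0))
        for s, n in zip(samples, ns)])

    z = rng.standard_normal((n_draws, k)) / np.sqrt(ns)
    z0 = rng.standard_normal(n_draws) / np.sqrt(n0)
    v = rng.chisquare(df, n_draws) / df
    t_null = np.abs(z - z0[:, None]) / np.sqrt(v[:, None] * (1.0 / ns + 1.0 / n0))
    max_t = t_null.max(axis=1)
    p = [(max_t >= abs(t)).mean() for t in t_obs]
    return pd.Series(p, index=names)


def delta_vs_wildtype(values: pd.DataFrame, wild_type_id: str,
                      alpha: float = 0.05,
                      extra_sem: Optional[Mapping[Tuple[str, str, str], float]] = None,
                      ) -> pd.DataFrame:
    """Mutant-minus-wild-type differences with Dunnett-adjusted significance.

    Parameters
    ----------
    values : tidy frame of per-experiment parameter values with columns
        ``construct_id, ligand_id, measure, experiment_id, value``.
    wild_type_id : construct id of the reference (wild-type) receptor.
    alpha : family-wise significance level.
    extra_sem : optional map ``(construct_id, ligand_id, measure) -> sem``
        of an additional independent error component (e.g. the propagated
        expression term of log tau_c), combined in quadrature into
        ``sem_delta``.

    One Dunnett family is formed per ligand x measure (all mutants against
    the wild-type). Returns one row per mutant x ligand x measure with
    ``delta`` (mean difference, log10 units), ``sem_delta`` (quadrature),
    ``anova_p``, ``p_adj``, ``significant``, ``fold_change = 10**|delta|``
    and ``direction``.
    """
    required = {"construct_id", "ligand_id", "measure", "experiment_id", "value"}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"values frame is missing columns: {sorted(missing)}")
    out = []
    for (ligand, measure), fam in values.groupby(["ligand_id", "measure"]):
        wt = fam.loc[fam["construct_id"] == wild_type_id, "value"].dropna().to_numpy()
        if wt.size < 3:
            raise ValueError(
                f"wild-type needs >= 3 per-experiment values for "
                f"ligand={ligand!r}, measure={measure!r} (got {wt.size})")
        wt_mean = wt.mean()
        wt_sem = wt.std(ddof=1) / np.sqrt(wt.size)
        groups = {
            c: g["value"].dropna().to_numpy()
            for c, g in fam.groupby("construct_id") if c != wild_type_id
        }
        pvals, excluded = dunnett_test(groups, wt)
        tested = [c for c in groups if c not in excluded]
        anova_p = np.nan
        if tested:
            anova_p = float(stats.f_oneway(wt, *[groups[c] for c in tested]).pvalue)
        for construct, vals in groups.items():
            vals = vals[np.isfinite(vals)]
            if construct in excluded or vals.size < 3:
                out.append(dict(construct_id=construct, ligand_id=ligand,
                                measure=measure, delta=np.nan, sem_delta=np.nan,
                                anova_p=np.nan, p_adj=np.nan, significant=False,
                                fold_change=np.nan, direction="reduced",
                                n_mut=int(vals.size), n_wt=int(wt.size),
                                status="not_determined"))
                continue
            delta = float(vals.mean() - wt_mean)
            sem_mut = vals.std(ddof=1) / np.sqrt(vals.size)
            sem = float(np.hypot(sem_mut, wt_sem))
            if extra_sem:
                sem = float(np.hypot(sem, extra_sem.get((construct, ligand, measure), 0.0)))
            p = float(pvals[construct])
            out.append(dict(construct_id=construct, ligand_id=ligand, measure=measure,
                            delta=delta, sem_delta=sem, anova_p=anova_p, p_adj=p,
                            significant=bool(p < alpha),
                            fold_change=float(10.0 ** abs(delta)),
                            direction="reduced" if delta < 0 else "enhanced",
                            n_mut=int(vals.size), n_wt=int(wt.size), status="ok"))
    return pd.DataFrame(out)


def classify_heat(significant: bool, direction: str, fold_change: float,
                  bins: Sequence[float] = DEFAULT_FOLD_BINS,
                  status: str = "ok", wt_window_ok: bool = True) -> HeatCategory:
    """Bin one mutant effect into its heat category.

    Half-open lower-inclusive bins: [3,5) -> fold_3_5, [5,10) -> fold_5_10,
    [10,30) -> fold_10_30, [30,inf) -> fold_gt_30. Non-significant effects
    and significant effects below the reporting threshold (fold < bins[0])
    render as no_effect. Significant enhanced effects map to ``enhanced``.

    A mutant with no detectable response (``status="not_determined"``) is
    treated as a >30-fold loss when the wild-type response window itself
    exceeds the top bin (``wt_window_ok``), else stays not_determined.
    """
    if status == "not_determined" or not np.isfinite(fold_change):
        return HeatCategory.fold_gt_30 if wt_window_ok else HeatCategory.not_determined
    if not significant or fold_change < bins[0]:
        return HeatCategory.no_effect
    if direction == "enhanced":
        return HeatCategory.enhanced
    edges = list(bins)
    cats = [HeatCategory.fold_3_5, HeatCategory.fold_5_10,
            HeatCategory.fold_10_30, HeatCategory.fold_gt_30]
    for upper, cat in zip(edges[1:] + [np.inf], cats):
        if fold_change < upper:
            return cat
    return HeatCategory.fold_gt_30


def classify_heat_table(deltas: pd.DataFrame,
                        bins: Sequence[float] = DEFAULT_FOLD_BINS,
                        wt_window_ok: bool = True) -> pd.DataFrame:
    """Vectorized :func:`classify_heat` over a delta table.

    Adds ``category`` (enum value) and ``category_code`` (integer used for
    B-factor encoding) columns.
    """
    cats = [
        classify_heat(bool(r.significant), str(r.direction), float(r.fold_change),
                      bins=bins, status=str(r.status), wt_window_ok=wt_window_ok)
        for r in deltas.itertuples()
    ]
    out = deltas.copy()
    out["category"] = [c.value for c in cats]
    out["category_code"] = [c.code for c in cats]
    return out
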