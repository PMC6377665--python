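"""Cross-sectional association analyses for standardized methylation scores.

Group contrasts in SD units, ROC-AUC discrimination of smoking status,
dose-response slopes per pack-year, and family-clustered estimation via
generalized estimating equations (GEE).  Confidence intervals are Wald
intervals with normal quantiles at two-sided alpha = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def _wald_ci(est: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    z = stats.norm.ppf(1 - alpha / 2)
    return est - z * se, est + z * se


def _wald_p(est: float, se: float) -> float:
    if se == 0:
        return 0.0 if est != 0 else 1.0
    return float(2 * stats.norm.sf(abs(est / se)))


@dataclass
class ContrastResult:
    """Mean difference of one group versus the reference group, in score units."""

    group: str
    reference: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n_group: int
    n_reference: int


@dataclass
class SlopeResult:
    """A regression slope with its Wald CI."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass
class AucResult:
    """Mann-Whitney AUC with a DeLong-style confidence interval."""

    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


def group_contrast(
    scores,
    groups,
    reference: str,
    cluster=None,
    alpha: float = 0.05,
) -> list[ContrastResult]:
    """Per-group mean score difference versus a reference group.

    Fits a single linear model with group indicators; with ``cluster``
    given, standard errors are cluster-robust (sandwich), which is how
    family-clustered cohorts should be analysed.

    Returns one :class:`ContrastResult` per non-reference group, in the
    order the groups first appear.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if scores.shape[0] != groups.shape[0]:
        raise ValueError("scores and groups must have equal length")
    levels = list(pd.unique(groups))
    if reference not in levels:
        raise ValueError(f"reference group {reference!r} not present")
    counts = pd.Series(groups).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"group(s) with fewer than two samples: {list(small.index)}")

    others = [g for g in levels if g != reference]
    X = np.column_stack(
        [np.ones_like(scores)] + [(groups == g).astype(float) for g in others]
    )
    model = sm.OLS(scores, X)
    if cluster is not None:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster)})
    else:
        fit = model.fit()
    results = []
    for j, g in enumerate(others, start=1):
        est, se = float(fit.params[j]), float(fit.bse[j])
        lo, hi = _wald_ci(est, se, alpha)
        results.append(
            ContrastResult(
                group=str(g),
                reference=str(reference),
                estimate=est,
                ci_low=lo,
                ci_high=hi,
                p=_wald_p(est, se),
                n_group=int(counts[g]),
                n_reference=int(counts[reference]),
            )
        )
    return results


def auc_discrimination(scores, labels, alpha: float = 0.05) -> AucResult:
    """ROC AUC by the midrank Mann-Whitney statistic, with a DeLong CI.

    ``labels`` is a boolean/0-1 vector marking cases.  The AUC equals
    P(score_case > score_control) + 0.5 P(tie); ties are handled by
    midranks.  The variance follows DeLong's structural-component
    (placement value) estimator.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    x = scores[labels]  # cases
    y = scores[~labels]  # controls
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both classes must be non-empty")

    allv = np.concatenate([x, y])
    r_all = stats.rankdata(allv)
    r_x = stats.rankdata(x)
    r_y = stats.rankdata(y)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    # placement values
    v10 = (r_all[:m] - r_x) / n          # per-case P(score > random control)
    v01 = 1.0 - (r_all[m:] - r_y) / m    # per-control P(random case > score)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = float(np.sqrt(var))
    lo, hi = _wald_ci(float(auc), se, alpha)
    return AucResult(
        auc=float(auc),
        se=se,
        ci_low=max(lo, 0.0),
        ci_high=min(hi, 1.0),
        n_cases=m,
        n_controls=n,
    )


def dose_response(
    z_scores,
    pack_years,
    covariates: pd.DataFrame | None = None,
    cluster=None,
    alpha: float = 0.05,
) -> SlopeResult:
    """Slope of the standardized score per pack-year smoked (Wald CI).

    Callers select the relevant subset (e.g. ever-smokers) beforehand.
    Additional covariates enter the linear model untransformed.
    """
    z = np.asarray(z_scores, dtype=float)
    py = np.asarray(pack_years, dtype=float)
    if py.std() == 0:
        raise ValueError("pack-years has zero variance")
    cols = [np.ones_like(z), py]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    X = np.column_stack(cols)
    model = sm.OLS(z, X)
    if cluster is not None:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster)})
    else:
        fit = model.fit()
    est, se = float(fit.params[1]), float(fit.bse[1])
    lo, hi = _wald_ci(est, se, alpha)
    return SlopeResult(est, se, lo, hi, _wald_p(est, se), len(z))


def gee_fit(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    cluster: str,
    cov_struct: str = "exchangeable",
) -> pd.DataFrame:
    """Gaussian identity-link GEE with robust (sandwich) standard errors.

    ``cov_struct`` selects the working correlation: ``"exchangeable"``
    (default; appropriate for twin/family clusters) or ``"independence"``
    (point estimates then coincide with OLS).

    Returns a coefficient table indexed by term with columns ``estimate``,
    ``robust_se``, ``ci_low``, ``ci_high``, ``p``.
    """
    missing = [c for c in [outcome, cluster, *predictors] if c not in data.columns]
    if missing:
        raise ValueError(f"column(s) not in data: {missing}")
    if data[cluster].isna().any():
        raise ValueError("every sample needs a cluster id")
    if data[cluster].nunique() < 2:
        raise ValueError("GEE needs at least two clusters")
    structs = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
    }
    if cov_struct not in structs:
        raise ValueError(f"cov_struct must be one of {list(structs)}")
    X = sm.add_constant(data[predictors].astype(float))
    model = sm.GEE(
        data[outcome].astype(float),
        X,
        groups=data[cluster],
        family=sm.families.Gaussian(),
        cov_struct=structs[cov_struct](),
    )
    fit = model.fit()
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "robust_se": fit.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
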