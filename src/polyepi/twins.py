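"""Twin analyses: intraclass correlations, ACE decomposition, between/within effects.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C) and non-shared environmental (E)
components by contrasting monozygotic (MZ) pairs, who share all segregating
genes, with dizygotic (DZ) pairs, who share half on average.  Under the
biometric model the expected pair correlations are rMZ = a2 + c2 and
rDZ = a2/2 + c2, where a2, c2, e2 are the variance fractions.

Two estimators are provided: the closed-form Falconer decomposition from
the two intraclass correlations, and a maximum-likelihood fit of the joint
bivariate-normal pair likelihood with nonnegativity enforced and
profile-likelihood (or bootstrap) confidence intervals.

The between/within decomposition regresses a twin's outcome simultaneously
on the pair-mean exposure (between-family effect) and the deviation from
the pair mean (within-pair effect).  For MZ pairs the within-pair effect is
free of all genetic and shared-environment confounding -- the discordant-
twin design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .association import _wald_ci, _wald_p

logger = logging.getLogger(__name__)

_CHI2_95_1DF = stats.chi2.ppf(0.95, 1)


@dataclass
class IccResult:
    """Double-entry intraclass correlation with a Fisher-z CI."""

    r: float
    ci_low: float
    ci_high: float
    n_pairs: int
    zygosity: str


@dataclass
class AceEstimate:
    """ACE variance fractions with per-component CIs and a method tag."""

    a2: float
    c2: float
    e2: float
    method: str
    ci_a2: tuple[float, float] | None = None
    ci_c2: tuple[float, float] | None = None
    ci_e2: tuple[float, float] | None = None
    truncated: bool = False
    loglik: float | None = None


@dataclass
class BwDecomposition:
    """Between-pair and within-pair regression coefficients."""

    between: float
    between_ci: tuple[float, float]
    between_p: float
    within: float
    within_ci: tuple[float, float]
    within_p: float
    n_pairs: int
    subset: str


def pairs_wide(
    pheno: pd.DataFrame,
    value_col: str,
    pair_col: str = "family_id",
    zygosity_col: str = "zygosity",
) -> pd.DataFrame:
    """Reshape a long per-twin table into one row per complete pair.

    Returns columns ``pair_id``, ``zygosity``, ``v1``, ``v2``; incomplete
    pairs (not exactly two members) are dropped with a log entry.
    """
    rows = []
    dropped = 0
    for pair_id, grp in pheno.groupby(pair_col, sort=False):
        if len(grp) != 2 or grp[value_col].isna().any():
            dropped += 1
            continue
        v = grp[value_col].to_numpy(dtype=float)
        rows.append(
            {
                "pair_id": pair_id,
                "zygosity": grp[zygosity_col].iloc[0],
                "v1": v[0],
                "v2": v[1],
            }
        )
    if dropped:
        logger.info("dropped %d incomplete pair(s)", dropped)
    return pd.DataFrame(rows)


def intraclass_correlation(
    pairs: pd.DataFrame, zygosity: str, alpha: float = 0.05
) -> IccResult:
    """Double-entry Pearson correlation for pairs of the given zygosity.

    Each pair contributes both orderings (v1, v2) and (v2, v1), which makes
    the statistic symmetric in twin labelling.  The CI uses the Fisher-z
    approximation with the number of pairs as the effective sample size.
    """
    sub = pairs.loc[pairs["zygosity"] == zygosity]
    n = len(sub)
    if n < 3:
        raise ValueError(f"need at least 3 complete {zygosity} pairs, got {n}")
    a = np.concatenate([sub["v1"].to_numpy(), sub["v2"].to_numpy()])
    b = np.concatenate([sub["v2"].to_numpy(), sub["v1"].to_numpy()])
    if a.std() == 0:
        raise ValueError("phenotype has zero variance across twins")
    r = float(np.corrcoef(a, b)[0, 1])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(max(n - 3, 1))
    q = stats.norm.ppf(1 - alpha / 2)
    return IccResult(
        r=r,
        ci_low=float(np.tanh(z - q * se)),
        ci_high=float(np.tanh(z + q * se)),
        n_pairs=n,
        zygosity=zygosity,
    )


def falconer_decomposition(rmz: float, rdz: float) -> AceEstimate:
    """Closed-form ACE fractions from the two intraclass correlations.

    a2 = 2 (rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ.  Components falling
    below zero are truncated at zero and the remainder renormalized to sum
    to one; truncation is flagged and logged.
    """
    for name, r in (("rMZ", rmz), ("rDZ", rdz)):
        if not -1 <= r <= 1:
            raise ValueError(f"{name} must lie in [-1, 1]")
    raw = np.array([2 * (rmz - rdz), 2 * rdz - rmz, 1 - rmz])
    truncated = bool((raw < 0).any())
    comp = np.clip(raw, 0, None)
    total = comp.sum()
    if total == 0:
        comp = np.array([0.0, 0.0, 1.0])
    else:
        comp = comp / total
    if truncated:
        logger.info(
            "Falconer component(s) truncated at zero (raw a2=%.3f c2=%.3f e2=%.3f)",
            *raw,
        )
    return AceEstimate(
        a2=float(comp[0]),
        c2=float(comp[1]),
        e2=float(comp[2]),
        method="falconer",
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# maximum-likelihood ACE
# ---------------------------------------------------------------------------


def _pair_stats(pairs: pd.DataFrame, zygosity: str) -> np.ndarray:
    sub = pairs.loc[pairs["zygosity"] == zygosity, ["v1", "v2"]]
    return sub.to_numpy(dtype=float)


def _ace_loglik(a2: float, c2: float, mz: np.ndarray, dz: np.ndarray) -> float:
    """Profile log-likelihood over (a2, c2); the scale sigma^2 is maximized out.

    Both zygosity groups share one phenotypic variance sigma^2; given the
    implied correlations rMZ = a2 + c2 and rDZ = a2/2 + c2, the MLE of
    sigma^2 is available in closed form.
    """
    eps = 1e-9
    rmz = min(a2 + c2, 1 - 1e-6)
    rdz = min(a2 / 2 + c2, 1 - 1e-6)
    nm, nd = len(mz), len(dz)

    def q(y, r):
        return np.sum(y[:, 0] ** 2 + y[:, 1] ** 2 - 2 * r * y[:, 0] * y[:, 1])

    qm, qd = q(mz, rmz), q(dz, rdz)
    s2 = (qm / (1 - rmz**2) + qd / (1 - rdz**2)) / (2 * (nm + nd))
    s2 = max(s2, eps)

    def ll_part(n, r, qv):
        return -n * (np.log(2 * np.pi) + np.log(s2) + 0.5 * np.log1p(-(r**2))) - qv / (
            2 * s2 * (1 - r**2)
        )

    return float(ll_part(nm, rmz, qm) + ll_part(nd, rdz, qd))


def _profile_max(mz, dz, a2=None, c2=None, e2=None):
    """Maximize the log-likelihood with one fraction held fixed."""
    if a2 is not None:
        hi = 1 - a2 - 1e-9

        def f(x):
            return -_ace_loglik(a2, x, mz, dz)

    elif c2 is not None:
        hi = 1 - c2 - 1e-9

        def f(x):
            return -_ace_loglik(x, c2, mz, dz)

    else:  # e2 fixed: split 1 - e2 between a2 and c2
        hi = 1 - e2 - 1e-9

        def f(x):
            return -_ace_loglik(x, 1 - e2 - x, mz, dz)

    if hi <= 0:
        return _ace_loglik(
            a2 if a2 is not None else 0.0, c2 if c2 is not None else 0.0, mz, dz
        )
    res = optimize.minimize_scalar(f, bounds=(0.0, hi), method="bounded")
    return -float(res.fun)


def _profile_ci(mz, dz, which: str, mle: float, ll_max: float) -> tuple[float, float]:
    """Profile-likelihood 95% CI for one variance fraction."""
    target = ll_max - _CHI2_95_1DF / 2

    def g(t):
        kwargs = {which: t}
        return _profile_max(mz, dz, **kwargs) - target

    lo, hi = 0.0, 1.0
    try:
        if g(0.0) < 0:
            lo = float(optimize.brentq(g, 0.0, mle, xtol=1e-4))
    except ValueError:
        lo = 0.0
    try:
        if g(1.0 - 1e-6) < 0:
            hi = float(optimize.brentq(g, mle, 1.0 - 1e-6, xtol=1e-4))
        else:
            hi = 1.0
    except ValueError:
        hi = 1.0
    return lo, hi


def ml_ace_fit(
    pairs: pd.DataFrame,
    ci_method: str | None = "profile",
    n_boot: int = 200,
    seed: int = 0,
) -> AceEstimate:
    """Maximum-likelihood ACE fit over MZ and DZ pairs jointly.

    The phenotype is standardized internally (pooled over all twins); the
    likelihood is the product of bivariate-normal pair densities with
    correlations a2 + c2 (MZ) and a2/2 + c2 (DZ) and a common variance that
    is profiled out in closed form.  Fractions are constrained to the unit
    simplex; estimates within 1e-3 of a boundary are flagged via the
    ``truncated`` field.

    ``ci_method`` is ``"profile"`` (default), ``"boot"`` (pair-resampling
    bootstrap percentile intervals) or ``None``.
    """
    mz = _pair_stats(pairs, "MZ")
    dz = _pair_stats(pairs, "DZ")
    if len(mz) < 20 or len(dz) < 20:
        raise ValueError("need at least 20 complete pairs per zygosity")
    allv = np.concatenate([mz.ravel(), dz.ravel()])
    mu, sd = allv.mean(), allv.std(ddof=1)
    if sd == 0:
        raise ValueError("phenotype has zero variance")
    mz = (mz - mu) / sd
    dz = (dz - mu) / sd

    # start from the Falconer estimate of the realized correlations
    def de_corr(y):
        a = np.concatenate([y[:, 0], y[:, 1]])
        b = np.concatenate([y[:, 1], y[:, 0]])
        return float(np.corrcoef(a, b)[0, 1])

    start = falconer_decomposition(de_corr(mz), de_corr(dz))
    x0 = np.clip([start.a2, start.c2], 1e-3, 0.95)

    def nll(x):
        a2, c2 = x
        if a2 < 0 or c2 < 0 or a2 + c2 > 1 - 1e-9:
            return 1e12 + 1e6 * (max(0, -a2) + max(0, -c2) + max(0, a2 + c2 - 1))
        return -_ace_loglik(a2, c2, mz, dz)

    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8})
    if not res.success and res.fun >= 1e12:
        raise RuntimeError("ACE likelihood optimization failed to converge")
    a2, c2 = (float(np.clip(v, 0.0, 1.0)) for v in res.x)
    e2 = max(1.0 - a2 - c2, 0.0)
    ll_max = -float(res.fun)
    boundary = a2 < 1e-3 or c2 < 1e-3 or e2 < 1e-3
    if boundary:
        logger.info("ML ACE solution at a boundary: a2=%.4f c2=%.4f e2=%.4f", a2, c2, e2)

    est = AceEstimate(
        a2=a2, c2=c2, e2=e2, method="ml", truncated=boundary, loglik=ll_max
    )
    if ci_method == "profile":
        est.ci_a2 = _profile_ci(mz, dz, "a2", a2, ll_max)
        est.ci_c2 = _profile_ci(mz, dz, "c2", c2, ll_max)
        est.ci_e2 = _profile_ci(mz, dz, "e2", e2, ll_max)
    elif ci_method == "boot":
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            bm = mz[rng.integers(0, len(mz), len(mz))]
            bd = dz[rng.integers(0, len(dz), len(dz))]
            r = optimize.minimize(
                lambda x: -_ace_loglik(x[0], x[1], bm, bd)
                if x[0] >= 0 and x[1] >= 0 and x[0] + x[1] <= 1
                else 1e12,
                [a2, c2],
                method="Nelder-Mead",
            )
            ba, bc = np.clip(r.x, 0, 1)
            draws.append((ba, bc, max(1 - ba - bc, 0)))
        draws = np.array(draws)
        qs = np.quantile(draws, [0.025, 0.975], axis=0)
        est.ci_a2 = (float(qs[0, 0]), float(qs[1, 0]))
        est.ci_c2 = (float(qs[0, 1]), float(qs[1, 1]))
        est.ci_e2 = (float(qs[0, 2]), float(qs[1, 2]))
    return est


# ---------------------------------------------------------------------------
# between / within decomposition
# ---------------------------------------------------------------------------


def between_within_decomposition(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    pair_col: str = "family_id",
    zygosity_col: str | None = "zygosity",
    subset: str | None = None,
    alpha: float = 0.05,
) -> BwDecomposition:
    """Split a twin regression into between-pair and within-pair effects.

    The outcome is regressed simultaneously on the pair-mean predictor
    (between coefficient) and the deviation from the pair mean (within
    coefficient), with cluster-robust standard errors by pair.  Pass
    ``subset="MZ"`` for the genetically controlled MZ-only estimate.
    """
    df = data.copy()
    if subset is not None:
        if zygosity_col is None:
            raise ValueError("subset requires a zygosity column")
        df = df.loc[df[zygosity_col] == subset]
    sizes = df.groupby(pair_col).size()
    keep = sizes.index[sizes == 2]
    df = df.loc[df[pair_col].isin(keep)].copy()
    if len(df) == 0:
        raise ValueError("no complete pairs in the chosen subset")
    pair_mean = df.groupby(pair_col)[predictor].transform("mean")
    deviation = df[predictor] - pair_mean
    if np.allclose(deviation, 0):
        raise ValueError("predictor is identical within every pair")

    X = np.column_stack([np.ones(len(df)), pair_mean.to_numpy(), deviation.to_numpy()])
    fit = sm.OLS(df[outcome].to_numpy(dtype=float), X).fit(
        cov_type="cluster", cov_kwds={"groups": df[pair_col].to_numpy()}
    )
    b_est, b_se = float(fit.params[1]), float(fit.bse[1])
    w_est, w_se = float(fit.params[2]), float(fit.bse[2])
    return BwDecomposition(
        between=b_est,
        between_ci=_wald_ci(b_est, b_se, alpha),
        between_p=_wald_p(b_est, b_se),
        within=w_est,
        within_ci=_wald_ci(w_est, w_se, alpha),
        within_p=_wald_p(w_est, w_se),
        n_pairs=int(len(keep)),
        subset=subset or "all",
    )
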