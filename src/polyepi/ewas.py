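"""Probe-wise EWAS and attenuation comparison for confounder substitution.

An epigenome-wide association study here is a per-probe linear regression
of the methylation beta on an exposure (plus covariates), with a family-
wise Bonferroni significance rule.  The attenuation comparison pairs two
EWAS runs on the same probes -- e.g. unadjusted versus pack-year-adjusted,
or pack-year-adjusted versus score-adjusted -- and summarises which hits
survive, the machinery behind using a methylation score as a proxy control
for smoking when observed smoking history is unavailable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _multi_ols(Y: np.ndarray, X: np.ndarray, cluster: np.ndarray | None = None):
    """OLS of many outcomes (columns of Y) on one design matrix X.

    Returns (coef, se, df) for every column of X and outcome.  Classical
    standard errors by default; with ``cluster``, one-way cluster-robust
    (sandwich) covariances with the usual small-sample factor and
    df = n_clusters - 1.
    """
    n, k = X.shape
    if n <= k:
        raise ValueError("more parameters than observations")
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k:
        raise ValueError("design matrix is singular (collinear predictors)")
    xtx_inv = np.linalg.inv(xtx)
    B = xtx_inv @ (X.T @ Y)  # (k, p)
    resid = Y - X @ B
    if cluster is None:
        df = n - k
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(np.diag(xtx_inv)[:, None] * sigma2[None, :])
        return B, se, df
    codes, _ = pd.factorize(cluster)
    n_g = codes.max() + 1
    # per-cluster score sums: U[g, k, p]
    XE = X[:, :, None] * resid[:, None, :]  # (n, k, p)
    U = np.zeros((n_g, k, XE.shape[2]))
    np.add.at(U, codes, XE)
    meat = np.einsum("gkp,glp->klp", U, U)
    cov = np.einsum("ik,klp,lj->ijp", xtx_inv, meat, xtx_inv)
    adj = (n_g / (n_g - 1)) * ((n - 1) / (n - k))
    se = np.sqrt(np.einsum("iip->ip", cov) * adj)
    return B, se, n_g - 1


def run_ewas(
    betas: pd.DataFrame,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    cluster: pd.Series | None = None,
    alpha_family: float = 0.05,
    model_tag: str = "unadjusted",
    mvalues: bool = False,
) -> pd.DataFrame:
    """Per-probe linear regression of methylation on an exposure.

    Parameters
    ----------
    betas
        Probes x samples matrix of methylation fractions.
    exposure
        Per-sample exposure indexed by sample id (e.g. an adversity count).
    covariates
        Optional per-sample covariates (same index).
    cluster
        Optional cluster ids (e.g. family) for sandwich standard errors.
    alpha_family
        Family-wise error budget; the per-probe threshold is Bonferroni
        ``alpha_family / n_probes_tested``.
    mvalues
        Analyse M-values ``log2(beta / (1 - beta))`` instead of betas.

    Returns
    -------
    pandas.DataFrame
        One row per tested probe: ``probe_id``, ``estimate``, ``se``, ``t``,
        ``p``, ``neg_log10_p``, ``significant``, ``model``.
    """
    samples = [s for s in betas.columns if s in exposure.index]
    if len(samples) < 4:
        raise ValueError("need at least four samples shared by betas and exposure")
    x = exposure.loc[samples].to_numpy(dtype=float)
    if x.std() == 0:
        raise ValueError("exposure has zero variance")
    cols = [np.ones(len(samples)), x]
    if covariates is not None:
        cov = covariates.loc[samples]
        arr = np.asarray(cov, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        cols.extend(arr.T)
    X = np.column_stack(cols)

    Yfull = betas[samples].T.to_numpy(dtype=float)  # (n, p)
    if mvalues:
        eps = 1e-6
        Yc = np.clip(Yfull, eps, 1 - eps)
        Yfull = np.log2(Yc / (1 - Yc))
    keep = Yfull.std(axis=0) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance probe(s) before testing", n_dropped)
    Y = Yfull[:, keep]
    probe_ids = betas.index.to_numpy()[keep]
    cl = None if cluster is None else cluster.loc[samples].to_numpy()

    B, se, df = _multi_ols(Y, X, cl)
    est, ses = B[1], se[1]
    t = np.divide(est, ses, out=np.zeros_like(est), where=ses > 0)
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    n_tested = len(probe_ids)
    threshold = alpha_family / n_tested
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "estimate": est,
            "se": ses,
            "t": t,
            "p": p,
            "neg_log10_p": -np.log10(p),
            "significant": p < threshold,
            "model": model_tag,
        }
    )


@dataclass
class AttenuationComparison:
    """Pairing of two EWAS runs on the same probe universe."""

    table: pd.DataFrame
    n_hits_a: int
    n_hits_b: int
    n_retained: int
    n_lost: int
    spearman_rho: float
    spearman_p: float


def attenuation_compare(
    ewas_a: pd.DataFrame, ewas_b: pd.DataFrame
) -> AttenuationComparison:
    """Compare two EWAS result tables probe by probe.

    Counts hits in each run, hits of run A retained or lost in run B, and
    the Spearman rank correlation between the two p-value vectors (useful
    when comparing two adjustment strategies: a good proxy adjustment
    reproduces the p-value ordering of the observed-covariate adjustment).
    """
    a = ewas_a.set_index("probe_id")
    b = ewas_b.set_index("probe_id")
    if set(a.index) != set(b.index):
        raise ValueError("EWAS results cover different probe sets")
    b = b.loc[a.index]
    table = pd.DataFrame(
        {
            "probe_id": a.index,
            "neg_log10_p_a": a["neg_log10_p"].to_numpy(),
            "neg_log10_p_b": b["neg_log10_p"].to_numpy(),
            "significant_a": a["significant"].to_numpy(),
            "significant_b": b["significant"].to_numpy(),
        }
    ).reset_index(drop=True)
    hits_a = table["significant_a"]
    hits_b = table["significant_b"]
    rho, rho_p = stats.spearmanr(a["p"].to_numpy(), b["p"].to_numpy())
    return AttenuationComparison(
        table=table,
        n_hits_a=int(hits_a.sum()),
        n_hits_b=int(hits_b.sum()),
        n_retained=int((hits_a & hits_b).sum()),
        n_lost=int((hits_a & ~hits_b).sum()),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
    )
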