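"""Methylation-expression integration: eQTM screening and annotation.

Implements a transcriptome-wide association of expression with the
methylation score, a stratified methylation x expression correlation screen
with a family-wise Bonferroni rule (a pair counts only if it clears the
per-test threshold in never-smokers AND current-smokers separately -- the
design that separates smoking-driven from smoking-independent links),
cis/trans annotation relative to gene starts, and a partial-correlation
sensitivity analysis (e.g. adjusting for second-hand-smoke exposure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def screen_grid_size(n_probes: int, n_probesets: int) -> int:
    """Number of tests in the full methylation x expression grid."""
    if n_probes <= 0 or n_probesets <= 0:
        raise ValueError("grid dimensions must be positive")
    return int(n_probes) * int(n_probesets)


def bonferroni_alpha(alpha_family: float, n_tests: int) -> Fraction:
    """Exact per-test threshold ``alpha_family / n_tests`` as a rational."""
    return Fraction(alpha_family).limit_denominator(10**9) / n_tests


def _row_standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    ok = sd[:, 0] > 0
    Z = np.zeros_like(M)
    np.divide(M - mu, sd, out=Z, where=sd > 0)
    return Z, ok


def _corr_matrix(meth: np.ndarray, expr: np.ndarray):
    """Pearson correlations of every meth row with every expr row."""
    n = meth.shape[1]
    zm, ok_m = _row_standardize(meth)
    ze, ok_e = _row_standardize(expr)
    R = (zm @ ze.T) / (n - 1)
    R[~ok_m, :] = np.nan
    R[:, ~ok_e] = np.nan
    return np.clip(R, -1, 1)


def _corr_p(R: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1 - R**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isclose(np.abs(R), 1.0), 0.0, p)
    return np.where(np.isnan(R), np.nan, p)


def transcriptome_association(
    expr: pd.DataFrame,
    scores: pd.Series,
    covariates: pd.DataFrame | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-probeset linear regression of expression on the methylation score.

    Benjamini-Hochberg discovery flags at FDR ``q`` (default 0.05).
    Constant probesets are dropped with a log entry.  Returns one row per
    tested probeset: estimate, SE, p, BH q-value and significance flag.
    """
    from .ewas import _multi_ols

    samples = [s for s in expr.columns if s in scores.index]
    if len(samples) < 10:
        raise ValueError("need at least ten samples shared by expression and scores")
    x = scores.loc[samples].to_numpy(dtype=float)
    cols = [np.ones(len(samples)), x]
    if covariates is not None:
        arr = np.asarray(covariates.loc[samples], dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        cols.extend(arr.T)
    X = np.column_stack(cols)
    Y = expr[samples].T.to_numpy(dtype=float)
    keep = Y.std(axis=0) > 0
    if (~keep).any():
        logger.info("dropped %d constant probeset(s)", int((~keep).sum()))
    Y = Y[:, keep]
    ids = expr.index.to_numpy()[keep]
    B, se, df = _multi_ols(Y, X)
    est, ses = B[1], se[1]
    t = est / ses
    p = 2 * stats.t.sf(np.abs(t), df)
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame(
        {
            "probeset_id": ids,
            "estimate": est,
            "se": ses,
            "t": t,
            "p": p,
            "q_value": qvals,
            "significant": reject,
        }
    )


@dataclass
class ScreenResult:
    """Stratified correlation screen over the full probe x probeset grid."""

    table: pd.DataFrame
    n_tests: int
    per_test_alpha: float
    per_test_alpha_exact: Fraction
    strata: tuple[str, str]
    n_per_stratum: dict

    @property
    def significant_pairs(self) -> pd.DataFrame:
        return self.table.loc[self.table["significant_both"]].reset_index(drop=True)


def correlation_screen(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    strata: pd.Series,
    strata_levels: tuple[str, str] = ("never", "current"),
    alpha_family: float = 0.05,
    method: str = "pearson",
    min_stratum: int = 10,
) -> ScreenResult:
    """Correlate every methylation probe with every expression probeset, per stratum.

    The per-test threshold is ``alpha_family`` divided by the full grid size
    (number of probes x number of probesets); a pair is flagged
    ``significant_both`` only when it clears that threshold in both strata.

    ``method`` is ``"pearson"`` (default) or ``"spearman"`` (rank-transform
    first).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    common = [s for s in meth.columns if s in expr.columns and s in strata.index]
    strata = strata.loc[common]
    n_tests = screen_grid_size(len(meth), len(expr))
    alpha_exact = bonferroni_alpha(alpha_family, n_tests)
    alpha = float(alpha_exact)

    per_stratum = {}
    n_per = {}
    for level in strata_levels:
        samp = [s for s in common if strata[s] == level]
        if len(samp) < min_stratum:
            raise ValueError(
                f"stratum {level!r} has {len(samp)} samples; need >= {min_stratum}"
            )
        M = meth[samp].to_numpy(dtype=float)
        E = expr[samp].to_numpy(dtype=float)
        if method == "spearman":
            M = np.apply_along_axis(stats.rankdata, 1, M)
            E = np.apply_along_axis(stats.rankdata, 1, E)
        R = _corr_matrix(M, E)
        P = _corr_p(R, len(samp))
        per_stratum[level] = (R, P)
        n_per[level] = len(samp)

    probes = meth.index.to_numpy()
    probesets = expr.index.to_numpy()
    table = pd.DataFrame(
        {
            "probe_id": np.repeat(probes, len(probesets)),
            "probeset_id": np.tile(probesets, len(probes)),
        }
    )
    sig_both = np.ones(n_tests, dtype=bool)
    for level in strata_levels:
        R, P = per_stratum[level]
        table[f"r_{level}"] = R.ravel()
        table[f"p_{level}"] = P.ravel()
        sig_both &= np.nan_to_num(P.ravel(), nan=1.0) < alpha
    table["significant_both"] = sig_both
    logger.info(
        "screened %d pairs at per-test alpha %.3g; %d significant in both strata",
        n_tests,
        alpha,
        int(sig_both.sum()),
    )
    return ScreenResult(
        table=table,
        n_tests=n_tests,
        per_test_alpha=alpha,
        per_test_alpha_exact=alpha_exact,
        strata=strata_levels,
        n_per_stratum=n_per,
    )


def cis_trans_annotate(
    pairs: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    probeset_map: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    window: int = 250_000,
) -> pd.DataFrame:
    """Label methylation-expression pairs as cis or trans.

    A pair is *cis* when probe and gene start share a chromosome and the
    probe lies within ``window`` bp (inclusive) of the gene start; the
    distance is signed, negative meaning the probe is upstream of the
    start.  Pairs with missing coordinates are labelled ``unknown``.

    Parameters
    ----------
    pairs
        Rows with ``probe_id`` and ``probeset_id``.
    probe_annotation
        ``probe_id``, ``chrom``, ``pos`` (1-based).
    probeset_map
        ``probeset_id`` -> ``gene``.
    gene_annotation
        ``gene``, ``chrom``, ``start`` (1-based gene start).
    """
    out = pairs.merge(
        probe_annotation[["probe_id", "chrom", "pos"]], on="probe_id", how="left"
    )
    out = out.merge(probeset_map, on="probeset_id", how="left")
    out = out.merge(
        gene_annotation[["gene", "chrom", "start"]],
        on="gene",
        how="left",
        suffixes=("", "_gene"),
    )
    dist = out["pos"].astype("Float64") - out["start"].astype("Float64")
    same_chrom = out["chrom"].astype("string") == out["chrom_gene"].astype("string")
    known = dist.notna() & out["chrom"].notna() & out["chrom_gene"].notna()
    label = np.where(
        ~known.to_numpy(),
        "unknown",
        np.where(
            same_chrom.fillna(False).to_numpy()
            & (dist.abs() <= window).fillna(False).to_numpy(),
            "cis",
            "trans",
        ),
    )
    out["distance_bp"] = dist.where(same_chrom.fillna(False))
    out["relation"] = label
    return out


@dataclass
class SensitivityResult:
    """Adjusted versus unadjusted correlation vectors within one stratum."""

    table: pd.DataFrame
    spearman_rho: float
    spearman_p: float
    skipped: list


def sensitivity_partial(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    pairs: pd.DataFrame,
    samples,
    covariate: pd.Series,
) -> SensitivityResult:
    """Partial correlations controlling for one covariate, per listed pair.

    Both variables are residualized on the covariate within the given
    sample set (residual-on-residual partial correlation; p-values use
    n - 3 degrees of freedom).  A pair is skipped, and recorded, when the
    covariate is collinear with its methylation probe.  The headline
    statistic is the Spearman correlation between the adjusted and
    unadjusted per-pair coefficient vectors.
    """
    samples = [s for s in samples if s in meth.columns and s in covariate.index]
    n = len(samples)
    if n < 10:
        raise ValueError("need at least ten samples in the stratum")
    c = covariate.loc[samples].to_numpy(dtype=float)
    c_centered = c - c.mean()
    c_ss = float(c_centered @ c_centered)

    def residualize(v):
        if c_ss == 0:
            return v - v.mean()
        beta = (c_centered @ v) / c_ss
        res = v - v.mean() - beta * c_centered
        return res

    rows, skipped = [], []
    for probe, probeset in pairs[["probe_id", "probeset_id"]].itertuples(index=False):
        x = meth.loc[probe, samples].to_numpy(dtype=float)
        y = expr.loc[probeset, samples].to_numpy(dtype=float)
        r_marg = float(np.corrcoef(x, y)[0, 1])
        rx, ry = residualize(x), residualize(y)
        if np.allclose(rx, 0) or np.allclose(ry, 0):
            skipped.append((probe, probeset))
            logger.warning(
                "pair (%s, %s) skipped: covariate collinear with a variable",
                probe,
                probeset,
            )
            continue
        r_part = float(
            (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
        )
        df = n - 3
        t = r_part * np.sqrt(df / max(1 - r_part**2, 1e-300))
        p = float(2 * stats.t.sf(abs(t), df))
        rows.append(
            {
                "probe_id": probe,
                "probeset_id": probeset,
                "r_marginal": r_marg,
                "r_partial": r_part,
                "p_partial": p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        rho, rho_p = stats.spearmanr(table["r_marginal"], table["r_partial"])
    else:
        rho, rho_p = np.nan, np.nan
    return SensitivityResult(
        table=table, spearman_rho=float(rho), spearman_p=float(rho_p), skipped=skipped
    )
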