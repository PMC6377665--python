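"""Two-wave change analyses: trajectories, change-on-change, dependence contrasts.

All change quantities are defined as wave 2 minus wave 1.  When scores are
standardized for change analysis, both waves are z-scored with the wave-1
mean and SD by default, so that a change of -0.25 reads as a quarter of a
baseline SD; pooled standardization is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import SlopeResult, _wald_ci, _wald_p


def standardize_waves(wave1, wave2, method: str = "wave1"):
    """Z-score two waves of a measure on a common scale.

    ``method="wave1"`` uses the wave-1 mean/SD for both waves (changes are
    then in baseline SD units); ``"pooled"`` uses the mean/SD of the stacked
    values.
    """
    w1 = np.asarray(wave1, dtype=float)
    w2 = np.asarray(wave2, dtype=float)
    if method == "wave1":
        mu, sd = w1.mean(), w1.std(ddof=1)
    elif method == "pooled":
        stacked = np.concatenate([w1, w2])
        mu, sd = stacked.mean(), stacked.std(ddof=1)
    else:
        raise ValueError("method must be 'wave1' or 'pooled'")
    if sd == 0:
        raise ValueError("zero variance; cannot standardize")
    return (w1 - mu) / sd, (w2 - mu) / sd


@dataclass
class GroupChange:
    group: str
    n: int
    mean_change: float
    ci_low: float
    ci_high: float


@dataclass
class TrajectoriesResult:
    """Per-group mean change plus contrasts of each group versus never-smokers."""

    changes: pd.DataFrame
    contrasts: pd.DataFrame
    reference: str


def group_trajectories(
    data: pd.DataFrame,
    group_col: str = "group",
    delta_col: str = "delta",
    reference: str = "never",
    alpha: float = 0.05,
) -> TrajectoriesResult:
    """Mean within-person change per smoking-history group, with contrasts.

    Contrasts are differences in mean change versus the reference (never-
    smoker) group, estimated from one linear model with group indicators;
    all intervals are Wald with normal quantiles.
    """
    if reference not in set(data[group_col]):
        raise ValueError(f"reference group {reference!r} not present")
    counts = data[group_col].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"group(s) with fewer than two samples: {list(small.index)}")

    rows = []
    for g, grp in data.groupby(group_col, sort=False):
        d = grp[delta_col].to_numpy(dtype=float)
        se = d.std(ddof=1) / np.sqrt(len(d))
        lo, hi = _wald_ci(d.mean(), se, alpha)
        rows.append(
            {
                "group": g,
                "n": len(d),
                "mean_change": d.mean(),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    changes = pd.DataFrame(rows)

    groups = data[group_col].to_numpy(dtype=object)
    others = [g for g in pd.unique(groups) if g != reference]
    X = np.column_stack(
        [np.ones(len(data))] + [(groups == g).astype(float) for g in others]
    )
    fit = sm.OLS(data[delta_col].to_numpy(dtype=float), X).fit()
    crows = []
    for j, g in enumerate(others, start=1):
        est, se = float(fit.params[j]), float(fit.bse[j])
        lo, hi = _wald_ci(est, se, alpha)
        crows.append(
            {
                "group": g,
                "estimate": est,
                "ci_low": lo,
                "ci_high": hi,
                "p": _wald_p(est, se),
            }
        )
    return TrajectoriesResult(
        changes=changes, contrasts=pd.DataFrame(crows), reference=reference
    )


def change_on_change(
    delta_outcome, delta_exposure, subset=None, alpha: float = 0.05
) -> SlopeResult:
    """OLS slope of an outcome change on an exposure change (Wald CI).

    Works for any numeric outcome -- score change on pack-year change, or
    lung-function / gum-attachment change on score change.  ``subset`` is an
    optional boolean mask (e.g. ever-smokers, pack-year accumulators).
    """
    dy = np.asarray(delta_outcome, dtype=float)
    dx = np.asarray(delta_exposure, dtype=float)
    if subset is not None:
        mask = np.asarray(subset, dtype=bool)
        dy, dx = dy[mask], dx[mask]
    if len(dy) < 3:
        raise ValueError("need at least three observations")
    if dx.std() == 0:
        raise ValueError("exposure change has zero variance")
    X = np.column_stack([np.ones_like(dx), dx])
    fit = sm.OLS(dy, X).fit()
    est, se = float(fit.params[1]), float(fit.bse[1])
    lo, hi = _wald_ci(est, se, alpha)
    return SlopeResult(est, se, lo, hi, _wald_p(est, se), len(dy))


def dependence_contrast(
    data: pd.DataFrame,
    delta_col: str = "delta",
    pattern_col: str = "dep_pattern",
    delta_packyears_col: str = "pack_years_delta",
    adjust_for_delta_packyears: bool = False,
    reference: str = "never_dependent",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Contrast score changes across nicotine-dependence patterns.

    Restricted (by the caller) to current smokers, the four patterns are
    never dependent, dependent at wave 1 only, at wave 2 only, or at both
    waves.  With ``adjust_for_delta_packyears`` the change in pack-years
    enters the linear model as a covariate, isolating the dependence effect
    from the extra tobacco volume dependent smokers accumulate.
    """
    df = data.dropna(subset=[pattern_col]).copy()
    if reference not in set(df[pattern_col]):
        raise ValueError(f"reference pattern {reference!r} not present")
    counts = df[pattern_col].value_counts()
    present = [g for g in counts.index if counts[g] >= 2]
    skipped = [g for g in counts.index if counts[g] < 2]
    if skipped:
        import warnings

        warnings.warn(f"dependence pattern(s) skipped (n < 2): {skipped}", stacklevel=2)
        df = df.loc[df[pattern_col].isin(present)]

    groups = df[pattern_col].to_numpy(dtype=object)
    others = [g for g in pd.unique(groups) if g != reference]
    cols = [np.ones(len(df))] + [(groups == g).astype(float) for g in others]
    if adjust_for_delta_packyears:
        cols.append(df[delta_packyears_col].to_numpy(dtype=float))
    X = np.column_stack(cols)
    fit = sm.OLS(df[delta_col].to_numpy(dtype=float), X).fit()
    rows = []
    for j, g in enumerate(others, start=1):
        est, se = float(fit.params[j]), float(fit.bse[j])
        lo, hi = _wald_ci(est, se, alpha)
        rows.append(
            {
                "pattern": g,
                "estimate": est,
                "ci_low": lo,
                "ci_high": hi,
                "p": _wald_p(est, se),
                "n": int(counts[g]),
                "adjusted": adjust_for_delta_packyears,
            }
        )
    return pd.DataFrame(rows)
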