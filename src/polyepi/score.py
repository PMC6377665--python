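"""Construction of polyepigenetic DNA-methylation scores.

A polyepigenetic score collapses genome-wide DNA methylation into one number
per sample: the beta value measured at each CpG (fraction of methylated
signal, in [0, 1]) is multiplied by an externally estimated effect size for
that CpG, and the products are averaged over the probe set.  The weights
typically come from a large EWAS meta-analysis of the exposure of interest;
the flagship instance for tobacco smoking uses the 2623 CpGs that reached
genome-wide significance in a current-vs-never meta-analysis.  Raw scores
are standardized to mean 0 and SD 1 within the cohort, so that every
downstream estimate is reported in cohort SD units.  Standardization also
makes the score invariant to whether betas are expressed as fractions or
percents, and to any uniform rescaling of the weights.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Coverage below which scoring refuses to proceed regardless of settings.
HARD_MIN_COVERAGE = 0.50


class WeightTableError(ValueError):
    """Raised when a CpG weight table fails validation."""


class BetaMatrixError(ValueError):
    """Raised when a methylation beta matrix fails validation."""


def load_weight_table(
    source,
    probe_col: str = "probe_id",
    effect_col: str = "effect",
    chrom_col: str | None = "chrom",
    pos_col: str | None = "pos",
    sep: str | None = None,
) -> pd.DataFrame:
    """Read and validate a CpG weight table from delimited text.

    Parameters
    ----------
    source
        Path or file-like handle of a delimited text file with a header row.
        The delimiter is sniffed when ``sep`` is None (CSV and TSV both work).
    probe_col, effect_col
        Names of the columns holding the CpG identifier and the per-unit-beta
        effect size.
    chrom_col, pos_col
        Optional columns with chromosome label and 1-based coordinate; they
        are carried through (as ``chrom`` / ``pos``) when present and silently
        ignored otherwise.

    Returns
    -------
    pandas.DataFrame
        Columns ``probe_id`` (str), ``effect`` (float) and, when available,
        ``chrom`` and ``pos``.

    Raises
    ------
    WeightTableError
        If the table is empty, a probe id is duplicated or empty, or an
        effect size is missing or non-numeric; the offending rows are named.
    """
    table = pd.read_csv(source, sep=sep, engine="python")
    for col in (probe_col, effect_col):
        if col not in table.columns:
            raise WeightTableError(
                f"weight table is missing required column {col!r} "
                f"(found: {list(table.columns)})"
            )
    if len(table) == 0:
        raise WeightTableError("weight table contains a header but no rows")

    probes = table[probe_col].astype("string")
    blank = probes.isna() | (probes.str.strip() == "")
    if blank.any():
        rows = (np.flatnonzero(blank.to_numpy()) + 2).tolist()
        raise WeightTableError(f"empty probe id at file line(s) {rows}")

    dup = probes.duplicated(keep=False)
    if dup.any():
        dup_ids = sorted(probes[dup].unique().tolist())
        raise WeightTableError(f"duplicate probe id(s): {dup_ids[:10]}")

    effects = pd.to_numeric(table[effect_col], errors="coerce")
    bad = ~np.isfinite(effects.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        offenders = probes[bad].tolist()[:10]
        raise WeightTableError(
            f"non-numeric or non-finite effect size for probe(s) {offenders}"
        )

    out = pd.DataFrame({"probe_id": probes.astype(str), "effect": effects.astype(float)})
    if chrom_col and chrom_col in table.columns:
        out["chrom"] = table[chrom_col].astype(str).values
    if pos_col and pos_col in table.columns:
        out["pos"] = pd.to_numeric(table[pos_col]).astype("Int64").values
    out = out.reset_index(drop=True)
    logger.info("loaded weight table with %d probes", len(out))
    return out


def load_beta_matrix(source, sep: str = "\t") -> pd.DataFrame:
    """Read a probes x samples beta matrix from delimited text.

    The first column holds probe ids; remaining columns are samples.  Missing
    values may be encoded as empty fields or ``NA``.  Values must lie in
    [0, 1] (betas are methylation fractions, not percents).
    """
    mat = pd.read_csv(source, sep=sep, index_col=0)
    mat.index = mat.index.astype(str)
    mat = mat.astype(float)
    return validate_beta_matrix(mat)


def validate_beta_matrix(betas: pd.DataFrame) -> pd.DataFrame:
    """Check label uniqueness and the [0, 1] range of a beta matrix."""
    if betas.index.has_duplicates:
        dups = betas.index[betas.index.duplicated()].unique().tolist()[:10]
        raise BetaMatrixError(f"duplicate probe id(s) in beta matrix: {dups}")
    if betas.columns.has_duplicates:
        dups = betas.columns[betas.columns.duplicated()].unique().tolist()[:10]
        raise BetaMatrixError(f"duplicate sample id(s) in beta matrix: {dups}")
    vals = betas.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out_of_range = (vals < 0) | (vals > 1)
    if np.nansum(out_of_range) > 0:
        rows = betas.index[np.where(out_of_range)[0]].unique().tolist()[:10]
        raise BetaMatrixError(
            f"beta values outside [0, 1] at probe(s) {rows}; "
            "betas must be methylation fractions"
        )
    return betas


def compute_raw_score(
    betas: pd.DataFrame,
    weights: pd.DataFrame,
    min_coverage: float = 0.95,
    on_low_coverage: str = "warn",
) -> pd.DataFrame:
    """Compute the raw polyepigenetic score for every sample.

    For sample *s* the raw score is the unweighted arithmetic mean, over the
    weight-table probes present and non-missing in that sample, of
    ``beta[i, s] * effect[i]``.  Probes absent from the matrix and missing
    entries simply shrink the denominator; per-sample coverage (fraction of
    weight-table probes used) is reported alongside.

    Parameters
    ----------
    betas
        Probes x samples matrix of methylation fractions (NaN allowed).
    weights
        Output of :func:`load_weight_table` (columns ``probe_id``, ``effect``).
    min_coverage
        Samples whose coverage falls below this threshold are warned about
        (``on_low_coverage="warn"``), dropped (``"drop"``) or rejected
        (``"error"``).  Coverage below :data:`HARD_MIN_COVERAGE` always
        raises: a score computed from fewer than half of its probes is not
        comparable across samples.

    Returns
    -------
    pandas.DataFrame
        Columns ``sample_id``, ``raw_score``, ``n_probes_used``, ``coverage``.
    """
    if on_low_coverage not in ("warn", "drop", "error"):
        raise ValueError("on_low_coverage must be 'warn', 'drop' or 'error'")
    validate_beta_matrix(betas)
    n_weight = len(weights)
    sub = betas.reindex(weights["probe_id"].to_numpy())
    overlap = int(sub.notna().any(axis=1).sum())
    if overlap == 0:
        raise BetaMatrixError(
            "no overlap between weight-table probes and beta-matrix probes"
        )
    products = sub.to_numpy(dtype=float) * weights["effect"].to_numpy()[:, None]
    n_used = np.sum(~np.isnan(products), axis=0)
    coverage = n_used / n_weight
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        raw = np.nanmean(products, axis=0)

    if (coverage < HARD_MIN_COVERAGE).any():
        bad = betas.columns[coverage < HARD_MIN_COVERAGE].tolist()[:10]
        raise BetaMatrixError(
            f"sample(s) {bad} cover less than {HARD_MIN_COVERAGE:.0%} of the "
            "weight-table probes"
        )
    result = pd.DataFrame(
        {
            "sample_id": betas.columns.astype(str),
            "raw_score": raw,
            "n_probes_used": n_used.astype(int),
            "coverage": coverage,
        }
    )
    low = coverage < min_coverage
    if low.any():
        bad = result.loc[low, "sample_id"].tolist()
        msg = (
            f"{low.sum()} sample(s) below min_coverage={min_coverage:g}: "
            f"{bad[:10]}"
        )
        if on_low_coverage == "error":
            raise BetaMatrixError(msg)
        if on_low_coverage == "drop":
            logger.warning("%s -- dropped", msg)
            result = result.loc[~low].reset_index(drop=True)
        else:
            warnings.warn(msg, stacklevel=2)
    return result


def standardize_scores(raw) -> np.ndarray:
    """Z-score a vector of raw scores (mean 0, sample SD 1, ddof=1).

    Raises ``ValueError`` for fewer than two values or zero variance, since
    SD-unit reporting is undefined for a constant score.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise ValueError("standardization needs at least two scores")
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("scores have zero variance; cannot standardize")
    return (arr - arr.mean()) / sd


def compute_scores(
    betas: pd.DataFrame,
    weights: pd.DataFrame,
    min_coverage: float = 0.95,
    on_low_coverage: str = "warn",
    standardize: bool = True,
) -> pd.DataFrame:
    """Raw plus (optionally) standardized scores in one call.

    Convenience wrapper around :func:`compute_raw_score` and
    :func:`standardize_scores`; adds a ``z_score`` column when
    ``standardize`` is True.
    """
    result = compute_raw_score(
        betas, weights, min_coverage=min_coverage, on_low_coverage=on_low_coverage
    )
    if standardize:
        result = result.assign(z_score=standardize_scores(result["raw_score"]))
    return result
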