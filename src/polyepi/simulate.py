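"""Synthetic cohorts with the statistical structure of smoking-methylation studies.

Every downstream analysis in this package (group contrasts, dose-response,
twin decompositions, two-wave change tracking, EWAS confounder substitution
and the methylation-expression screen) is exercised on cohorts produced
here, because real birth-cohort methylation data are not redistributable.

Generative model
----------------
Each sample carries a latent smoking-methylation burden ``T`` expressed on
the cohort SD scale (the generator calibrates the residual variance so that
``Var(T) = 1`` given the configured group effects and pack-year slope).
Probes respond to the burden on the logit scale::

    beta[i, s] = expit( logit(b0_i) + coupling * w_i * T_s + eps )

with probe-specific baselines ``b0_i ~ U(0.2, 0.8)``, weights
``w_i ~ N(0, 1)`` (the same weights are emitted as the cohort's weight
table) and independent logit-scale noise ``eps ~ N(0, probe_noise_sd)``.
Because the weighted-mean score estimator averages ``w_i * beta_i`` over
many probes, it is an affinely consistent estimator of ``T``: its
standardized version converges on the standardized latent burden, which is
what makes configured effect sizes recoverable downstream.

Defaults mirror published birth-cohort conditions: smoking groups of
405 never / 233 former / 165 current with contrasts of 0.45 and
1.65 SD, a 0.07 SD-per-pack-year slope, a 56:44 MZ:DZ twin structure
(rMZ = 0.87, rDZ = 0.52 via a2 = 0.709, c2 = 0.160), a -0.25 SD quit
recovery between waves, and a mediation cohort in which childhood adversity
raises pack-years and pack-years drive the smoking-sensitive probes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------


@dataclass
class ExpressionConfig:
    """Methylation-expression link structure attached to a cohort.

    Expression probesets are organized into regulatory modules; each module
    has a latent activity factor shared by its member CpGs (added to their
    logits with ``module_loading``) and by its member probesets
    (``link_rho`` of the probeset's variance).  The factor itself loads on
    the smoking burden with ``score_loading`` -- linked probesets are
    therefore discoverable by a transcriptome-wide association with the
    score -- but most of its variance is smoking-independent, so the
    methylation-expression pair correlations survive within never-smokers
    and current-smokers separately.
    """

    n_probesets: int = 143
    n_genes: int = 98
    n_modules: int = 14
    n_linked_probes: int = 47
    n_linked_probesets: int = 22
    module_loading: float = 1.0
    link_rho: float = 0.75
    score_loading: float = 0.4
    #: place the first linked probe this many bp upstream of its gene start
    showcase_cis_offset: int = -124


@dataclass
class CohortConfig:
    """Cross-sectional cohort: never/former/current smokers with pack-years."""

    seed: int = 0
    n_never: int = 405
    n_former: int = 233
    n_current: int = 165
    n_probes: int = 2623
    effect_former: float = 0.45
    effect_current: float = 1.65
    packyear_slope: float = 0.07
    packyear_mean: float = 11.71
    packyear_sd: float = 8.65
    coupling: float = 0.2
    probe_noise_sd: float = 0.5
    shs_prob: float = 0.30
    expression: ExpressionConfig | None = None


@dataclass
class TwinConfig:
    """Twin cohort generated under the standard biometric (ACE) model.

    The trait (latent methylation burden) decomposes into additive genetic
    (A), shared (C) and non-shared (E) components with fractions ``a2``,
    ``c2`` and ``1 - a2 - c2``; MZ pairs share A fully, DZ pairs with
    correlation one half, so the expected intraclass correlations are
    ``a2 + c2`` (MZ) and ``a2/2 + c2`` (DZ).  Pack-years get their own ACE
    structure.  ``packyear_effect`` injects a causal within-family effect of
    pack-years on the trait, and ``genetic_confounding`` loads the trait on
    the pack-years additive-genetic factor, which inflates the within-pair
    slope among DZ (but not MZ) twins -- the discordant-twin signature.
    When either is non-zero the ACE residual is rescaled so the trait keeps
    unit variance.
    """

    seed: int = 0
    n_mz_pairs: int = 625
    n_dz_pairs: int = 491
    a2: float = 0.709
    c2: float = 0.160
    py_a2: float = 0.485
    py_c2: float = 0.160
    packyear_effect: float = 0.0
    genetic_confounding: float = 0.0
    packyear_mean: float = 2.04
    packyear_sd: float = 1.76
    make_betas: bool = False
    n_probes: int = 500
    coupling: float = 1.0
    probe_noise_sd: float = 0.5


@dataclass
class MediationConfig:
    """Adversity -> pack-years -> methylation cohort for EWAS confounding.

    The adversity count (0-10, CDC-style categories) raises pack-years;
    pack-years shift the causal probes through the latent burden.  With
    ``direct_effect = 0`` the adversity-methylation association is entirely
    mediated, so it vanishes after conditioning on pack-years (or on a good
    pack-year proxy such as the methylation score itself).
    """

    seed: int = 0
    n_samples: int = 800
    n_probes: int = 1000
    n_causal: int = 100
    ace_categories: int = 10
    ace_prob: float = 0.15
    adversity_to_packyears: float = 2.0
    direct_effect: float = 0.0
    packyear_noise_mean: float = 8.0
    packyear_noise_sd: float = 6.0
    packyear_slope: float = 0.07
    burden_noise_sd: float = 0.1
    #: moderate coupling keeps the logistic probe response near-linear over
    #: the realized burden range, so conditioning on pack-years (linearly)
    #: really does remove the mediated adversity signal
    coupling: float = 0.5
    probe_noise_sd: float = 0.5


@dataclass
class TwoWaveConfig:
    """Two-wave cohort: quit/continue trajectories, dependence, organ damage.

    Wave-1 burden follows the cross-sectional group structure; the change
    between waves is zero drift for never-smokers and early quitters, the
    ``quit_recovery`` offset for those who quit between waves, and
    ``change_slope`` per additional pack-year (plus a direct nicotine-
    dependence effect) for continuing smokers.  Dependent smokers also
    accumulate ``dep_extra_packyears`` more pack-years, so their raw change
    contrast exceeds the direct effect until pack-year change is adjusted
    for.  Organ-damage changes (lung DLco/VA, periodontal attachment loss)
    are driven by the burden change with the configured slopes.
    """

    seed: int = 0
    n_never: int = 405
    n_quit_by_w1: int = 143
    n_quit_between: int = 90
    n_current: int = 165
    effect_former: float = 0.45
    effect_current: float = 1.65
    quit_recovery: float = -0.25
    change_slope: float = 0.05
    #: mean pack-year increment for non-dependent continuing smokers, set so
    #: the overall current-smoker mean change (pack-year accumulation plus
    #: dependence effects) lands near +0.49 SD
    delta_packyears_mean: float = 5.2
    delta_packyears_sd: float = 4.0
    change_noise_sd: float = 0.5
    dependence_direct: float = 0.35
    dep_extra_packyears: float = 4.6
    dep_pattern_probs: tuple[float, float, float, float] = (0.5, 0.1, 0.15, 0.25)
    dlco_slope: float = -0.23
    dlco_noise_sd: float = 0.6
    attach_slope: float = 0.17
    attach_noise_sd: float = 0.5
    n_probes: int = 500
    coupling: float = 0.2
    probe_noise_sd: float = 0.5


@dataclass
class SyntheticCohort:
    """Container for a generated cohort (phenotypes, betas, weights, expression)."""

    pheno: pd.DataFrame
    betas: pd.DataFrame | None = None
    weights: pd.DataFrame | None = None
    betas_wave2: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    gene_annotation: pd.DataFrame | None = None
    probeset_map: pd.DataFrame | None = None
    links: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# probe machinery
# ---------------------------------------------------------------------------


def _probe_panel(rng: np.random.Generator, n_probes: int) -> pd.DataFrame:
    """Draw a probe panel: ids, effect sizes, baselines, genomic coordinates."""
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(n_probes)],
            "effect": rng.normal(0.0, 1.0, n_probes),
            "baseline": rng.uniform(0.2, 0.8, n_probes),
            "chrom": [f"chr{c}" for c in rng.integers(1, 23, n_probes)],
            "pos": rng.integers(1, 200_000_000, n_probes),
        }
    )


def _betas_from_latent(
    rng: np.random.Generator,
    panel: pd.DataFrame,
    latent: np.ndarray,
    sample_ids,
    coupling: float,
    noise_sd: float,
    extra_logit: np.ndarray | None = None,
) -> pd.DataFrame:
    """Invert latent burdens to a beta matrix via the logistic probe model."""
    w = panel["effect"].to_numpy()[:, None]
    b0 = logit(panel["baseline"].to_numpy())[:, None]
    logits = b0 + coupling * w * latent[None, :]
    if extra_logit is not None:
        logits = logits + extra_logit
    logits = logits + rng.normal(0.0, noise_sd, logits.shape)
    betas = expit(logits)
    saturated = np.mean((betas < 1e-6) | (betas > 1 - 1e-6))
    if saturated > 0.01:
        warnings.warn(
            f"{saturated:.1%} of simulated betas are saturated at the [0, 1] "
            "bounds; consider a weaker coupling or smaller effects",
            stacklevel=2,
        )
    return pd.DataFrame(betas, index=panel["probe_id"].to_numpy(), columns=sample_ids)


def _weight_table(panel: pd.DataFrame) -> pd.DataFrame:
    return panel[["probe_id", "effect", "chrom", "pos"]].copy()


def _gamma(rng, mean, sd, size):
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size)


# ---------------------------------------------------------------------------
# cross-sectional cohort
# ---------------------------------------------------------------------------


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cross-sectional smoking cohort (betas, phenotypes, weights).

    Group effects and the pack-year slope are injected on the latent-burden
    scale; the residual SD is derived so that the burden has unit variance
    in expectation, which keeps configured effects interpretable as cohort
    SD units after score standardization.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_never + cfg.n_former + cfg.n_current
    if min(cfg.n_never, cfg.n_former, cfg.n_current) < 2:
        raise ConfigError("each smoking group needs at least two samples")

    status = np.array(
        ["never"] * cfg.n_never + ["former"] * cfg.n_former + ["current"] * cfg.n_current
    )
    mu_map = {"never": 0.0, "former": cfg.effect_former, "current": cfg.effect_current}
    mu = np.array([mu_map[s] for s in status])

    ever = status != "never"
    pack_years = np.zeros(n)
    pack_years[ever] = _gamma(rng, cfg.packyear_mean, cfg.packyear_sd, ever.sum())

    resid_sd = _cohort_residual_sd(cfg)
    latent = (
        mu
        + cfg.packyear_slope * (pack_years - cfg.packyear_mean) * ever
        + rng.normal(0.0, resid_sd, n)
    )

    sample_ids = [f"S{i:04d}" for i in range(n)]
    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "smoking_status": status,
            "ever_smoked": ever.astype(int),
            "pack_years": pack_years,
            "shs_exposure": rng.binomial(1, cfg.shs_prob, n),
            "latent_score": latent,
        }
    )

    panel = _probe_panel(rng, cfg.n_probes)
    extra = None
    expression = gene_ann = ps_map = links = None
    if cfg.expression is not None:
        extra, expression, gene_ann, ps_map, links, panel = _attach_expression(
            rng, panel, latent, sample_ids, cfg.expression
        )
    betas = _betas_from_latent(
        rng, panel, latent, sample_ids, cfg.coupling, cfg.probe_noise_sd, extra
    )

    meta = {"kind": "cohort", "seed": cfg.seed, "residual_sd": resid_sd}
    return SyntheticCohort(
        pheno=pheno,
        betas=betas,
        weights=_weight_table(panel),
        expression=expression,
        gene_annotation=gene_ann,
        probeset_map=ps_map,
        links=links,
        meta=meta,
    )


def _cohort_residual_sd(cfg: CohortConfig) -> float:
    n = cfg.n_never + cfg.n_former + cfg.n_current
    p = np.array([cfg.n_never, cfg.n_former, cfg.n_current]) / n
    mu = np.array([0.0, cfg.effect_former, cfg.effect_current])
    var_group = float(p @ mu**2 - (p @ mu) ** 2)
    p_ever = p[1] + p[2]
    var_py = cfg.packyear_slope**2 * cfg.packyear_sd**2 * p_ever
    resid_var = 1.0 - var_group - var_py
    if resid_var <= 0:
        raise ConfigError(
            "configured group effects and pack-year slope explain more than "
            "the total unit variance of the latent burden"
        )
    return float(np.sqrt(resid_var))


def _attach_expression(rng, panel, latent, sample_ids, xcfg: ExpressionConfig):
    """Build module factors, expression matrix and gene annotation.

    Returns the extra logit term for the beta model plus the expression
    artifacts; the probe panel is returned with the showcase cis probe moved
    next to its gene start.
    """
    n = len(sample_ids)
    n_probes = len(panel)
    if xcfg.n_linked_probes > n_probes:
        raise ConfigError("more linked probes requested than probes in the panel")
    panel = panel.copy()

    # partition linked probes / probesets into modules (round-robin)
    probe_idx = rng.choice(n_probes, xcfg.n_linked_probes, replace=False)
    ps_ids = [f"PS{i:05d}" for i in range(xcfg.n_probesets)]
    linked_ps = list(rng.choice(ps_ids, xcfg.n_linked_probesets, replace=False))
    probe_mod = np.arange(xcfg.n_linked_probes) % xcfg.n_modules
    ps_mod = np.arange(xcfg.n_linked_probesets) % xcfg.n_modules

    lam = xcfg.score_loading
    latent_z = (latent - latent.mean()) / latent.std()
    factors = lam * latent_z[None, :] + np.sqrt(1 - lam**2) * rng.normal(
        0.0, 1.0, (xcfg.n_modules, n)
    )
    extra = np.zeros((n_probes, n))
    for k, pi in enumerate(probe_idx):
        extra[pi] = xcfg.module_loading * factors[probe_mod[k]]

    expr = rng.normal(0.0, 1.0, (xcfg.n_probesets, n))
    ps_pos = {ps: i for i, ps in enumerate(ps_ids)}
    rho = xcfg.link_rho
    for k, ps in enumerate(linked_ps):
        expr[ps_pos[ps]] = rho * factors[ps_mod[k]] + np.sqrt(1 - rho**2) * rng.normal(
            0.0, 1.0, n
        )
    expression = pd.DataFrame(expr, index=ps_ids, columns=sample_ids)

    # genes: one per module for the linked probesets, the rest round-robin
    gene_ids = [f"G{i:04d}" for i in range(xcfg.n_genes)]
    gene_ann = pd.DataFrame(
        {
            "gene": gene_ids,
            "chrom": [f"chr{c}" for c in rng.integers(1, 23, xcfg.n_genes)],
            "start": rng.integers(1_000_000, 200_000_000, xcfg.n_genes),
        }
    )
    ps_gene = {}
    for k, ps in enumerate(linked_ps):
        ps_gene[ps] = gene_ids[ps_mod[k] % xcfg.n_modules]
    rest = [ps for ps in ps_ids if ps not in ps_gene]
    other_genes = gene_ids[xcfg.n_modules :] or gene_ids
    for k, ps in enumerate(rest):
        ps_gene[ps] = other_genes[k % len(other_genes)]
    ps_map = pd.DataFrame(
        {"probeset_id": ps_ids, "gene": [ps_gene[ps] for ps in ps_ids]}
    )

    # showcase cis probe: first linked probe sits just upstream of the start
    # of its module's gene; all other linked probes stay where they are.
    first_probe = probe_idx[0]
    gene_row = gene_ann.loc[gene_ann["gene"] == gene_ids[probe_mod[0]]].iloc[0]
    panel.loc[first_probe, "chrom"] = gene_row["chrom"]
    panel.loc[first_probe, "pos"] = int(gene_row["start"]) + xcfg.showcase_cis_offset

    links = pd.DataFrame(
        [
            {
                "probe_id": panel["probe_id"].iloc[pi],
                "probeset_id": linked_ps[j],
                "module": int(m),
            }
            for k, (pi, m) in enumerate(zip(probe_idx, probe_mod))
            for j, mj in enumerate(ps_mod)
            if mj == m
        ]
    )
    return extra, expression, gene_ann, ps_map, links, panel


# ---------------------------------------------------------------------------
# twins
# ---------------------------------------------------------------------------


def simulate_twins(config: TwinConfig) -> SyntheticCohort:
    """Generate MZ/DZ twin pairs under the biometric ACE model."""
    cfg = config
    if cfg.n_mz_pairs < 2 or cfg.n_dz_pairs < 2:
        raise ConfigError("need at least two pairs per zygosity")
    for name, (a2, c2) in {"trait": (cfg.a2, cfg.c2), "pack-years": (cfg.py_a2, cfg.py_c2)}.items():
        if a2 < 0 or c2 < 0 or a2 + c2 > 1:
            raise ConfigError(f"{name} variance fractions must be >= 0 and a2+c2 <= 1")
    rng = np.random.default_rng(cfg.seed)

    rows = []
    trait_all, ids = [], []
    for zyg, n_pairs in (("MZ", cfg.n_mz_pairs), ("DZ", cfg.n_dz_pairs)):
        a_shared = rng.normal(size=n_pairs)
        a_unique = rng.normal(size=(n_pairs, 2))
        if zyg == "MZ":
            A = np.repeat(a_shared[:, None], 2, axis=1)
        else:
            A = np.sqrt(0.5) * a_shared[:, None] + np.sqrt(0.5) * a_unique
        C = np.repeat(rng.normal(size=n_pairs)[:, None], 2, axis=1)
        E = rng.normal(size=(n_pairs, 2))

        a_py_shared = rng.normal(size=n_pairs)
        a_py_unique = rng.normal(size=(n_pairs, 2))
        if zyg == "MZ":
            A_py = np.repeat(a_py_shared[:, None], 2, axis=1)
        else:
            A_py = np.sqrt(0.5) * a_py_shared[:, None] + np.sqrt(0.5) * a_py_unique
        C_py = np.repeat(rng.normal(size=n_pairs)[:, None], 2, axis=1)
        E_py = rng.normal(size=(n_pairs, 2))

        py_e2 = 1.0 - cfg.py_a2 - cfg.py_c2
        py_z = (
            np.sqrt(cfg.py_a2) * A_py + np.sqrt(cfg.py_c2) * C_py + np.sqrt(py_e2) * E_py
        )

        b, k = cfg.packyear_effect, cfg.genetic_confounding
        var_extra = b**2 + k**2 + 2 * b * k * np.sqrt(cfg.py_a2)
        if var_extra >= 1:
            raise ConfigError(
                "pack-year effect and genetic confounding exceed unit trait variance"
            )
        resid_scale = np.sqrt(1.0 - var_extra)
        e2 = 1.0 - cfg.a2 - cfg.c2
        ace = np.sqrt(cfg.a2) * A + np.sqrt(cfg.c2) * C + np.sqrt(e2) * E
        trait = b * py_z + k * A_py + resid_scale * ace

        for p in range(n_pairs):
            fam = f"{zyg}{p:05d}"
            for t in (0, 1):
                sid = f"{fam}_{t + 1}"
                rows.append(
                    {
                        "sample_id": sid,
                        "family_id": fam,
                        "zygosity": zyg,
                        "twin": t + 1,
                        "pack_years_z": py_z[p, t],
                        "pack_years": max(
                            cfg.packyear_mean + cfg.packyear_sd * py_z[p, t], 0.0
                        ),
                        "latent_score": trait[p, t],
                    }
                )
                trait_all.append(trait[p, t])
                ids.append(sid)

    pheno = pd.DataFrame(rows)
    betas = weights = None
    if cfg.make_betas:
        panel = _probe_panel(rng, cfg.n_probes)
        betas = _betas_from_latent(
            rng, panel, np.array(trait_all), ids, cfg.coupling, cfg.probe_noise_sd
        )
        weights = _weight_table(panel)
    return SyntheticCohort(
        pheno=pheno, betas=betas, weights=weights, meta={"kind": "twins", "seed": cfg.seed}
    )


# ---------------------------------------------------------------------------
# mediation (adversity -> smoking -> methylation)
# ---------------------------------------------------------------------------


def simulate_mediation(config: MediationConfig) -> SyntheticCohort:
    """Generate the adversity/pack-years mediation cohort for EWAS tests."""
    cfg = config
    if cfg.n_causal > cfg.n_probes:
        raise ConfigError("n_causal cannot exceed n_probes")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    ace = rng.binomial(cfg.ace_categories, cfg.ace_prob, n)
    pack_years = (
        _gamma(rng, cfg.packyear_noise_mean, cfg.packyear_noise_sd, n)
        + cfg.adversity_to_packyears * ace
    )
    burden = (
        cfg.packyear_slope * (pack_years - pack_years.mean())
        + cfg.direct_effect * (ace - ace.mean())
        + rng.normal(0.0, cfg.burden_noise_sd, n)
    )

    panel = _probe_panel(rng, cfg.n_probes)
    causal = np.zeros(cfg.n_probes, dtype=bool)
    causal[: cfg.n_causal] = True
    # null probes keep their weight-table effect but do not respond to the burden
    panel_eff = panel.copy()
    coupling_vec = np.where(causal, cfg.coupling, 0.0)[:, None]

    sample_ids = [f"S{i:04d}" for i in range(n)]
    w = panel_eff["effect"].to_numpy()[:, None]
    b0 = logit(panel_eff["baseline"].to_numpy())[:, None]
    logits = b0 + coupling_vec * w * burden[None, :]
    betas = pd.DataFrame(
        expit(logits + rng.normal(0.0, cfg.probe_noise_sd, logits.shape)),
        index=panel_eff["probe_id"].to_numpy(),
        columns=sample_ids,
    )

    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "ace_count": ace,
            "pack_years": pack_years,
            "latent_score": burden,
        }
    )
    weights = _weight_table(panel_eff.loc[causal])
    return SyntheticCohort(
        pheno=pheno,
        betas=betas,
        weights=weights,
        meta={
            "kind": "mediation",
            "seed": cfg.seed,
            "causal_probes": panel_eff.loc[causal, "probe_id"].tolist(),
        },
    )


# ---------------------------------------------------------------------------
# two-wave cohort
# ---------------------------------------------------------------------------

TWO_WAVE_GROUPS = ("never", "quit_by_w1", "quit_between", "current_at_w2")
DEP_PATTERNS = ("never_dependent", "w1_only", "w2_only", "both")


def simulate_two_wave(config: TwoWaveConfig) -> SyntheticCohort:
    """Generate a two-wave cohort with quit/continue and dependence structure."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    counts = [cfg.n_never, cfg.n_quit_by_w1, cfg.n_quit_between, cfg.n_current]
    if min(counts) < 2:
        raise ConfigError("each smoking-history group needs at least two samples")
    n = sum(counts)
    group = np.repeat(TWO_WAVE_GROUPS, counts)

    mu_w1 = {
        "never": 0.0,
        "quit_by_w1": cfg.effect_former,
        "quit_between": cfg.effect_current,
        "current_at_w2": cfg.effect_current,
    }
    mu = np.array([mu_w1[g] for g in group])
    p = np.array(counts) / n
    mus = np.array([mu_w1[g] for g in TWO_WAVE_GROUPS])
    var_group = float(p @ mus**2 - (p @ mus) ** 2)
    if var_group >= 1:
        raise ConfigError("group effects exceed unit wave-1 variance")
    latent_w1 = mu + rng.normal(0.0, np.sqrt(1 - var_group), n)

    current = group == "current_at_w2"
    dep_pattern = np.full(n, "", dtype=object)
    dep_pattern[current] = rng.choice(
        DEP_PATTERNS, size=current.sum(), p=cfg.dep_pattern_probs
    )
    dep_w1 = np.isin(dep_pattern, ("w1_only", "both"))
    dep_w2 = np.isin(dep_pattern, ("w2_only", "both"))

    delta_py = np.zeros(n)
    mean_py = np.where(dep_w2[current], cfg.delta_packyears_mean + cfg.dep_extra_packyears,
                       cfg.delta_packyears_mean)
    delta_py[current] = rng.gamma(
        (mean_py / cfg.delta_packyears_sd) ** 2,
        cfg.delta_packyears_sd**2 / mean_py,
    )

    delta = rng.normal(0.0, cfg.change_noise_sd, n)
    delta[group == "quit_between"] += cfg.quit_recovery
    delta[current] += cfg.change_slope * delta_py[current]
    delta[dep_w2] += cfg.dependence_direct
    latent_w2 = latent_w1 + delta

    dlco_delta = cfg.dlco_slope * delta + rng.normal(0.0, cfg.dlco_noise_sd, n)
    attach_delta = cfg.attach_slope * delta + rng.normal(0.0, cfg.attach_noise_sd, n)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "dep_pattern": np.where(current, dep_pattern, pd.NA),
            "dep_w1": dep_w1.astype(int),
            "dep_w2": dep_w2.astype(int),
            "pack_years_delta": delta_py,
            "latent_w1": latent_w1,
            "latent_w2": latent_w2,
            "dlco_delta": dlco_delta,
            "attach_delta": attach_delta,
        }
    )

    panel = _probe_panel(rng, cfg.n_probes)
    betas_w1 = _betas_from_latent(
        rng, panel, latent_w1, sample_ids, cfg.coupling, cfg.probe_noise_sd
    )
    betas_w2 = _betas_from_latent(
        rng, panel, latent_w2, sample_ids, cfg.coupling, cfg.probe_noise_sd
    )
    return SyntheticCohort(
        pheno=pheno,
        betas=betas_w1,
        betas_wave2=betas_w2,
        weights=_weight_table(panel),
        meta={"kind": "two_wave", "seed": cfg.seed},
    )


# ---------------------------------------------------------------------------
# YAML config + TSV output plumbing for the CLI
# ---------------------------------------------------------------------------

_KINDS = {
    "cohort": CohortConfig,
    "twins": TwinConfig,
    "mediation": MediationConfig,
    "two_wave": TwoWaveConfig,
}


def load_sim_config(path):
    """Read a YAML simulation config: ``kind`` plus dataclass fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kind = raw.pop("kind", "cohort")
    if kind not in _KINDS:
        raise ConfigError(f"unknown simulation kind {kind!r}; choose from {list(_KINDS)}")
    cls = _KINDS[kind]
    expr = raw.pop("expression", None)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise ConfigError(f"unknown config field(s) for kind {kind!r}: {sorted(unknown)}")
    cfg = cls(**raw)
    if expr is not None:
        if kind != "cohort":
            raise ConfigError("expression block is only supported for kind: cohort")
        cfg.expression = ExpressionConfig(**expr)
    return cfg


def simulate(config) -> SyntheticCohort:
    """Dispatch on config type."""
    dispatch = {
        CohortConfig: simulate_cohort,
        TwinConfig: simulate_twins,
        MediationConfig: simulate_mediation,
        TwoWaveConfig: simulate_two_wave,
    }
    return dispatch[type(config)](config)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort as the delimited-text formats the scoring tools read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.pheno.to_csv(out / "pheno.tsv", sep="\t", index=False)
    if cohort.weights is not None:
        cohort.weights.to_csv(out / "weights.csv", index=False)
    if cohort.betas is not None:
        cohort.betas.to_csv(out / "betas.tsv", sep="\t", index_label="probe_id")
    if cohort.betas_wave2 is not None:
        cohort.betas_wave2.to_csv(out / "betas_wave2.tsv", sep="\t", index_label="probe_id")
    if cohort.expression is not None:
        cohort.expression.to_csv(out / "expression.tsv", sep="\t", index_label="probeset_id")
    if cohort.gene_annotation is not None:
        cohort.gene_annotation.to_csv(out / "genes.tsv", sep="\t", index=False)
    if cohort.probeset_map is not None:
        cohort.probeset_map.to_csv(out / "probeset_map.tsv", sep="\t", index=False)
    if cohort.links is not None:
        cohort.links.to_csv(out / "links.tsv", sep="\t", index=False)
    with open(out / "meta.json", "w") as fh:
        json.dump(cohort.meta, fh, indent=2, default=str)
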