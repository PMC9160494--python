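"""Two-stage random-effects pooling of cohort-specific DFY differences.

Stage one estimates the disease-free-years difference versus the reference
category separately in every cohort, with a per-cohort bootstrap standard
error.  Stage two pools the cohort estimates with the classical
DerSimonian-Laird moment estimator: fixed-effect weights ``w = 1/se^2`` give
Cochran's ``Q``; the between-study variance is

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),

and random-effects weights ``1/(se^2 + tau^2)`` give the pooled difference.
Heterogeneity is summarised by ``I^2 = max(0, (Q - df)/Q) * 100``.  The
one-stage alternative fits a single model on the pooled data with
category-specific baselines and proportional study effects, reporting DFY at
the reference study level plus a study-frequency-weighted average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dfy import DFYConfig, DFYEstimate, disease_free_years, estimate_dfy
from .model import ConvergenceError, ModelConfig

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyEstimate:
    """One cohort's DFY difference versus the reference, with its SE."""

    study: str
    estimate: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Random-effects pooled difference with heterogeneity summaries."""

    pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    df: int
    i2: float
    p_q: float
    k: int


def i_squared(Q: float, df: int) -> float:
    """Percent of between-study variability beyond chance; truncated at 0."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if Q <= 0:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


def dersimonian_laird(estimates: list[StudyEstimate]) -> MetaResult:
    """Classical moment-estimator random-effects pooling."""
    k = len(estimates)
    if k < 2:
        raise ValueError("need at least 2 studies to pool; report the single study directly")
    y = np.array([e.estimate for e in estimates])
    se = np.array([e.se for e in estimates])
    w = 1.0 / se**2
    ybar = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - ybar) ** 2))
    df = k - 1
    tau2 = max(0.0, (Q - df) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
    wstar = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(wstar * y) / np.sum(wstar))
    se_p = float(1.0 / np.sqrt(np.sum(wstar)))
    z = stats.norm.ppf(0.975)
    return MetaResult(
        pooled=pooled,
        se_pooled=se_p,
        ci_low=pooled - z * se_p,
        ci_high=pooled + z * se_p,
        tau2=float(tau2),
        Q=Q,
        df=df,
        i2=i_squared(Q, df),
        p_q=float(stats.chi2.sf(Q, df)),
        k=k,
    )


def first_stage(
    data: pd.DataFrame,
    model_config: ModelConfig,
    dfy_config: DFYConfig,
    reference: str,
    n_boot: int = 50,
) -> dict[str, list[StudyEstimate]]:
    """Per-cohort DFY differences vs the reference, bootstrap SEs.

    The per-cohort bootstrap uses a reduced replicate count (default 50),
    recorded on the config, since only a standard error is needed at this
    stage.  Cohorts whose fit fails are excluded with a warning; the pooled
    ``k`` reflects the exclusion.
    """
    out: dict[str, list[StudyEstimate]] = {}
    cfg = replace(dfy_config, n_boot=n_boot)
    for i, (study, chunk) in enumerate(data.groupby("cohort")):
        try:
            _, ests = estimate_dfy(
                chunk.reset_index(drop=True),
                model_config,
                replace(cfg, seed=cfg.seed + i + 1),
                reference=reference,
            )
        except (ConvergenceError, ValueError) as exc:
            log.warning("cohort %s excluded from pooling: %s", study, exc)
            continue
        for e in ests:
            if e.category == reference:
                continue
            se = (e.diff_ci_high - e.diff_ci_low) / (2 * stats.norm.ppf(0.975))
            if not np.isfinite(se) or se <= 0:
                log.warning("cohort %s category %s: unusable SE, excluded", study, e.category)
                continue
            out.setdefault(e.category, []).append(
                StudyEstimate(study=str(study), estimate=e.diff_vs_reference, se=float(se))
            )
    return out


def two_stage(
    data: pd.DataFrame,
    model_config: ModelConfig,
    dfy_config: DFYConfig,
    reference: str,
    n_boot: int = 50,
) -> dict[str, MetaResult]:
    """First stage then DerSimonian-Laird pooling, per category."""
    stage1 = first_stage(data, model_config, dfy_config, reference, n_boot=n_boot)
    return {cat: dersimonian_laird(ests) for cat, ests in stage1.items() if len(ests) >= 2}


def add_study_dummies(data: pd.DataFrame, reference_study: str | None = None):
    """Append 0/1 study indicator columns (reference study omitted)."""
    studies = sorted(data["cohort"].astype(str).unique())
    if reference_study is None:
        reference_study = studies[0]
    cols = []
    out = data.copy()
    for s in studies:
        if s == reference_study:
            continue
        col = f"study:{s}"
        out[col] = (out["cohort"].astype(str) == s).astype(float)
        cols.append(col)
    return out, tuple(cols), reference_study


def one_stage(
    data: pd.DataFrame,
    model_config: ModelConfig,
    dfy_config: DFYConfig,
    reference: str,
) -> tuple[list[DFYEstimate], pd.DataFrame]:
    """Single pooled fit with proportional study adjustment.

    Returns DFY estimates at the reference study level plus a table that also
    carries the study-frequency-weighted average DFY per category (the
    prediction level is a reporting choice, so both are emitted).  With a
    single study the adjustment is skipped with a warning.
    """
    studies = data["cohort"].astype(str).unique()
    if len(studies) < 2:
        log.warning("single-study input: study adjustment skipped")
        aug, cols = data, ()
    else:
        aug, cols, _ = add_study_dummies(data)
    mc = replace(
        model_config, covariate_columns=tuple(model_config.covariate_columns) + cols
    )
    fit_, estimates = estimate_dfy(aug, mc, dfy_config, reference=reference)

    # weighted-average alternative across study levels
    freqs = aug["cohort"].astype(str).value_counts(normalize=True)
    rows = []
    for est in estimates:
        avg = 0.0
        for s, f in freqs.items():
            col = f"study:{s}"
            covs = {col: 1.0} if col in fit_.covariate_names else None
            avg += f * disease_free_years(fit_, est.category, dfy_config, covs)
        rows.append(
            {
                "category": est.category,
                "years_reference_study": est.years,
                "years_weighted": avg,
                "diff": est.diff_vs_reference,
                "ci_low": est.diff_ci_low,
                "ci_high": est.diff_ci_high,
            }
        )
    return estimates, pd.DataFrame(rows)


def compare_stages(
    two_stage_results: dict[str, MetaResult],
    one_stage_estimates: list[DFYEstimate],
) -> pd.DataFrame:
    """Side-by-side two-stage vs one-stage differences with CI-overlap flags."""
    one = {e.category: e for e in one_stage_estimates}
    common = [c for c in two_stage_results if c in one]
    if not common:
        raise ValueError("no categories shared between the two analyses")
    rows = []
    for cat in common:
        m = two_stage_results[cat]
        e = one[cat]
        overlap = not (
            m.ci_high < e.diff_ci_low or e.diff_ci_high < m.ci_low
        ) if np.isfinite(e.diff_ci_low) else np.nan
        rows.append(
            {
                "category": cat,
                "two_stage": m.pooled,
                "two_stage_ci_low": m.ci_low,
                "two_stage_ci_high": m.ci_high,
                "one_stage": e.diff_vs_reference,
                "one_stage_ci_low": e.diff_ci_low,
                "one_stage_ci_high": e.diff_ci_high,
                "abs_difference": abs(m.pooled - e.diff_vs_reference),
                "ci_overlap": overlap,
                "tau2": m.tau2,
                "i2": m.i2,
            }
        )
    return pd.DataFrame(rows)
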