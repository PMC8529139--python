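"""Stability analyses: leave-one-out, outliers, exclusions, subgroups.

Leave-one-out refits the bivariate model n times, each time omitting one
trial, and compares the pooled estimates with the full fit.  Outliers
are trials whose continuity-corrected logit pair lies outside the
chi-square(2) acceptance ellipsoid of the fitted random-effects
distribution (between-study plus within-study covariance).  Subgroup
analysis refits the model within each level of a metadata column,
falling back to univariate random-effects pooling of logits when a
level has too few trials for the full bivariate model, in which case no
SROC/AUC is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.meta_analysis import combine_effects

from .bivariate import (
    MIN_TRIALS_FULL,
    BivariateFit,
    PooledSummary,
    fit_bivariate,
    pooled_summary,
)
from .data import StudySet
from .exceptions import ConvergenceError, InsufficientStudiesError
from .metrics import CC_DEFAULT, CC_POLICY_DEFAULT, logit_pairs
from .sroc import SROCResult, sroc_result

__all__ = [
    "LOOEntry",
    "SubgroupRow",
    "OutlierReport",
    "leave_one_out",
    "refit_excluding",
    "detect_outliers",
    "subgroup_analysis",
    "subgroup_frame",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class LOOEntry:
    """One leave-one-out refit: pooled summary without ``omitted_id``."""

    omitted_id: str
    summary: PooledSummary | None
    delta_sens: float
    delta_spec: float
    converged: bool


@dataclass(frozen=True)
class SubgroupRow:
    """Pooled accuracy for one level of a grouping column.

    ``auc`` is NaN for levels with fewer trials than the full bivariate
    model supports; those summaries come from univariate pooling.
    """

    label: str
    n_trials: int
    summary: PooledSummary
    auc: float
    i2_sens: float
    i2_spec: float
    method: str


@dataclass(frozen=True)
class OutlierReport:
    flagged_ids: list[str]
    statistic: dict[str, float]
    threshold: float
    level: float


def leave_one_out(
    studies: StudySet,
    quad_nodes: int | None = None,
) -> tuple[list[LOOEntry], bool]:
    """Omit one trial at a time and refit; report deltas and stability.

    Returns ``(entries, stable)`` where ``stable`` is True when every
    refit's pooled sensitivity and specificity lie inside the full
    fit's 95% CIs.  Non-convergence of a refit is recorded in its
    entry, not raised.
    """
    if len(studies) < MIN_TRIALS_FULL + 1:
        raise InsufficientStudiesError(
            f"leave-one-out needs >= {MIN_TRIALS_FULL + 1} trials"
        )
    kwargs = {} if quad_nodes is None else {"quad_nodes": quad_nodes}
    full = fit_bivariate(studies, **kwargs)
    full_sum = pooled_summary(full)
    entries = []
    stable = True
    for sid in studies.ids:
        reduced = studies.exclude([sid])
        try:
            fit = fit_bivariate(reduced, **kwargs)
            summ = pooled_summary(fit)
            entries.append(
                LOOEntry(
                    omitted_id=sid,
                    summary=summ,
                    delta_sens=summ.sens - full_sum.sens,
                    delta_spec=summ.spec - full_sum.spec,
                    converged=True,
                )
            )
            if not (full_sum.sens_ci[0] <= summ.sens <= full_sum.sens_ci[1]):
                stable = False
            if not (full_sum.spec_ci[0] <= summ.spec <= full_sum.spec_ci[1]):
                stable = False
        except ConvergenceError:
            entries.append(
                LOOEntry(
                    omitted_id=sid,
                    summary=None,
                    delta_sens=float("nan"),
                    delta_spec=float("nan"),
                    converged=False,
                )
            )
            stable = False
    return entries, stable


def refit_excluding(
    studies: StudySet,
    exclude_ids,
    quad_nodes: int | None = None,
) -> tuple[BivariateFit, PooledSummary, SROCResult]:
    """Full pipeline (fit + pooled summary + SROC) on a reduced set."""
    reduced = studies.exclude(exclude_ids) if exclude_ids else studies
    if len(reduced) < MIN_TRIALS_FULL:
        raise InsufficientStudiesError(
            f"{len(reduced)} trials remain after exclusion; "
            f"need >= {MIN_TRIALS_FULL}"
        )
    kwargs = {} if quad_nodes is None else {"quad_nodes": quad_nodes}
    fit = fit_bivariate(reduced, **kwargs)
    return fit, pooled_summary(fit), sroc_result(fit)


def detect_outliers(
    studies: StudySet,
    fit: BivariateFit,
    level: float = 0.95,
    cc: float = CC_DEFAULT,
    policy: str = CC_POLICY_DEFAULT,
    within: str = "model",
) -> OutlierReport:
    """Flag trials outside the model's chi-square(2) acceptance region.

    For each trial the statistic is d_i = z_i' (Sigma + W_i)^{-1} z_i
    with z_i the continuity-corrected (logit Se, logit Sp) pair minus
    mu-hat and W_i the diagonal within-study variance matrix; trials
    with d_i > chi2_2(level) are flagged.

    ``within="model"`` (default) evaluates W_i at the fitted pooled
    probabilities, 1/(n p(1-p)) per arm — a Pearson-type
    standardisation that stays finite for zero-cell tables and does not
    let a perfect-but-tiny study mask itself behind its own inflated
    observed variance.  ``within="observed"`` uses the corrected-count
    variances 1/tp*+1/fn* and 1/fp*+1/tn* instead.
    """
    y, var = logit_pairs(studies, cc, policy)
    y = y * np.array([1.0, -1.0])  # to (logit Se, logit Sp)
    if within == "model":
        pse, psp = special.expit(fit.mu)
        n1 = np.array([s.n_diseased for s in studies], dtype=float)
        n2 = np.array([s.n_healthy for s in studies], dtype=float)
        var = np.column_stack(
            [1.0 / (n1 * pse * (1.0 - pse)), 1.0 / (n2 * psp * (1.0 - psp))]
        )
    elif within != "observed":
        raise ValueError(f"unknown within-variance mode {within!r}")
    threshold = float(stats.chi2.ppf(level, df=2))
    statistic: dict[str, float] = {}
    flagged: list[str] = []
    for sid, yi, vi in zip(studies.ids, y, var):
        cov = fit.sigma + np.diag(vi)
        d = yi - fit.mu
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
        if det <= 0:
            statistic[sid] = float("inf")
            flagged.append(sid)
            continue
        q = float(
            (cov[1, 1] * d[0] ** 2 - 2 * cov[0, 1] * d[0] * d[1] + cov[0, 0] * d[1] ** 2)
            / det
        )
        statistic[sid] = q
        if q > threshold:
            flagged.append(sid)
    return OutlierReport(
        flagged_ids=flagged, statistic=statistic, threshold=threshold, level=level
    )


def _univariate_pool(y: np.ndarray, var: np.ndarray) -> tuple[float, float, float]:
    """Random-effects (DerSimonian-Laird) pooled mean on the logit scale.

    Returns (pooled, lo, hi) back-transformed with expit.  For a single
    study this degenerates to its own estimate and Wald CI.
    """
    if len(y) == 1:
        m, se = float(y[0]), math.sqrt(float(var[0]))
    else:
        import warnings

        with warnings.catch_warnings():
            # tiny-k random-effects summaries emit spurious sqrt warnings
            # for auxiliary (HKSJ) columns we never read
            warnings.simplefilter("ignore", RuntimeWarning)
            res = combine_effects(y, var, method_re="dl")
            frame = res.summary_frame()
        m = float(frame.loc["random effect", "eff"])
        se = float(frame.loc["random effect", "sd_eff"])
    return (
        float(special.expit(m)),
        float(special.expit(m - _Z95 * se)),
        float(special.expit(m + _Z95 * se)),
    )


def _descriptive_summary(studies: StudySet, cc, policy) -> PooledSummary:
    """Univariate pooled summary for levels below the bivariate minimum."""
    y, var = logit_pairs(studies, cc, policy)
    y = y * np.array([1.0, -1.0])
    sens, se_lo, se_hi = _univariate_pool(y[:, 0], var[:, 0])
    spec, sp_lo, sp_hi = _univariate_pool(y[:, 1], var[:, 1])
    plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec
    dor = plr / nlr
    # crude ratio CIs from the independent axis bounds
    plr_ci = (se_lo / (1.0 - sp_lo), se_hi / (1.0 - sp_hi))
    nlr_ci = ((1.0 - se_hi) / sp_hi, (1.0 - se_lo) / sp_lo)
    dor_ci = (plr_ci[0] / nlr_ci[1], plr_ci[1] / nlr_ci[0])
    return PooledSummary(
        sens=sens, sens_ci=(se_lo, se_hi),
        spec=spec, spec_ci=(sp_lo, sp_hi),
        plr=plr, plr_ci=plr_ci,
        nlr=nlr, nlr_ci=nlr_ci,
        dor=dor, dor_ci=dor_ci,
    )


def subgroup_analysis(
    studies: StudySet,
    grouping: str,
    cc: float = CC_DEFAULT,
    policy: str = CC_POLICY_DEFAULT,
    quad_nodes: int | None = None,
) -> list[SubgroupRow]:
    """Refit the model within each level of a metadata column.

    Levels with at least :data:`MIN_TRIALS_FULL` trials get the full
    bivariate fit and SROC AUC; smaller levels fall back to univariate
    random-effects pooling with ``auc = nan`` (reported as N.A.).
    """
    groups = studies.groupby(grouping)
    kwargs = {} if quad_nodes is None else {"quad_nodes": quad_nodes}
    rows = []
    for label, subset in groups.items():
        n = len(subset)
        if n >= 2:
            from .heterogeneity import heterogeneity  # local to avoid cycle

            het = heterogeneity(subset, cc, policy)
            i2s, i2p = het.i2_sens, het.i2_spec
        else:
            i2s = i2p = float("nan")
        if n >= MIN_TRIALS_FULL:
            try:
                fit = fit_bivariate(subset, **kwargs)
                rows.append(
                    SubgroupRow(
                        label=label, n_trials=n,
                        summary=pooled_summary(fit),
                        auc=sroc_result(fit).auc,
                        i2_sens=i2s, i2_spec=i2p,
                        method="bivariate",
                    )
                )
                continue
            except ConvergenceError:
                pass
        rows.append(
            SubgroupRow(
                label=label, n_trials=n,
                summary=_descriptive_summary(subset, cc, policy),
                auc=float("nan"),
                i2_sens=i2s, i2_spec=i2p,
                method="univariate",
            )
        )
    return rows


def _ci_text(value: float, ci: tuple[float, float], nd: int = 2) -> str:
    return f"{value:.{nd}f} ({ci[0]:.{nd}f}, {ci[1]:.{nd}f})"


def subgroup_frame(rows: list[SubgroupRow]) -> pd.DataFrame:
    """Summary-table layout: one row per level, CI text columns."""
    records = []
    for r in rows:
        s = r.summary
        records.append(
            {
                "Analysis": r.label,
                "N trials": r.n_trials,
                "Sensitivity (95% CI)": _ci_text(s.sens, s.sens_ci),
                "Specificity (95% CI)": _ci_text(s.spec, s.spec_ci),
                "PLR (95% CI)": _ci_text(s.plr, s.plr_ci),
                "NLR (95% CI)": _ci_text(s.nlr, s.nlr_ci),
                "DOR (95% CI)": _ci_text(s.dor, s.dor_ci),
                "AUC": "N.A." if math.isnan(r.auc) else f"{r.auc:.2f}",
            }
        )
    return pd.DataFrame(records)
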