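"""Per-study accuracy statistics on the probability and logit scales.

Sensitivity Se = TP/(TP+FN), specificity Sp = TN/(TN+FP), positive and
negative likelihood ratios PLR = Se/(1-Sp), NLR = (1-Se)/Sp, and the
diagnostic odds ratio DOR = PLR/NLR.  Logit-scale quantities use the
(logit Se, logit FPR) convention: logit_fpr = ln(FP*/TN*) = -logit Sp.

Zero cells make ratios and logits undefined; the standard remedy — a
continuity correction of 0.5 added to all four cells of any table that
contains a zero — is the default policy here.  The correction feeds the
descriptive metrics and the rank/regression tests; the bivariate
likelihood model works on raw counts and needs none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .data import Study2x2, StudySet
from .exceptions import ValidationError

__all__ = [
    "AccuracyEstimates",
    "continuity_correct",
    "study_metrics",
    "metrics_table",
    "metrics_frame",
    "logit_pairs",
    "CC_DEFAULT",
    "CC_POLICY_DEFAULT",
]

CC_DEFAULT = 0.5
CC_POLICY_DEFAULT = "zero_cells_only"
_POLICIES = ("zero_cells_only", "all_cells", "never")


@dataclass(frozen=True)
class AccuracyEstimates:
    """Accuracy statistics for one trial (possibly continuity-corrected)."""

    study_id: str
    sens: float
    spec: float
    plr: float
    nlr: float
    dor: float
    logit_sens: float
    logit_fpr: float
    var_logit_sens: float
    var_logit_fpr: float
    corrected: bool


def continuity_correct(
    study: Study2x2,
    cc: float = CC_DEFAULT,
    policy: str = CC_POLICY_DEFAULT,
) -> tuple[float, float, float, float]:
    """Return (tp, fn, fp, tn) with the continuity correction applied.

    ``zero_cells_only`` adds ``cc`` to all four cells iff any cell is 0;
    ``all_cells`` always adds; ``never`` returns the raw counts.
    """
    if cc < 0:
        raise ValueError(f"continuity correction must be >= 0, got {cc}")
    if policy not in _POLICIES:
        raise ValueError(f"unknown policy {policy!r}; one of {_POLICIES}")
    counts = tuple(float(c) for c in study.counts)
    if cc == 0 or policy == "never":
        return counts
    if policy == "all_cells" or study.has_zero_cell():
        return tuple(c + cc for c in counts)
    return counts


def study_metrics(
    study: Study2x2,
    cc: float = CC_DEFAULT,
    policy: str = CC_POLICY_DEFAULT,
) -> AccuracyEstimates:
    """Compute :class:`AccuracyEstimates` for one trial."""
    tp, fn, fp, tn = continuity_correct(study, cc, policy)
    if 0.0 in (tp, fn, fp, tn):
        raise ZeroDivisionError(
            f"study {study.study_id!r} has a zero cell and no continuity "
            f"correction was applied (cc={cc}, policy={policy!r})"
        )
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec
    return AccuracyEstimates(
        study_id=study.study_id,
        sens=sens,
        spec=spec,
        plr=plr,
        nlr=nlr,
        dor=(tp * tn) / (fn * fp),
        logit_sens=math.log(tp / fn),
        logit_fpr=math.log(fp / tn),
        var_logit_sens=1.0 / tp + 1.0 / fn,
        var_logit_fpr=1.0 / fp + 1.0 / tn,
        corrected=(tp, fn, fp, tn) != tuple(float(c) for c in study.counts),
    )


def metrics_table(
    studies: StudySet,
    cc: float = CC_DEFAULT,
    policy: str = CC_POLICY_DEFAULT,
) -> list[AccuracyEstimates]:
    """One :class:`AccuracyEstimates` per trial, input order preserved."""
    if len(studies) == 0:
        raise ValidationError("empty study set")
    return [study_metrics(s, cc, policy) for s in studies]


def logit_pairs(
    studies: StudySet,
    cc: float = CC_DEFAULT,
    policy: str = CC_POLICY_DEFAULT,
):
    """(logit Se, logit FPR) pairs and their variances as arrays.

    Returns ``(y, var)``: ``y`` of shape (n, 2) with columns
    (logit_sens, logit_fpr) and ``var`` the matching within-study
    variances ``1/tp*+1/fn*`` and ``1/fp*+1/tn*``.
    """
    ms = metrics_table(studies, cc, policy)
    y = np.array([[m.logit_sens, m.logit_fpr] for m in ms])
    var = np.array([[m.var_logit_sens, m.var_logit_fpr] for m in ms])
    return y, var


def metrics_frame(
    studies: StudySet,
    cc: float = CC_DEFAULT,
    policy: str = CC_POLICY_DEFAULT,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Forest-plot data table with exact (Clopper-Pearson) per-study CIs.

    CIs are computed on the *raw* counts (exact binomial needs no
    correction); point estimates follow the correction policy.
    """
    ms = metrics_table(studies, cc, policy)
    alpha = 1.0 - ci_level
    rows = []
    for s, m in zip(studies, ms):
        se_lo, se_hi = proportion_confint(s.tp, s.tp + s.fn, alpha=alpha, method="beta")
        sp_lo, sp_hi = proportion_confint(s.tn, s.tn + s.fp, alpha=alpha, method="beta")
        rows.append(
            {
                "study_id": m.study_id,
                "sens": m.sens,
                "sens_lo": se_lo,
                "sens_hi": se_hi,
                "spec": m.spec,
                "spec_lo": sp_lo,
                "spec_hi": sp_hi,
                "plr": m.plr,
                "nlr": m.nlr,
                "dor": m.dor,
                "corrected": m.corrected,
            }
        )
    return pd.DataFrame(rows)


def illustrative_ppv(study: Study2x2, pooled_sens: float, pooled_spec: float) -> float:
    """Positive predictive value at the study's own prevalence.

    Applies the pooled sensitivity/specificity to an illustrative 2x2
    table with the study's disease prevalence (tp+fn)/n and reads off
    PPV = Se*p / (Se*p + (1-Sp)*(1-p)).
    """
    n = study.tp + study.fn + study.fp + study.tn
    prev = study.n_diseased / n
    num = pooled_sens * prev
    return num / (num + (1.0 - pooled_spec) * (1.0 - prev))
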