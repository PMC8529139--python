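"""Heterogeneity, threshold-effect and publication-bias diagnostics.

Cochran's Q and the inconsistency index I^2 quantify between-study
heterogeneity of the logit-scale accuracy parameters (computed on each
axis separately).  The threshold effect — spread induced by differing
positivity cut-offs — is screened by the Spearman rank correlation of
logit sensitivity against logit(1 - specificity).  Funnel-plot
asymmetry, the usual signature of small-study/publication bias in
diagnostic accuracy data, is tested by the Deeks regression of ln DOR
on the inverse square root of the effective sample size
ESS = 4 n1 n2 / (n1 + n2), weighted by ESS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import StudySet
from .exceptions import InsufficientStudiesError
from .metrics import CC_DEFAULT, CC_POLICY_DEFAULT, logit_pairs, metrics_table

__all__ = [
    "HeterogeneityResult",
    "ThresholdResult",
    "DeeksResult",
    "cochran_q",
    "i_squared",
    "heterogeneity",
    "threshold_spearman",
    "deeks_test",
    "funnel_coordinates",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    q_sens: float
    q_spec: float
    df: int
    p_sens: float
    p_spec: float
    i2_sens: float
    i2_spec: float


@dataclass(frozen=True)
class ThresholdResult:
    rho: float
    p: float
    n: int
    threshold_effect: bool


@dataclass(frozen=True)
class DeeksResult:
    slope: float
    slope_se: float
    intercept: float
    t_stat: float
    p: float
    n: int


def cochran_q(y, var) -> tuple[float, int, float]:
    """Cochran's Q against the fixed-effect inverse-variance pooled mean.

    Returns ``(Q, df, p)`` with Q = sum w_i (y_i - ybar)^2,
    w_i = 1/var_i, and p from chi-square on df = n - 1.
    """
    y = np.asarray(y, dtype=float)
    var = np.asarray(var, dtype=float)
    if len(y) < 2:
        raise InsufficientStudiesError("Cochran's Q needs at least 2 studies")
    if np.any(var <= 0):
        raise ValueError("variances must be positive")
    w = 1.0 / var
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    df = len(y) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def i_squared(q: float, df: int) -> float:
    """I^2 = max(0, (Q - df)/Q) * 100; 0 when Q = 0."""
    if q < 0:
        raise ValueError("Q must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    if q == 0.0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def heterogeneity(
    studies: StudySet,
    cc: float = CC_DEFAULT,
    policy: str = CC_POLICY_DEFAULT,
) -> HeterogeneityResult:
    """Q/I^2 for logit sensitivity and logit specificity separately."""
    y, var = logit_pairs(studies, cc, policy)
    # second column is logit FPR = -logit Sp; Q is sign-invariant
    q1, df, p1 = cochran_q(y[:, 0], var[:, 0])
    q2, _, p2 = cochran_q(y[:, 1], var[:, 1])
    return HeterogeneityResult(
        q_sens=q1, q_spec=q2, df=df, p_sens=p1, p_spec=p2,
        i2_sens=i_squared(q1, df), i2_spec=i_squared(q2, df),
    )


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = _average_ranks(x), _average_ranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("undefined correlation: zero variance in ranks")
    return float(np.corrcoef(rx, ry)[0, 1])


def threshold_spearman(
    studies: StudySet,
    cc: float = CC_DEFAULT,
    policy: str = CC_POLICY_DEFAULT,
    method: str = "t",
    rho_cut: float = 0.6,
    alpha: float = 0.05,
) -> ThresholdResult:
    """Spearman correlation of logit Se vs logit(1-Sp) across studies.

    A strong positive correlation (rho > ``rho_cut`` with p < ``alpha``)
    flags a threshold effect.  The two-sided p-value uses the t
    approximation t = rho sqrt((n-2)/(1-rho^2)) on n-2 df by default;
    ``method="exact"`` enumerates all rank permutations (n <= 9).
    """
    n = len(studies)
    if n < 3:
        raise InsufficientStudiesError("Spearman needs at least 3 studies")
    y, _ = logit_pairs(studies, cc, policy)
    rho = _spearman_rho(y[:, 0], y[:, 1])
    if method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    elif method == "exact":
        if n > 9:
            raise ValueError("exact permutation p-value limited to n <= 9")
        rx = _average_ranks(y[:, 0])
        ry = _average_ranks(y[:, 1])
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return ThresholdResult(
        rho=rho, p=p, n=n, threshold_effect=bool(rho > rho_cut and p < alpha)
    )


def _ess(studies: StudySet) -> np.ndarray:
    n1 = np.array([s.n_diseased for s in studies], dtype=float)
    n2 = np.array([s.n_healthy for s in studies], dtype=float)
    return 4.0 * n1 * n2 / (n1 + n2)


def deeks_test(
    studies: StudySet,
    cc: float = CC_DEFAULT,
    policy: str = CC_POLICY_DEFAULT,
) -> DeeksResult:
    """Deeks' funnel-plot asymmetry test for publication bias.

    Weighted least squares of ln(DOR) on 1/sqrt(ESS) with weights ESS;
    ESS uses the raw arm sizes while ln DOR follows the continuity
    correction policy.  The two-sided p tests slope = 0 on n - 2 df.
    """
    n = len(studies)
    if n < 3:
        raise InsufficientStudiesError("Deeks' test needs at least 3 studies")
    ess = _ess(studies)
    if np.ptp(ess) == 0:
        raise ValueError("degenerate regressor: all effective sample sizes equal")
    ln_dor = np.array([math.log(m.dor) for m in metrics_table(studies, cc, policy)])
    x = sm.add_constant(1.0 / np.sqrt(ess))
    res = sm.WLS(ln_dor, x, weights=ess).fit()
    slope = float(res.params[1])
    slope_se = float(res.bse[1])
    t_stat = float(res.tvalues[1])
    p = float(res.pvalues[1])
    return DeeksResult(
        slope=slope, slope_se=slope_se, intercept=float(res.params[0]),
        t_stat=t_stat, p=p, n=n,
    )


def funnel_coordinates(
    studies: StudySet,
    cc: float = CC_DEFAULT,
    policy: str = CC_POLICY_DEFAULT,
) -> pd.DataFrame:
    """Deeks funnel-plot coordinates (1/sqrt(ESS) vs DOR) for plotting."""
    ess = _ess(studies)
    ms = metrics_table(studies, cc, policy)
    return pd.DataFrame(
        {
            "study_id": [m.study_id for m in ms],
            "inv_sqrt_ess": 1.0 / np.sqrt(ess),
            "dor": [m.dor for m in ms],
        }
    )
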