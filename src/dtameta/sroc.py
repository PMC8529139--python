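"""Hierarchical summary ROC curve and its AUC from a bivariate fit.

The bivariate random-effects model and the hierarchical SROC (HSROC,
Rutter-Gatsonis) model are algebraically equivalent; the HSROC curve is
obtained from the bivariate moments once they are re-expressed with
x = logit FPR on the second axis (mean m2 = -mu2, covariance
s12 = -sigma12):

    beta   = 0.5 * ln(s2^2 / s1^2)                (asymmetry)
    Lambda = (s2/s1)^(1/2) mu1 - (s1/s2)^(1/2) m2  (accuracy)
    sigma_theta^2 = (s1 s2 + s12) / 2             (cut-point spread)
    sigma_alpha^2 = 2 (s1 s2 - s12)               (accuracy spread, >= 0)

and the summary curve is sens(x) = expit(Lambda e^{-beta/2} + x e^{-beta}).
The AUC integrates sensitivity over FPR by the trapezoid rule, by
default over the full (0, 1) range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .bivariate import BivariateFit
from .exceptions import DegenerateGeometryError

__all__ = ["SROCResult", "hsroc_params", "sroc_curve", "sroc_auc", "sroc_result"]

_NPOINTS_DEFAULT = 2001


@dataclass(frozen=True)
class SROCResult:
    """HSROC parameters, curve coordinates and AUC."""

    lambda_acc: float
    beta_shape: float
    theta_var: float
    alpha_var: float
    curve: np.ndarray  # (n, 2) columns (fpr, sens)
    auc: float
    fpr_range: tuple[float, float]
    mode: str = "hsroc"


def _fpr_moments(fit: BivariateFit):
    """Bivariate moments re-expressed on the (logit Se, logit FPR) scale."""
    mu1 = float(fit.mu[0])
    m2 = -float(fit.mu[1])
    s1sq = float(fit.sigma[0, 0])
    s2sq = float(fit.sigma[1, 1])
    s12 = -float(fit.sigma[0, 1])
    return mu1, m2, s1sq, s2sq, s12


def hsroc_params(fit: BivariateFit) -> tuple[float, float, float, float]:
    """Map a bivariate fit to HSROC (Lambda, beta, theta_var, alpha_var)."""
    mu1, m2, s1sq, s2sq, s12 = _fpr_moments(fit)
    if s1sq <= 0 or s2sq <= 0:
        raise DegenerateGeometryError(
            "zero between-study variance on an axis; HSROC mapping undefined"
        )
    s1, s2 = math.sqrt(s1sq), math.sqrt(s2sq)
    beta = 0.5 * math.log(s2sq / s1sq)
    lam = math.sqrt(s2 / s1) * mu1 - math.sqrt(s1 / s2) * m2
    theta_var = (s1 * s2 + s12) / 2.0
    alpha_var = 2.0 * (s1 * s2 - s12)
    if alpha_var < 0:
        warnings.warn("sigma_alpha^2 < 0 numerically; truncated at 0")
        alpha_var = 0.0
    return lam, beta, theta_var, alpha_var


def _curve_sens(fpr: np.ndarray, lam: float, beta: float) -> np.ndarray:
    """sens(fpr) along the HSROC curve; endpoints by continuity."""
    sens = np.empty_like(fpr)
    interior = (fpr > 0.0) & (fpr < 1.0)
    x = special.logit(fpr[interior])
    sens[interior] = special.expit(lam * math.exp(-beta / 2.0) + x * math.exp(-beta))
    sens[fpr <= 0.0] = 0.0
    sens[fpr >= 1.0] = 1.0
    return sens


def _regression_sens(fpr: np.ndarray, fit: BivariateFit) -> np.ndarray:
    """Alternative curve: regression of logit Se on logit FPR."""
    mu1, m2, s1sq, s2sq, s12 = _fpr_moments(fit)
    if s2sq <= 0:
        raise DegenerateGeometryError("zero FPR-axis variance; regression undefined")
    slope = s12 / s2sq
    sens = np.empty_like(fpr)
    interior = (fpr > 0.0) & (fpr < 1.0)
    x = special.logit(fpr[interior])
    sens[interior] = special.expit(mu1 + slope * (x - m2))
    # limits depend on the slope sign; slope >= 0 is the regular case
    lo, hi = (0.0, 1.0) if slope > 0 else (special.expit(mu1), special.expit(mu1))
    sens[fpr <= 0.0] = lo
    sens[fpr >= 1.0] = hi
    return sens


def sroc_curve(
    fit: BivariateFit,
    n_points: int = _NPOINTS_DEFAULT,
    fpr_range: tuple[float, float] = (0.0, 1.0),
    mode: str = "hsroc",
) -> np.ndarray:
    """Summary ROC curve as an (n_points, 2) array of (fpr, sens) rows.

    ``mode="hsroc"`` (default) draws the HSROC curve implied by the
    bivariate fit; ``mode="regression"`` draws the regression of logit
    sensitivity on logit FPR, kept as a sensitivity analysis.
    """
    lo, hi = fpr_range
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid fpr_range {fpr_range}")
    fpr = np.linspace(lo, hi, n_points)
    if mode == "hsroc":
        lam, beta, _, _ = hsroc_params(fit)
        sens = _curve_sens(fpr, lam, beta)
    elif mode == "regression":
        sens = _regression_sens(fpr, fit)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.column_stack([fpr, sens])


def sroc_auc(
    fit: BivariateFit,
    n_points: int = _NPOINTS_DEFAULT,
    fpr_range: tuple[float, float] = (0.0, 1.0),
    normalize: bool = False,
    mode: str = "hsroc",
) -> float:
    """Area under the summary ROC curve by trapezoidal integration.

    Defaults to the full (0, 1) FPR range without normalisation; a
    restricted range can be requested, optionally normalised by its
    width so the result stays on the [0, 1] scale.
    """
    curve = sroc_curve(fit, n_points=n_points, fpr_range=fpr_range, mode=mode)
    lo, hi = fpr_range
    area = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    if normalize:
        area /= hi - lo
    return area


def sroc_result(
    fit: BivariateFit,
    n_points: int = _NPOINTS_DEFAULT,
    fpr_range: tuple[float, float] = (0.0, 1.0),
    mode: str = "hsroc",
) -> SROCResult:
    """Bundle HSROC parameters, curve and AUC for one fit."""
    lam, beta, theta_var, alpha_var = hsroc_params(fit)
    curve = sroc_curve(fit, n_points=n_points, fpr_range=fpr_range, mode=mode)
    area = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return SROCResult(
        lambda_acc=lam,
        beta_shape=beta,
        theta_var=theta_var,
        alpha_var=alpha_var,
        curve=curve,
        auc=area,
        fpr_range=fpr_range,
        mode=mode,
    )


def bivariate_from_hsroc(lam, beta, theta_var, alpha_var, mu1=None):
    """Invert :func:`hsroc_params` back to bivariate moments.

    The HSROC quadruple fixes the geometry up to one location degree of
    freedom; supplying ``mu1`` (mean logit sensitivity) pins it down.
    Returns ``(mu1, m2, s1sq, s2sq, s12)`` on the (logit Se, logit FPR)
    scale.  Used in tests as an algebraic round-trip oracle.
    """
    b = math.exp(beta)  # s2/s1
    s1s2 = (alpha_var / 2.0 + 2.0 * theta_var) / 2.0  # s1*s2
    s1sq = s1s2 / b
    s2sq = s1s2 * b
    s12 = (2.0 * theta_var) - s1s2  # from theta_var = (s1 s2 + s12)/2
    if mu1 is None:
        raise ValueError("mu1 required to resolve the location of the pair")
    s1, s2 = math.sqrt(s1sq), math.sqrt(s2sq)
    m2 = (math.sqrt(s2 / s1) * mu1 - lam) / math.sqrt(s1 / s2)
    return mu1, m2, s1sq, s2sq, s12
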