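"""Bivariate binomial-normal random-effects model for test accuracy.

The model (often called the Reitsma or bivariate GLMM model) assumes
each trial i has latent logit-scale accuracy (a_i, b_i) — logit
sensitivity and logit specificity — drawn from a bivariate normal
N2(mu, Sigma), with the observed cells binomial within the trial:

    tp_i ~ Bin(tp_i + fn_i, expit(a_i)),   tn_i ~ Bin(fp_i + tn_i, expit(b_i)).

The marginal likelihood integrates the random effects out numerically by
adaptive tensor-product Gauss-Hermite quadrature (per-study Laplace
recentring).  Maximum likelihood is obtained by quasi-Newton
optimisation in an unconstrained parameterisation; the covariance of
the pooled means comes from the inverse numerical Hessian.

Pooled summaries back-transform mu: Se = expit(mu1), Sp = expit(mu2),
PLR = Se/(1-Sp), NLR = (1-Se)/Sp, DOR = exp(mu1 + mu2), with Wald CIs
on the logit (proportions) and log (ratios) scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .data import StudySet
from .exceptions import (
    ConvergenceError,
    DegenerateGeometryError,
    InsufficientStudiesError,
)
from .metrics import logit_pairs

__all__ = [
    "BivariateFit",
    "PooledSummary",
    "binom_bivariate_loglik",
    "fit_bivariate",
    "pooled_summary",
    "predict_region",
    "MIN_TRIALS_FULL",
]

#: the full 5-parameter model needs at least this many trials
MIN_TRIALS_FULL = 4

_QUAD_DEFAULT = 25
_Z95 = stats.norm.ppf(0.975)  # Wald multiplier, = 1.959964...


@dataclass(frozen=True)
class BivariateFit:
    """ML fit of the bivariate random-effects model.

    ``mu`` holds (mean logit sensitivity, mean logit specificity);
    ``sigma`` the 2x2 between-study covariance on that scale; ``cov_mu``
    the estimator covariance of ``mu`` (inverse-Hessian block).
    """

    mu: np.ndarray
    sigma: np.ndarray
    cov_mu: np.ndarray
    loglik: float
    converged: bool
    n_trials: int
    method: str
    quad_nodes: int

    @property
    def correlation(self) -> float:
        s1, s2 = math.sqrt(self.sigma[0, 0]), math.sqrt(self.sigma[1, 1])
        if s1 == 0 or s2 == 0:
            return 0.0
        return float(self.sigma[0, 1] / (s1 * s2))


@dataclass(frozen=True)
class PooledSummary:
    """Back-transformed pooled accuracy with 95% Wald CIs."""

    sens: float
    sens_ci: tuple[float, float]
    spec: float
    spec_ci: tuple[float, float]
    plr: float
    plr_ci: tuple[float, float]
    nlr: float
    nlr_ci: tuple[float, float]
    dor: float
    dor_ci: tuple[float, float]


def _check_psd(sigma: np.ndarray) -> None:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (2, 2):
        raise ValueError("sigma must be 2x2")
    if not np.allclose(sigma, sigma.T):
        raise ValueError("sigma must be symmetric")
    if sigma[0, 0] < 0 or sigma[1, 1] < 0:
        raise ValueError("sigma has a negative diagonal entry")
    det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
    if det < -1e-12 * max(1.0, sigma[0, 0] * sigma[1, 1]):
        raise ValueError("sigma is not positive semidefinite")


def _chol_psd(sigma: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor tolerating singular (PSD) input."""
    s11, s12, s22 = sigma[0, 0], sigma[0, 1], sigma[1, 1]
    l11 = math.sqrt(max(s11, 0.0))
    l21 = s12 / l11 if l11 > 0 else 0.0
    l22 = math.sqrt(max(s22 - l21 * l21, 0.0))
    return np.array([[l11, 0.0], [l21, l22]])


def _study_arrays(studies: StudySet):
    tp = np.array([s.tp for s in studies], dtype=float)
    fn = np.array([s.fn for s in studies], dtype=float)
    fp = np.array([s.fp for s in studies], dtype=float)
    tn = np.array([s.tn for s in studies], dtype=float)
    return tp, fn, fp, tn


def _log_binom_coef(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def binom_bivariate_loglik(
    mu,
    sigma,
    studies: StudySet,
    quad_nodes: int = _QUAD_DEFAULT,
) -> float:
    """Marginal log-likelihood of the bivariate binomial-normal model.

    Computed as sum_i ln ∫∫ Bin(tp_i | n1_i, expit(a)) *
    Bin(tn_i | n2_i, expit(b)) * N2((a,b) | mu, Sigma) da db with the
    double integral approximated by an adaptive ``quad_nodes`` x
    ``quad_nodes`` Gauss-Hermite rule (recentred per study at the
    integrand's mode).  A singular Sigma degrades gracefully: Sigma = 0
    collapses the integral to the binomials at mu.
    """
    if quad_nodes < 3:
        raise ValueError("quad_nodes must be >= 3")
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    _check_psd(sigma)
    tp, fn, fp, tn = _study_arrays(studies)
    return _loglik_core(mu, sigma, tp, fn, fp, tn, quad_nodes)


def _loglik_core(mu, sigma, tp, fn, fp, tn, quad_nodes) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood.

    For each study the integrand (binomial kernels times the bivariate
    normal prior) is first Laplace-approximated: a damped Newton search
    finds its mode and curvature, and the tensor-product Hermite nodes
    are recentred and rescaled accordingly.  This keeps the rule
    accurate even when a large study's likelihood is far sharper than
    the random-effects prior, where a prior-centred rule would miss the
    mass entirely.
    """
    n1, n2 = tp + fn, fp + tn
    const = _log_binom_coef(tp, n1) + _log_binom_coef(tn, n2)
    mu = np.asarray(mu, dtype=float)

    if np.all(sigma == 0.0):
        # point-mass random effects: the integral collapses exactly
        la = tp * special.log_expit(mu[0]) + fn * special.log_expit(-mu[0])
        lb = tn * special.log_expit(mu[1]) + fp * special.log_expit(-mu[1])
        return float(np.sum(const + la + lb))

    # regularise for inversion; contributes O(1e-12) to the loglik
    sig = np.asarray(sigma, dtype=float) + 1e-12 * np.eye(2)
    sinv = np.linalg.inv(sig)
    _, logdet_sig = np.linalg.slogdet(sig)

    m = len(tp)
    # Newton search for the per-study mode of the log-integrand,
    # started from the continuity-corrected observed logits
    u = np.column_stack(
        [
            np.log((tp + 0.5) / (fn + 0.5)),
            np.log((tn + 0.5) / (fp + 0.5)),
        ]
    )
    for _ in range(50):
        pa = special.expit(u[:, 0])
        pb = special.expit(u[:, 1])
        d = u - mu
        grad = np.column_stack([tp - n1 * pa, tn - n2 * pb]) - d @ sinv
        h11 = n1 * pa * (1 - pa) + sinv[0, 0]
        h22 = n2 * pb * (1 - pb) + sinv[1, 1]
        h12 = np.full(m, sinv[0, 1])
        det = h11 * h22 - h12**2
        step = np.column_stack(
            [(h22 * grad[:, 0] - h12 * grad[:, 1]) / det,
             (h11 * grad[:, 1] - h12 * grad[:, 0]) / det]
        )
        norms = np.linalg.norm(step, axis=1)
        step[norms > 4.0] *= (4.0 / norms[norms > 4.0])[:, None]
        u = u + step
        if np.max(np.abs(step)) < 1e-12:
            break

    # curvature at the mode -> per-study scaling C_i with C C' = H^{-1}
    pa = special.expit(u[:, 0])
    pb = special.expit(u[:, 1])
    h11 = n1 * pa * (1 - pa) + sinv[0, 0]
    h22 = n2 * pb * (1 - pb) + sinv[1, 1]
    h12 = sinv[0, 1]
    det_h = h11 * h22 - h12**2
    # Cholesky of the 2x2 inverse Hessian, closed form
    c11 = np.sqrt(h22 / det_h)
    c21 = -h12 / np.sqrt(h22 * det_h)
    c22 = 1.0 / np.sqrt(h22)
    logdet_c = np.log(c11 * c22)

    x, w = np.polynomial.hermite.hermgauss(quad_nodes)
    x1 = np.repeat(x, quad_nodes)
    x2 = np.tile(x, quad_nodes)
    logw = np.log(np.repeat(w, quad_nodes)) + np.log(np.tile(w, quad_nodes))
    sq = x1**2 + x2**2

    root2 = math.sqrt(2.0)
    a = u[:, 0, None] + root2 * c11[:, None] * x1[None, :]
    b = u[:, 1, None] + root2 * (c21[:, None] * x1[None, :] + c22[:, None] * x2[None, :])

    ll_bin = (
        tp[:, None] * special.log_expit(a)
        + fn[:, None] * special.log_expit(-a)
        + tn[:, None] * special.log_expit(b)
        + fp[:, None] * special.log_expit(-b)
    )
    da = a - mu[0]
    db = b - mu[1]
    quad_form = sinv[0, 0] * da**2 + 2 * sinv[0, 1] * da * db + sinv[1, 1] * db**2
    log_prior = -math.log(2 * math.pi) - 0.5 * logdet_sig - 0.5 * quad_form

    per_study = (
        math.log(2.0)
        + logdet_c
        + special.logsumexp(logw[None, :] + sq[None, :] + ll_bin + log_prior, axis=1)
    )
    return float(np.sum(const + per_study))


def _normal_approx_loglik(mu, sigma, y, var) -> float:
    """Marginal normal loglik of corrected logits: y_i ~ N(mu*, Sigma + W_i).

    ``y`` columns are (logit sens, logit fpr); the model mean on that
    scale is (mu1, -mu2) and the covariance flips the off-diagonal sign.
    """
    mean = np.array([mu[0], -mu[1]])
    flip = np.array([[1.0, -1.0], [-1.0, 1.0]])
    total = 0.0
    for yi, vi in zip(y, var):
        cov = sigma * flip + np.diag(vi)
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
        if det <= 0:
            return -np.inf
        d = yi - mean
        quad = (cov[1, 1] * d[0] ** 2 - 2 * cov[0, 1] * d[0] * d[1] + cov[0, 0] * d[1] ** 2) / det
        total += -0.5 * (2 * math.log(2 * math.pi) + math.log(det) + quad)
    return total


# --- unconstrained parameterisations -----------------------------------

_LOGSD_BOUNDS = (-6.0, 3.0)
_ATANH_BOUNDS = (-7.0, 7.0)


def _theta_to_sigma_logsd(theta):
    s1, s2 = math.exp(theta[2]), math.exp(theta[3])
    rho = math.tanh(theta[4])
    return np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])


def _theta_to_sigma_chol(theta):
    l11, l22 = math.exp(theta[2]), math.exp(theta[3])
    l21 = theta[4]
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


_PARAMS = {"logsd_rho": _theta_to_sigma_logsd, "cholesky": _theta_to_sigma_chol}


def _moment_start(studies: StudySet) -> np.ndarray:
    """Moment start: mean/covariance of corrected (logit Se, logit Sp)."""
    y, var = logit_pairs(studies)
    y = y * np.array([1.0, -1.0])  # second column -> logit Sp
    mu0 = y.mean(axis=0)
    if len(y) > 1:
        cov = np.cov(y.T, ddof=1)
        # remove the average within-study noise so sigma is not inflated
        cov = cov - np.diag(var.mean(axis=0))
    else:
        cov = np.zeros((2, 2))
    v1 = max(cov[0, 0], 0.05)
    v2 = max(cov[1, 1], 0.05)
    rho = cov[0, 1] / math.sqrt(v1 * v2)
    rho = min(max(rho, -0.9), 0.9)
    return np.array(
        [mu0[0], mu0[1], 0.5 * math.log(v1), 0.5 * math.log(v2), math.atanh(rho)]
    )


def _numerical_hessian(f, x, step=1e-4):
    """Central-difference Hessian of scalar f at x."""
    n = len(x)
    h = step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_bivariate(
    studies: StudySet,
    method: str = "glmm_quadrature",
    quad_nodes: int = _QUAD_DEFAULT,
    param: str = "logsd_rho",
    max_restarts: int = 5,
) -> BivariateFit:
    """Maximum-likelihood fit of the bivariate random-effects model.

    Parameters
    ----------
    method
        ``"glmm_quadrature"`` (exact binomial within-study likelihood,
        the default) or ``"normal_approx"`` (marginal normal on
        continuity-corrected logits with fixed within-study variances).
    quad_nodes
        Gauss-Hermite nodes per dimension for the GLMM likelihood.
    param
        Internal unconstrained coordinates for Sigma: ``"logsd_rho"``
        (log-SDs and atanh correlation) or ``"cholesky"`` (log-diagonal
        Cholesky).  Both reach the same optimum; exposed for
        diagnostics.
    max_restarts
        Deterministically jittered restarts before declaring
        non-convergence.

    The fit is deterministic: no randomness enters the optimisation.
    """
    n = len(studies)
    if n < MIN_TRIALS_FULL:
        raise InsufficientStudiesError(
            f"full bivariate model needs >= {MIN_TRIALS_FULL} trials, got {n}"
        )
    if param not in _PARAMS:
        raise ValueError(f"unknown parameterisation {param!r}")
    to_sigma = _PARAMS[param]

    if method == "glmm_quadrature":
        tp, fn, fp, tn = _study_arrays(studies)

        def nll(theta):
            sigma = to_sigma(theta)
            return -_loglik_core(theta[:2], sigma, tp, fn, fp, tn, quad_nodes)

    elif method == "normal_approx":
        y, var = logit_pairs(studies)

        def nll(theta):
            return -_normal_approx_loglik(theta[:2], to_sigma(theta), y, var)

    else:
        raise ValueError(f"unknown method {method!r}")

    theta0 = _moment_start(studies)
    bounds = [(None, None), (None, None), _LOGSD_BOUNDS, _LOGSD_BOUNDS, _ATANH_BOUNDS]

    best = None
    rng = np.random.default_rng(20130525)  # deterministic jitter stream
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.3, 5)
        start = np.clip(start, [-20, -20, *np.array(bounds[2:])[:, 0]],
                        [20, 20, *np.array(bounds[2:])[:, 1]])
        res = optimize.minimize(
            nll, start, method="L-BFGS-B", bounds=bounds, jac="3-point",
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success:
            best = res if res.fun <= best.fun + 1e-10 else best
            break
    if not best.success:
        # gradient-free polish rescues line-search stalls on flat or
        # boundary likelihoods (e.g. correlation pinned at +-1)
        nm = optimize.minimize(
            nll, np.clip(best.x, [b[0] or -np.inf for b in bounds],
                         [b[1] or np.inf for b in bounds]),
            method="Nelder-Mead", bounds=bounds,
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9},
        )
        if nm.fun <= best.fun + 1e-10:
            best = nm
    converged = bool(best.success)
    theta_hat = best.x
    sigma_hat = to_sigma(theta_hat)

    H = _numerical_hessian(nll, theta_hat)
    cov_mu = _mu_covariance(H)

    fit = BivariateFit(
        mu=theta_hat[:2].copy(),
        sigma=sigma_hat,
        cov_mu=cov_mu,
        loglik=-float(best.fun),
        converged=converged,
        n_trials=n,
        method=method,
        quad_nodes=quad_nodes if method == "glmm_quadrature" else 0,
    )
    if not converged:
        raise ConvergenceError(
            f"bivariate fit did not converge after {max_restarts} restarts "
            f"({best.message})",
            best=fit,
        )
    return fit


def _mu_covariance(H: np.ndarray) -> np.ndarray:
    """Covariance of mu from the full-parameter Hessian of the NLL.

    Inverts the full 5x5 Hessian and takes the mu block so that the
    uncertainty in the variance components propagates into the means.
    Falls back to inverting the mu block alone if the full Hessian is
    numerically singular (variance components at the boundary).
    """
    try:
        cov = np.linalg.inv(H)
        block = cov[:2, :2]
        if np.all(np.isfinite(block)) and block[0, 0] > 0 and block[1, 1] > 0:
            return block
    except np.linalg.LinAlgError:
        pass
    return np.linalg.inv(H[:2, :2])


def pooled_summary(fit: BivariateFit, z: float = _Z95) -> PooledSummary:
    """Back-transform a converged fit into pooled accuracy summaries.

    Proportions get Wald CIs on the logit scale; PLR/NLR/DOR get
    delta-method Wald CIs on the log scale using ``cov_mu``.
    """
    mu1, mu2 = fit.mu
    cov = fit.cov_mu
    se_mu1, se_mu2 = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])

    sens = special.expit(mu1)
    spec = special.expit(mu2)
    sens_ci = tuple(special.expit(mu1 + s * z * se_mu1) for s in (-1, 1))
    spec_ci = tuple(special.expit(mu2 + s * z * se_mu2) for s in (-1, 1))

    plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec
    dor = plr / nlr

    # gradients of the log-ratios w.r.t. (mu1, mu2)
    g_plr = np.array([1.0 - sens, spec])
    g_nlr = np.array([-sens, -(1.0 - spec)])
    g_dor = np.array([1.0, 1.0])

    def ratio_ci(value, grad):
        var = float(grad @ cov @ grad)
        half = z * math.sqrt(max(var, 0.0))
        return (value * math.exp(-half), value * math.exp(half))

    return PooledSummary(
        sens=float(sens), sens_ci=sens_ci,
        spec=float(spec), spec_ci=spec_ci,
        plr=float(plr), plr_ci=ratio_ci(plr, g_plr),
        nlr=float(nlr), nlr_ci=ratio_ci(nlr, g_nlr),
        dor=float(dor), dor_ci=ratio_ci(dor, g_dor),
    )


def predict_region(
    fit: BivariateFit,
    level: float = 0.95,
    kind: str = "prediction",
    n_points: int = 200,
) -> np.ndarray:
    """Confidence or prediction contour in (FPR, sensitivity) space.

    The region is the ellipse {z : (z-mu)' M^{-1} (z-mu) = chi2_2(level)}
    on the (logit Se, logit Sp) scale with M = cov_mu (confidence) or
    M = Sigma + cov_mu (prediction), back-transformed pointwise.
    Returns an (n_points, 2) closed curve of (fpr, sens) rows.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if kind == "confidence":
        M = fit.cov_mu
    elif kind == "prediction":
        M = fit.sigma + fit.cov_mu
    else:
        raise ValueError(f"unknown kind {kind!r}")
    det = M[0, 0] * M[1, 1] - M[0, 1] ** 2
    if det <= 0 and not np.allclose(M, 0):
        raise DegenerateGeometryError("singular covariance; region is degenerate")
    r2 = stats.chi2.ppf(level, df=2)
    L = _chol_psd(M)
    t = np.linspace(0.0, 2.0 * math.pi, n_points)
    circle = np.vstack([np.cos(t), np.sin(t)])
    pts = fit.mu[:, None] + math.sqrt(r2) * (L @ circle)
    sens = special.expit(pts[0])
    fpr = special.expit(-pts[1])  # 1 - Sp = expit(-logit Sp)
    return np.column_stack([fpr, sens])


def mahalanobis_inside(fit: BivariateFit, point_logit, kind="prediction", level=0.95) -> bool:
    """Whether a (logit Se, logit Sp) point lies inside the region."""
    M = fit.cov_mu if kind == "confidence" else fit.sigma + fit.cov_mu
    d = np.asarray(point_logit, dtype=float) - fit.mu
    q = float(d @ np.linalg.solve(M, d))
    return q <= stats.chi2.ppf(level, df=2)
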