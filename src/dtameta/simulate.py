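"""Synthetic study sets from the hierarchical model, and recovery runs.

The generator draws, for each simulated trial, a latent
(logit Se, logit Sp) pair from N2(mu, Sigma), a total sample size and a
diseased fraction from configurable laws, then binomial cell counts —
exactly the generative structure the bivariate random-effects model
assumes.  Default sizes (totals uniform on [20, 300], diseased fraction
uniform on [0.3, 0.7]) echo the span of typical published diagnostic
trials of a circulating biomarker.

A single root seed spawns independent substreams per study and per
replicate, so any replicate can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import special

from .bivariate import fit_bivariate
from .data import Study2x2, StudySet
from .exceptions import ConvergenceError

__all__ = ["SimConfig", "simulate_studies", "parameter_recovery"]

_LAWS = ("fixed", "uniform_range", "lognormal")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study-set generator.

    ``mu`` is (mean logit sensitivity, mean logit specificity) and
    ``sigma`` the 2x2 between-study covariance on that scale.
    ``arm_size_law`` controls the total per-trial sample size:
    ``("fixed", n)``, ``("uniform_range", lo, hi)`` (integer-inclusive)
    or ``("lognormal", mean_log, sd_log)``.  ``prevalence_law`` uses the
    same family for the diseased fraction.
    """

    n_studies: int
    mu: tuple[float, float] = (1.0, 1.5)
    sigma: tuple[tuple[float, float], tuple[float, float]] = ((0.3, 0.0), (0.0, 0.3))
    arm_size_law: tuple = ("uniform_range", 20, 300)
    prevalence_law: tuple = ("uniform_range", 0.3, 0.7)
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        sig = np.asarray(self.sigma, dtype=float)
        if sig.shape != (2, 2) or not np.allclose(sig, sig.T):
            raise ValueError("sigma must be a symmetric 2x2 matrix")
        if sig[0, 0] < 0 or sig[1, 1] < 0 or np.linalg.det(sig) < -1e-12:
            raise ValueError("sigma must be positive semidefinite")
        for law in (self.arm_size_law, self.prevalence_law):
            if not law or law[0] not in _LAWS:
                raise ValueError(f"unknown law {law!r}; families: {_LAWS}")

    @property
    def sigma_array(self) -> np.ndarray:
        return np.asarray(self.sigma, dtype=float)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Read a config from YAML or JSON (keys match the field names)."""
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping of config fields")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "mu" in raw:
            raw["mu"] = tuple(raw["mu"])
        if "sigma" in raw:
            raw["sigma"] = tuple(tuple(r) for r in raw["sigma"])
        for k in ("arm_size_law", "prevalence_law"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def _draw_law(law: tuple, rng: np.random.Generator) -> float:
    kind = law[0]
    if kind == "fixed":
        return float(law[1])
    if kind == "uniform_range":
        lo, hi = float(law[1]), float(law[2])
        if float(lo).is_integer() and float(hi).is_integer() and hi > 1:
            return float(rng.integers(int(lo), int(hi) + 1))
        return float(rng.uniform(lo, hi))
    if kind == "lognormal":
        return float(rng.lognormal(float(law[1]), float(law[2])))
    raise ValueError(f"unknown law {kind!r}")


def simulate_studies(config: SimConfig) -> StudySet:
    """Generate a :class:`StudySet` from the hierarchical model.

    Per study i: (a_i, b_i) ~ N2(mu, Sigma); total n_i and diseased
    count n1_i from the configured laws (n1 clamped so both arms have
    at least one subject); tp_i ~ Bin(n1_i, expit(a_i)),
    tn_i ~ Bin(n2_i, expit(b_i)).  Deterministic given ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_studies)
    L = np.linalg.cholesky(
        config.sigma_array + 1e-12 * np.eye(2)
    ) if np.any(config.sigma_array) else np.zeros((2, 2))
    mu = np.asarray(config.mu, dtype=float)
    studies = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        z = rng.standard_normal(2)
        a, b = mu + L @ z
        total = max(2, int(round(_draw_law(config.arm_size_law, rng))))
        prev = min(max(_draw_law(config.prevalence_law, rng), 0.0), 1.0)
        n1 = int(round(total * prev))
        n1 = min(max(n1, 1), total - 1)
        n2 = total - n1
        tp = int(rng.binomial(n1, special.expit(a)))
        tn = int(rng.binomial(n2, special.expit(b)))
        studies.append(
            Study2x2(
                study_id=f"sim{i:04d}",
                tp=tp, fn=n1 - tp, fp=n2 - tn, tn=tn,
                sample_size=total,
            )
        )
    return StudySet(studies, provenance=f"simulated(seed={config.seed})")


def parameter_recovery(config: SimConfig, n_reps: int = 100) -> pd.DataFrame:
    """Repeated simulate-and-fit: bias, RMSE and CI coverage per parameter.

    Each replicate re-seeds the generator from a substream of
    ``config.seed``, simulates a study set, fits the bivariate model and
    records the estimates.  Coverage counts 95% Wald CIs (for the two
    means) that contain the truth.  Replicates whose fit fails to
    converge are counted but excluded from the summaries.
    """
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    root = np.random.SeedSequence(config.seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_reps)]
    truth = {
        "mu1": config.mu[0],
        "mu2": config.mu[1],
        "sigma1_sq": config.sigma_array[0, 0],
        "sigma2_sq": config.sigma_array[1, 1],
        "correlation": (
            config.sigma_array[0, 1]
            / np.sqrt(config.sigma_array[0, 0] * config.sigma_array[1, 1])
            if config.sigma_array[0, 0] > 0 and config.sigma_array[1, 1] > 0
            else 0.0
        ),
    }
    z = 1.959963984540054
    rows = []
    n_failed = 0
    for seed in rep_seeds:
        rep_cfg = dataclasses.replace(config, seed=seed)
        studies = simulate_studies(rep_cfg)
        try:
            fit = fit_bivariate(studies)
        except ConvergenceError:
            n_failed += 1
            continue
        se1 = np.sqrt(fit.cov_mu[0, 0])
        se2 = np.sqrt(fit.cov_mu[1, 1])
        rows.append(
            {
                "mu1": fit.mu[0],
                "mu2": fit.mu[1],
                "sigma1_sq": fit.sigma[0, 0],
                "sigma2_sq": fit.sigma[1, 1],
                "correlation": fit.correlation,
                "cover_mu1": abs(fit.mu[0] - truth["mu1"]) <= z * se1,
                "cover_mu2": abs(fit.mu[1] - truth["mu2"]) <= z * se2,
            }
        )
    if not rows:
        raise ConvergenceError("no replicate converged")
    est = pd.DataFrame(rows)
    out = []
    for name in ("mu1", "mu2", "sigma1_sq", "sigma2_sq", "correlation"):
        err = est[name] - truth[name]
        out.append(
            {
                "parameter": name,
                "truth": truth[name],
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
                "coverage": (
                    float(est[f"cover_{name}"].mean())
                    if f"cover_{name}" in est
                    else float("nan")
                ),
                "n_converged": len(est),
                "n_failed": n_failed,
            }
        )
    return pd.DataFrame(out)
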