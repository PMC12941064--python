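"""Binomial (Bernoulli-photon) model of Monte Carlo reflectance uncertainty.

Each launched photon is treated as an independent Bernoulli trial: success =
detected at the top surface, failure = absorbed or escaped at the bottom.
The reflectance is then the success probability with MLE
``r_hat = N_returned / N_total``, count-scale standard deviation
``sigma = sqrt(N_total r_hat (1 - r_hat))`` and coefficient of variation
``CoV = sqrt((1 - r_hat) / (N_total r_hat))``.

These closed forms provide first-principles lower error bounds (noise
floors) for surrogate fidelity analysis.  With weighted (implicit-capture)
transport the model is interpreted on effective counts
``N_returned = r_hat * N_total``; weighted-photon variance is bounded by the
analog binomial variance, so the model is a sound noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ErrorEstimate",
    "mle_reflectance",
    "reflectance_uncertainty",
    "prediction_interval",
    "noise_floor_sigma",
]


@dataclass(frozen=True)
class ErrorEstimate:
    """Uncertainty summary of a binomial reflectance estimate."""

    r_hat: float
    n_total: int
    sigma_counts: float
    sigma_reflectance: float
    cov: float
    pi_level: float
    pi_low: float
    pi_high: float


def mle_reflectance(n_returned, n_total):
    """Maximum-likelihood reflectance estimate N_returned / N_total."""
    n_returned = np.asarray(n_returned, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if np.any(n_total < 1):
        raise ValueError("n_total must be >= 1; the estimate is undefined otherwise")
    if np.any(n_returned < 0) or np.any(n_returned > n_total):
        raise ValueError("need 0 <= n_returned <= n_total")
    r = n_returned / n_total
    return r if r.ndim else float(r)


def noise_floor_sigma(r_hat, n_total):
    """Reflectance-scale binomial standard deviation sqrt(r(1-r)/N).

    Vectorized convenience used as the per-sample noise floor in surrogate
    fidelity analysis; returns 0 at r in {0, 1}.
    """
    r = np.asarray(r_hat, dtype=float)
    n = np.asarray(n_total, dtype=float)
    s = np.sqrt(np.clip(r * (1.0 - r), 0.0, None) / n)
    return s if s.ndim else float(s)


def reflectance_uncertainty(r_hat: float, n_total: int, pi_level: float = 0.95) -> ErrorEstimate:
    """Full binomial error summary for one reflectance estimate.

    Raises for r_hat outside (0, 1) when the CoV is requested implicitly;
    at the degenerate endpoints sigma is zero and the CoV undefined.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0.0 <= r_hat <= 1.0:
        raise ValueError("r_hat must lie in [0, 1]")
    sigma_counts = float(np.sqrt(n_total * r_hat * (1.0 - r_hat)))
    sigma_reflectance = sigma_counts / n_total
    if r_hat in (0.0, 1.0):
        cov = float("nan")  # undefined: signalled as NaN, sigma_counts = 0
    else:
        cov = float(np.sqrt((1.0 - r_hat) / (n_total * r_hat)))
    lo, hi = prediction_interval(r_hat, n_total, pi_level)
    return ErrorEstimate(
        r_hat=float(r_hat),
        n_total=int(n_total),
        sigma_counts=sigma_counts,
        sigma_reflectance=sigma_reflectance,
        cov=cov,
        pi_level=float(pi_level),
        pi_low=lo,
        pi_high=hi,
    )


def prediction_interval(r_hat: float, n_total: int, level: float = 0.95,
                        *, exact: bool = False):
    """Prediction interval for the binomial reflectance estimate.

    Default: normal approximation ``r_hat +/- z(level) * sigma_reflectance``
    clipped to [0, 1] (excellent at the photon counts used here).  With
    ``exact`` the Clopper-Pearson-style central binomial quantiles are used.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if exact:
        alpha = 1.0 - level
        lo = stats.binom.ppf(alpha / 2, n_total, r_hat) / n_total
        hi = stats.binom.ppf(1 - alpha / 2, n_total, r_hat) / n_total
        return float(lo), float(hi)
    z = stats.norm.ppf(0.5 + level / 2.0)
    sigma_r = np.sqrt(r_hat * (1.0 - r_hat) / n_total)
    return (
        float(np.clip(r_hat - z * sigma_r, 0.0, 1.0)),
        float(np.clip(r_hat + z * sigma_r, 0.0, 1.0)),
    )
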