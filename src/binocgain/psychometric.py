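"""Psychometric-function estimation for 2IFC binomial data.

A cumulative Gaussian on decibel contrast (C_dB = 20*log10(C%)) is the
underlying function, with the guess rate fixed at 0.5 and a small lapse
rate::

    psi(x) = 0.5 + (0.5 - lapse) * Phi((x - alpha) / sigma)

Estimation is by Bayesian numerical integration on a dense
(alpha, sigma, lapse) grid with a binomial likelihood: posterior means
and central credible intervals follow by direct summation, with no
sampling.  The threshold is reported at the 75%-absolute-correct point
of the lapse-corrected function, and the Gaussian slope converts to an
equivalent Weibull slope via beta = 10.3 / sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

__all__ = [
    "BETA_SIGMA_PRODUCT",
    "LevelCounts",
    "PsychometricFit",
    "to_dB",
    "from_dB",
    "fit_psychometric",
    "threshold_elevation",
]

#: Product of the equivalent Weibull slope and the Gaussian sigma in dB.
BETA_SIGMA_PRODUCT = 10.3


def to_dB(contrast_percent):
    """Contrast in % to decibels: ``20 * log10(C%)``; 1% maps to 0 dB."""
    c = np.asarray(contrast_percent, dtype=float)
    if np.any(c <= 0):
        raise ValueError("contrast must be positive")
    out = 20.0 * np.log10(c)
    return float(out) if out.ndim == 0 else out


def from_dB(db):
    """Inverse of :func:`to_dB`."""
    out = 10.0 ** (np.asarray(db, dtype=float) / 20.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LevelCounts:
    """Binomial counts of correct responses at each tested level (dB)."""

    levels_dB: tuple[float, ...]
    n_correct: tuple[int, ...]
    n_total: tuple[int, ...]

    def __post_init__(self) -> None:
        k = np.asarray(self.n_correct)
        n = np.asarray(self.n_total)
        x = np.asarray(self.levels_dB, dtype=float)
        if not (len(x) == len(k) == len(n)):
            raise ValueError("levels, n_correct, n_total must have equal length")
        if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= n_correct <= n_total, n_total >= 1")

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "LevelCounts":
        """Aggregate a trial table slice (columns target_norm, correct)."""
        g = trials.groupby("target_norm")["correct"].agg(["sum", "size"])
        levels_db = 20.0 * np.log10(np.asarray(g.index, dtype=float))
        return cls(
            tuple(levels_db),
            tuple(int(v) for v in g["sum"]),
            tuple(int(v) for v in g["size"]),
        )


@dataclass(frozen=True)
class PsychometricFit:
    """Posterior summary of a cumulative-Gaussian psychometric fit."""

    threshold_dB: float
    sigma_dB: float
    lapse: float
    threshold_ci: tuple[float, float]
    sigma_ci: tuple[float, float]
    guess: float = 0.5
    identifiable: bool = True

    @property
    def beta(self) -> float:
        """Equivalent Weibull slope, ``10.3 / sigma_dB``."""
        return BETA_SIGMA_PRODUCT / self.sigma_dB

    def predict(self, levels_dB) -> np.ndarray:
        x = np.asarray(levels_dB, dtype=float)
        return self.guess + (self.guess - self.lapse) * norm.cdf(
            (x - self._alpha()) / self.sigma_dB
        )

    def _alpha(self) -> float:
        # alpha from the 75%-correct threshold definition
        zc = norm.ppf((0.75 - self.guess) / (self.guess - self.lapse))
        return self.threshold_dB - self.sigma_dB * zc


def _threshold_from_alpha(alpha, sigma, lapse, guess=0.5, target_pc=0.75):
    """Level at which the lapse-corrected function hits ``target_pc``."""
    zc = norm.ppf((target_pc - guess) / (guess - lapse))
    return alpha + sigma * zc


def fit_psychometric(
    data: LevelCounts,
    lapse_max: float = 0.06,
    n_alpha: int = 81,
    n_sigma: int = 41,
    n_lapse: int = 7,
    sigma_range: tuple[float, float] = (0.3, 30.0),
    alpha_pad_dB: float = 6.0,
    ci: float = 0.95,
) -> PsychometricFit:
    """Fit a cumulative Gaussian by grid-based Bayesian integration.

    Priors: uniform on the location over the tested range (padded by
    ``alpha_pad_dB``), log-uniform on sigma over ``sigma_range``, and a
    Beta(1, 4)-shaped weighting on the lapse over [0, lapse_max].  The
    point estimate is the posterior mean of the derived threshold and of
    sigma; intervals are central posterior quantiles.  Degenerate data
    (all correct or all wrong) yield a near-flat posterior and are
    flagged ``identifiable=False`` rather than raising.
    """
    x = np.asarray(data.levels_dB, dtype=float)
    k = np.asarray(data.n_correct, dtype=float)
    n = np.asarray(data.n_total, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct levels")

    alphas = np.linspace(x.min() - alpha_pad_dB, x.max() + alpha_pad_dB, n_alpha)
    sigmas = np.exp(np.linspace(math.log(sigma_range[0]), math.log(sigma_range[1]), n_sigma))
    lapses = np.linspace(0.0, lapse_max, n_lapse)
    lapse_w = beta_dist.pdf(np.clip(lapses / max(lapse_max, 1e-12), 1e-9, 1 - 1e-9), 1.0, 4.0)
    lapse_w /= lapse_w.sum()

    # psi grid: (n_alpha, n_sigma, n_lapse, n_levels)
    z = (x[None, None, :] - alphas[:, None, None]) / sigmas[None, :, None]
    phi = norm.cdf(z)  # (A, S, L)
    psi = 0.5 + (0.5 - lapses[None, None, :, None]) * phi[:, :, None, :]
    psi = np.clip(psi, 1e-9, 1 - 1e-9)
    loglik = (k * np.log(psi) + (n - k) * np.log1p(-psi)).sum(axis=-1)
    loglik -= loglik.max()
    post = np.exp(loglik) * lapse_w[None, None, :]
    post /= post.sum()

    thr = _threshold_from_alpha(
        alphas[:, None, None], sigmas[None, :, None], lapses[None, None, :]
    )
    thr = np.broadcast_to(thr, post.shape)
    sig = np.broadcast_to(sigmas[None, :, None], post.shape)

    def _mean_and_ci(vals):
        mean = float((vals * post).sum())
        order = np.argsort(vals, axis=None)
        v = vals.ravel()[order]
        w = np.cumsum(post.ravel()[order])
        lo = float(v[np.searchsorted(w, (1 - ci) / 2)])
        hi = float(v[min(np.searchsorted(w, 1 - (1 - ci) / 2), v.size - 1)])
        return mean, (lo, hi)

    thr_mean, thr_ci = _mean_and_ci(thr)
    sig_mean, sig_ci = _mean_and_ci(sig)
    lapse_mean = float((np.broadcast_to(lapses[None, None, :], post.shape) * post).sum())

    # Non-identifiable data (e.g. all-correct or all-wrong everywhere)
    # pile posterior mass for the location against an edge of its prior
    # grid; flag when either outer 10% of the alpha axis carries more
    # than a quarter of the mass.
    alpha_marg = post.sum(axis=(1, 2))
    tail = max(1, n_alpha // 10)
    identifiable = (
        float(alpha_marg[:tail].sum()) < 0.25 and float(alpha_marg[-tail:].sum()) < 0.25
    )
    return PsychometricFit(
        threshold_dB=thr_mean,
        sigma_dB=sig_mean,
        lapse=lapse_mean,
        threshold_ci=thr_ci,
        sigma_ci=sig_ci,
        identifiable=bool(identifiable),
    )


def threshold_elevation(masked: PsychometricFit, baseline: PsychometricFit) -> float:
    """Masked / baseline threshold as a linear contrast ratio."""
    return float(10.0 ** ((masked.threshold_dB - baseline.threshold_dB) / 20.0))
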