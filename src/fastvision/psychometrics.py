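"""Maximum-likelihood cumulative-Gaussian psychometric fitting and
75%-correct threshold extraction.

The model is the 2AFC psychometric function used by the synthetic observers:
P(correct | c) = guess + (1 - guess - lapse) * Phi((c - mu)/sigma) with the
guess rate fixed at 0.5.  Fitting maximizes the Bernoulli/binomial
likelihood of the per-level counts (the correct likelihood for binary
trials); a least-squares mode on proportions is available for sensitivity
checks.  The lapse rate is either fixed (control tasks) or free up to a
ceiling (the image task, whose performance saturates near 90%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

__all__ = [
    "PsychFit",
    "ThresholdEstimate",
    "pool_proportions",
    "fit_cumulative_gaussian",
    "fit_trials",
    "threshold_at",
]

GUESS = 0.5
_PCLIP = 1e-9


@dataclass(frozen=True)
class PsychFit:
    """Fitted psychometric parameters plus fit diagnostics."""

    mu_hat: float
    sigma_hat: float
    lapse_hat: float
    log_likelihood: float
    converged: bool
    n_trials: int
    lapse_mode: str
    guess: float = GUESS
    message: str = ""

    def predict(self, c):
        """Model proportion correct at contrast ``c``."""
        c = np.asarray(c, dtype=float)
        p = self.guess + (1 - self.guess - self.lapse_hat) * ndtr(
            (c - self.mu_hat) / self.sigma_hat
        )
        return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class ThresholdEstimate:
    """Contrast yielding criterion performance on the fitted curve."""

    T: float
    criterion: float = 0.75
    subject: str | None = None
    task: str | None = None
    condition: str | None = None
    extrapolated: bool = False


def pool_proportions(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-contrast trial counts and proportion correct (exact counts)."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    g = trials.groupby("contrast", sort=True)["correct"]
    out = g.agg(n="count", k="sum").reset_index()
    out["k"] = out["k"].astype(float)
    out["proportion"] = out["k"] / out["n"]
    return out


def _nll_terms(levels, k, n, mu, sigma, lapse):
    p = GUESS + (1 - GUESS - lapse) * ndtr((levels - mu) / sigma)
    p = np.clip(p, _PCLIP, 1 - _PCLIP)
    return p, -(k * np.log(p) + (n - k) * np.log1p(-p)).sum()


def _pack_objective(levels, k, n, lapse_mode, lapse_value, lapse_max, loss):
    free_lapse = lapse_mode == "free"

    def unpack(theta):
        mu = theta[0]
        sigma = np.exp(theta[1])
        if free_lapse:
            s = 1.0 / (1.0 + np.exp(-theta[2]))
            lapse = lapse_max * s
        else:
            lapse = lapse_value
        return mu, sigma, lapse

    def fun(theta):
        mu, sigma, lapse = unpack(theta)
        if loss == "mle":
            _, val = _nll_terms(levels, k, n, mu, sigma, lapse)
            return val
        p = GUESS + (1 - GUESS - lapse) * ndtr((levels - mu) / sigma)
        return float((n * (k / n - p) ** 2).sum())

    def grad(theta):
        # analytic gradient of the negative binomial log-likelihood
        mu, sigma, lapse = unpack(theta)
        z = (levels - mu) / sigma
        span = 1 - GUESS - lapse
        p = np.clip(GUESS + span * ndtr(z), _PCLIP, 1 - _PCLIP)
        dldp = -(k / p - (n - k) / (1 - p))
        phi = np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
        g_mu = (dldp * span * phi * (-1.0 / sigma)).sum()
        g_logsig = (dldp * span * phi * (-z)).sum()
        if free_lapse:
            s = lapse / lapse_max
            g_l = (dldp * (-ndtr(z)) * lapse_max * s * (1 - s)).sum()
            return np.array([g_mu, g_logsig, g_l])
        return np.array([g_mu, g_logsig])

    return fun, (grad if loss == "mle" else None), unpack, free_lapse


def fit_cumulative_gaussian(
    levels: Sequence[float],
    successes: Sequence[float],
    totals: Sequence[float],
    lapse_mode: str = "fixed",
    lapse_value: float = 0.0,
    lapse_max: float = 0.15,
    loss: str = "mle",
) -> PsychFit:
    """Fit the 2AFC cumulative-Gaussian model to per-level counts.

    ``successes`` may be fractional (e.g. proportion * totals) — the
    binomial objective handles non-integer counts, which makes noiseless
    self-consistency checks exact.  Degenerate data (fewer than two distinct
    levels, all trials correct, or a fit pinned at the parameter bounds)
    come back with ``converged=False`` rather than a silent estimate.
    """
    levels = np.asarray(levels, dtype=float)
    k = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if levels.size != k.size or levels.size != n.size:
        raise ValueError("levels, successes and totals must be equal length")
    if np.unique(levels).size < 2:
        raise ValueError("need at least 2 distinct contrast levels")
    if (k < 0).any() or (k > n + 1e-9).any() or (n <= 0).any():
        raise ValueError("need 0 <= successes <= totals and totals > 0")
    if lapse_mode not in ("fixed", "free"):
        raise ValueError("lapse_mode must be 'fixed' or 'free'")
    if loss not in ("mle", "ls"):
        raise ValueError("loss must be 'mle' or 'ls'")

    n_trials = int(round(n.sum()))
    if np.allclose(k, n):
        return PsychFit(
            mu_hat=float("nan"), sigma_hat=float("nan"), lapse_hat=float("nan"),
            log_likelihood=0.0, converged=False, n_trials=n_trials,
            lapse_mode=lapse_mode, message="all responses correct: unidentifiable",
        )

    lo, hi = levels.min(), levels.max()
    span = hi - lo
    fun, grad, unpack, free_lapse = _pack_objective(
        levels, k, n, lapse_mode, lapse_value, lapse_max, loss
    )

    # crude threshold guess from the running-max of the observed proportions
    props = k / n
    run = np.maximum.accumulate(props)
    target = GUESS + 0.5 * (1 - GUESS - (lapse_value if lapse_mode == "fixed" else 0.05))
    idx = int(np.searchsorted(run, target))
    mu0 = levels[min(idx, levels.size - 1)]

    bounds = [(lo - 3 * span, hi + 3 * span), (np.log(span) - 8, np.log(span) + 4)]
    starts = [
        [mu0, np.log(span / 4)],
        [mu0, np.log(span / 10)],
        [0.5 * (lo + hi), np.log(span / 2)],
    ]
    if free_lapse:
        bounds.append((-12.0, 12.0))
        starts = [s + [-2.0] for s in starts] + [[mu0, np.log(span / 4), 0.0]]

    best = None
    for x0 in starts:
        res = minimize(
            fun, np.asarray(x0, dtype=float), jac=grad, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not best.success and grad is not None:
        # simplex fallback from the best point found so far
        res = minimize(
            fun, best.x, method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if res.fun <= best.fun:
            best = res

    mu, sigma, lapse = unpack(best.x)
    tol = 1e-6
    at_bound = (
        mu <= bounds[0][0] + tol
        or mu >= bounds[0][1] - tol
        or best.x[1] <= bounds[1][0] + tol
        or best.x[1] >= bounds[1][1] - tol
    )
    converged = bool(best.success or best.fun < np.inf) and not at_bound
    _, nll = _nll_terms(levels, k, n, mu, sigma, lapse)
    return PsychFit(
        mu_hat=float(mu),
        sigma_hat=float(sigma),
        lapse_hat=float(lapse),
        log_likelihood=float(-nll),
        converged=converged,
        n_trials=n_trials,
        lapse_mode=lapse_mode,
        message="" if converged else "fit at parameter bound or failed",
    )


def fit_trials(trials: pd.DataFrame, **kwargs) -> PsychFit:
    """Aggregate a tidy trial table to per-level counts and fit."""
    pooled = pool_proportions(trials)
    return fit_cumulative_gaussian(
        pooled["contrast"].to_numpy(),
        pooled["k"].to_numpy(),
        pooled["n"].to_numpy(),
        **kwargs,
    )


def threshold_at(
    fit: PsychFit,
    criterion: float = 0.75,
    subject: str | None = None,
    task: str | None = None,
    condition: str | None = None,
    ladder: Sequence[float] | None = None,
) -> ThresholdEstimate:
    """Invert the fitted curve at ``criterion`` proportion correct.

    The fitted curve is analytically invertible:
    T = mu + sigma * Phi^-1((criterion - guess) / (1 - guess - lapse)).
    Raises if the fit did not converge or the criterion is unattainable
    (at or above the fitted asymptote).  If the task's contrast ladder is
    given, thresholds outside its range are flagged as extrapolated.
    """
    if not fit.converged:
        raise ValueError("cannot extract a threshold from a non-converged fit")
    asymptote = 1 - fit.lapse_hat
    if not fit.guess < criterion < asymptote:
        raise ValueError(
            f"criterion {criterion} unattainable: must lie strictly between "
            f"guess {fit.guess} and asymptote {asymptote:.4f}"
        )
    z = ndtri((criterion - fit.guess) / (1 - fit.guess - fit.lapse_hat))
    T = fit.mu_hat + fit.sigma_hat * z
    extrapolated = False
    if ladder is not None:
        lad = np.asarray(ladder, dtype=float)
        extrapolated = bool(T < lad.min() or T > lad.max())
    return ThresholdEstimate(
        T=float(T),
        criterion=criterion,
        subject=subject,
        task=task,
        condition=condition,
        extrapolated=extrapolated,
    )
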