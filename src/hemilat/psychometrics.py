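"""Psychometric-function fitting and behavioral scoring.

Speech reception thresholds come from a two-parameter logistic psychometric
function fitted to percent-correct vs signal-to-noise ratio (SNR) data:

    P(snr) = 1 / (1 + exp(-(snr - alpha) / beta))

``alpha`` is the SNR at 50% correct (the threshold, in dB) and ``beta`` the
slope scale (dB). Guess and lapse rates are fixed at 0. The fit is ordinary
least squares on observed proportions via the Levenberg-Marquardt algorithm.
The task threshold for a masker type averages the fitted alpha over the two
spatial configurations (target-masker colocated / separated).

Also scores the auditory digit-span task (longest list repeated, forward +
backward, stopping when both trials of a length fail) and the auditory
Stroop interference time (asynchronous minus synchronous; larger = poorer
inhibition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import DegenerateSignalError, NumericError

DEFAULT_SNR_LEVELS = (-12.0, -8.0, -4.0, 0.0, 4.0)


@dataclass(frozen=True)
class PsychometricData:
    """Trial counts per SNR level for one subject x masker x spatial condition."""

    snr: np.ndarray
    n_trials: np.ndarray
    #: may be fractional (e.g. exact expected counts or averaged sessions)
    n_correct: np.ndarray

    def __post_init__(self) -> None:
        snr = np.asarray(self.snr, dtype=float)
        nt = np.asarray(self.n_trials, dtype=int)
        nc = np.asarray(self.n_correct, dtype=float)
        if not (len(snr) == len(nt) == len(nc)):
            raise ValueError("snr, n_trials and n_correct must have equal length")
        if len(np.unique(snr)) < 3:
            raise ValueError("need at least 3 distinct SNR levels")
        if np.any(nc < 0) or np.any(nc > nt) or np.any(nt <= 0):
            raise ValueError("require 0 <= n_correct <= n_trials and n_trials > 0")
        object.__setattr__(self, "snr", snr)
        object.__setattr__(self, "n_trials", nt)
        object.__setattr__(self, "n_correct", nc)

    @property
    def proportions(self) -> np.ndarray:
        return self.n_correct / self.n_trials


@dataclass(frozen=True)
class PsychometricFit:
    alpha: float  # 50%-correct SNR, dB
    beta: float  # slope scale, dB
    rss: float
    converged: bool
    n_iterations: int = 0
    #: true when the observed proportions span [0.05, 0.95] reasonably
    well_covered: bool = True


def logistic(snr: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    return expit((np.asarray(snr, dtype=float) - alpha) / beta)


def fit_logistic(
    data: PsychometricData,
    init: tuple[float, float] | None = None,
    max_iterations: int = 200,
    tol: float = 1e-10,
) -> PsychometricFit:
    """Least-squares logistic fit; alpha is the 50% threshold.

    Initialization: alpha0 = the SNR level whose proportion is nearest 0.5,
    beta0 = 1 dB (overridable via ``init``). beta is kept positive by fitting
    log(beta).
    """
    p = data.proportions
    if np.all(p == p[0]):
        raise DegenerateSignalError("all proportions identical; threshold undefined")
    if init is None:
        alpha0 = float(data.snr[np.argmin(np.abs(p - 0.5))])
        beta0 = 1.0
    else:
        alpha0, beta0 = float(init[0]), float(init[1])
        if beta0 <= 0:
            raise ValueError("initial beta must be positive")

    def residuals(theta: np.ndarray) -> np.ndarray:
        alpha, log_beta = theta
        return logistic(data.snr, alpha, float(np.exp(log_beta))) - p

    sol = least_squares(
        residuals,
        x0=np.array([alpha0, np.log(beta0)]),
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iterations * 3,
    )
    alpha, beta = float(sol.x[0]), float(np.exp(sol.x[1]))
    covered = bool(p.min() <= 0.35 and p.max() >= 0.65)
    return PsychometricFit(
        alpha=alpha,
        beta=beta,
        rss=float(2.0 * sol.cost),
        converged=bool(sol.success),
        n_iterations=int(sol.nfev),
        well_covered=covered,
    )


def threshold_across_conditions(fits: Sequence[PsychometricFit]) -> float:
    """Masker-type threshold: mean fitted alpha over the spatial conditions."""
    if not fits:
        raise ValueError("need at least one fit")
    for f in fits:
        if not f.converged:
            raise NumericError("cannot average an unconverged psychometric fit")
    return float(np.mean([f.alpha for f in fits]))


def score_digit_span(trials: Sequence[tuple[int, Sequence[bool]]], start_length: int | None = None) -> int:
    """Longest list length passed before the first length where both trials fail.

    ``trials`` is an ordered sequence of (length, [trial1_correct,
    trial2_correct, ...]) with consecutive lengths. Returns start_length - 1
    when both trials of the first length fail.
    """
    if not trials:
        raise ValueError("no trials")
    lengths = [t[0] for t in trials]
    if lengths != list(range(lengths[0], lengths[0] + len(lengths))):
        raise ValueError("trial lengths must be consecutive from the starting length")
    first = start_length if start_length is not None else lengths[0]
    best = first - 1
    for length, outcomes in trials:
        if not any(outcomes):
            break
        best = length
    return best


def score_stroop(sync_time: float, async_time: float) -> float:
    """Stroop interference: asynchronous minus synchronous response time (s)."""
    if sync_time <= 0 or async_time <= 0:
        raise ValueError("response times must be positive")
    return float(async_time - sync_time)
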