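"""Rhythmicity statistics: lack-of-fit F-test, Kendall agreement, FDR, regulation.

A feature is called rhythmic when the selected waveform model explains
significantly more variance than its zero-amplitude reduction (a constant
at the equilibrium value y) by a lack-of-fit F-test, AND the fitted
values agree with the observations by Kendall's tau.  Both p-value
families are Benjamini-Hochberg adjusted across all features in a batch,
and a feature must pass both adjusted thresholds.

Regulatory behaviour is read off the amplitude-change coefficient gamma:
damped (gamma below -threshold), forced (above +threshold), stable
(within the threshold band).  The transient family carries no gamma
envelope, so its regulation class is always "not applicable".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .fitting import FitResult, TimeSeries
from .models import ModelParameters, WaveformKind

__all__ = [
    "Regulation",
    "RhythmCall",
    "zero_amplitude_f_test",
    "kendall_agreement",
    "bh_adjust",
    "classify_regulation",
]


class Regulation(str, Enum):
    DAMPED = "damped"
    FORCED = "forced"
    STABLE = "stable"
    NOT_APPLICABLE = "not_applicable"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass
class RhythmCall:
    """Per-feature verdict assembled by the pipeline."""

    feature_id: str
    best: FitResult
    f_stat: float
    f_p: float
    tau: float
    tau_p: float
    f_q: float = math.nan
    tau_q: float = math.nan
    regulation: Regulation = Regulation.NOT_APPLICABLE
    rhythmic: bool = False
    perfect_fit: bool = False
    degenerate_tau: bool = False


def zero_amplitude_f_test(series: TimeSeries, best: FitResult) -> tuple[float, float]:
    """Lack-of-fit F-test of the best model against its zero-amplitude reduction.

    The null model keeps all optimal parameters but forces A = 0, which
    reduces every prediction to the constant y.  With n observations and
    p model parameters, q = p - 1 shape parameters become inert under
    A = 0, giving

        F = ((SSR0 - SSR1) / q) / (SSR1 / (n - p)),   F ~ F(q, n - p)

    where SSR1 is the best model's residual sum of squares and SSR0 the
    null's.  SSR0 < SSR1 clamps to F = 0.  A perfect fit (SSR1 = 0 with
    non-trivial amplitude improvement) reports p = 0 rather than dividing
    by zero; callers see this via the returned p-value being exactly 0.

    Returns
    -------
    (f_stat, f_p)
    """
    if not best.converged:
        return 0.0, 1.0
    n, p = best.n_obs, best.n_params
    if n <= p:
        raise ValueError(f"F-test requires n_obs > n_params ({n} <= {p})")
    q = p - 1
    ssr1 = best.ssr
    resid0 = series.values - best.params.y
    ssr0 = float(np.dot(resid0, resid0))
    if ssr1 <= 0.0:
        if ssr0 > ssr1:
            return math.inf, 0.0
        return 0.0, 1.0
    f_stat = ((ssr0 - ssr1) / q) / (ssr1 / (n - p))
    if f_stat <= 0.0:
        return 0.0, 1.0
    f_p = float(sps.f.sf(f_stat, q, n - p))
    return float(f_stat), f_p


def kendall_agreement(observed, fitted) -> tuple[float, float]:
    """Kendall's tau (tie-corrected, tau-b) between observed and fitted values.

    Two-sided p-value; the exact pair-count distribution is used for small
    untied samples, the normal approximation otherwise.  Degenerate input
    (all observed or all fitted values tied) reports tau = 0, p = 1.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValueError("observed and fitted must have equal length")
    if observed.size < 3:
        raise ValueError("kendall_agreement requires at least 3 observations")
    if np.ptp(observed) == 0.0 or np.ptp(fitted) == 0.0:
        return 0.0, 1.0
    res = sps.kendalltau(observed, fitted)
    tau, p = float(res.statistic), float(res.pvalue)
    if math.isnan(tau):
        return 0.0, 1.0
    return tau, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_regulation(
    params: ModelParameters, kind: WaveformKind | str, threshold: float = 0.01
) -> Regulation:
    """Classify regulatory behaviour from the amplitude-change coefficient.

    Parameters
    ----------
    threshold : float
        Half-width of the "stable" band on gamma, per hour.  The default
        0.01/h allows roughly a +-27% envelope change over 48 h.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kind = WaveformKind(kind)
    if kind is WaveformKind.TRANSIENT:
        return Regulation.NOT_APPLICABLE
    g = params.gamma
    if g < -threshold:
        return Regulation.DAMPED
    if g > threshold:
        return Regulation.FORCED
    return Regulation.STABLE
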