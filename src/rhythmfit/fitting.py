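"""Per-feature nonlinear least-squares fitting and SSR-based model selection.

Each of the four waveform families is fitted to one feature's time course
by bounded nonlinear least squares (scipy ``least_squares``, trust-region
reflective).  Phase and impulse location are the multimodal axes of the
objective, so fitting multi-starts over a phase grid (oscillatory
families) or a grid of candidate impulse offsets taken from the per-cycle
maxima (transient family).  The family with the lowest sum of squared
residuals (SSR) is selected as optimal.

Replicates are fitted as individual observations, never averaged, which
preserves the error degrees of freedom used downstream by the
lack-of-fit F-test.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .models import (
    N_PARAMS,
    PARAM_NAMES,
    TWO_PI,
    ModelParameters,
    WaveformKind,
    evaluate,
)

__all__ = ["TimeSeries", "FitResult", "FitConfig", "fit_model", "fit_all_models", "select_best"]

logger = logging.getLogger(__name__)

KIND_ORDER = (
    WaveformKind.HARMONIC,
    WaveformKind.SQUARE,
    WaveformKind.CYCLOID,
    WaveformKind.TRANSIENT,
)


@dataclass
class TimeSeries:
    """One molecule's observations: times (hours), values, replicate labels.

    Times may repeat across replicates; observations are kept replicate-
    resolved.  A minimum of six observations is required to fit the
    largest model.
    """

    feature_id: str
    times: np.ndarray
    values: np.ndarray
    replicates: np.ndarray | None = None
    normalized_flag: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError(
                f"{self.feature_id}: times and values must have equal length "
                f"({self.times.size} != {self.values.size})"
            )
        if self.replicates is None:
            self.replicates = np.asarray(["r1"] * self.times.size)
        else:
            self.replicates = np.asarray(self.replicates)
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.values = self.values[order]
        self.replicates = self.replicates[order]

    @property
    def n_obs(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class FitResult:
    """Outcome of fitting one waveform family to one feature."""

    kind: WaveformKind
    params: ModelParameters
    ssr: float
    rmse: float
    fitted: np.ndarray
    converged: bool
    n_obs: int
    n_params: int
    perfect_fit: bool = False

    @classmethod
    def from_params(
        cls, kind: WaveformKind, params: ModelParameters, series: TimeSeries, converged: bool
    ) -> "FitResult":
        fitted = evaluate(kind, params, series.times)
        resid = series.values - fitted
        ssr = float(np.dot(resid, resid))
        n = series.n_obs
        return cls(
            kind=kind,
            params=params,
            ssr=ssr,
            rmse=math.sqrt(ssr / n),
            fitted=fitted,
            converged=converged,
            n_obs=n,
            n_params=N_PARAMS[kind],
        )


@dataclass
class FitConfig:
    """Fitting options.

    Parameters
    ----------
    expected_period : float
        Expected oscillation period in hours (default 24, circadian).
    period_tolerance : float
        Fractional search half-width rho for the period: omega is bounded
        to [2*pi/(T*(1+rho)), 2*pi/(T*(1-rho))].
    n_phase_starts : int
        Equispaced initial phases in [0, 2*pi) for the oscillatory families.
    gamma_max : float | None
        Cap on |gamma|; None derives 6/t_max so the envelope changes by at
        most e^(+-3) over the observed span.
    min_obs : int
        Minimum observations required to fit (>= largest model + 1).
    """

    expected_period: float = 24.0
    period_tolerance: float = 0.25
    n_phase_starts: int = 8
    gamma_max: float | None = None
    min_obs: int = 6
    xtol: float = 1e-8
    ftol: float = 1e-8
    max_nfev: int = 5000

    def __post_init__(self) -> None:
        if not (0.0 < self.period_tolerance < 1.0):
            raise ValueError(f"period_tolerance must be in (0, 1), got {self.period_tolerance}")
        if self.expected_period <= 0:
            raise ValueError("expected_period must be positive")

    def omega_bounds(self) -> tuple[float, float]:
        T, rho = self.expected_period, self.period_tolerance
        return TWO_PI / (T * (1.0 + rho)), TWO_PI / (T * (1.0 - rho))

    def effective_gamma_max(self, t_max: float) -> float:
        if self.gamma_max is not None:
            return self.gamma_max
        return 6.0 / max(t_max, 1e-12)


def _constant_fit(series: TimeSeries, kind: WaveformKind, config: FitConfig, converged: bool) -> FitResult:
    """Zero-amplitude fit at the sample mean (flat input / total fallback)."""
    y0 = float(np.mean(series.values))
    params = ModelParameters(
        A=0.0, gamma=0.0, omega=TWO_PI / config.expected_period, phi=0.0, y=y0,
        p_tau=0.0, sigma=max(_sampling_interval(series), 1e-6),
    )
    return FitResult.from_params(kind, params, series, converged=converged)


def _sampling_interval(series: TimeSeries) -> float:
    diffs = np.diff(np.unique(series.times))
    return float(np.min(diffs)) if diffs.size else 1.0


def _unpack(kind: WaveformKind, x: np.ndarray) -> ModelParameters:
    kw = dict(zip(PARAM_NAMES[kind], (float(v) for v in x)))
    return ModelParameters(**kw)


# Oscillatory shape functions S(a) and derivatives S'(a); the model is
# A*exp(g*t/2)*S(w*t + phi) + y for each family.
_SHAPES = {
    WaveformKind.HARMONIC: (
        lambda a: np.cos(a),
        lambda a: -np.sin(a),
    ),
    WaveformKind.SQUARE: (
        lambda a: np.sin(a) + 0.25 * np.sin(3.0 * a),
        lambda a: np.cos(a) + 0.75 * np.cos(3.0 * a),
    ),
    WaveformKind.CYCLOID: (
        lambda a: -0.5 * (np.cos(2.0 * a) - 2.0 * np.cos(a)),
        lambda a: np.sin(2.0 * a) - np.sin(a),
    ),
}


def _residual_and_jac(kind: WaveformKind, series: TimeSeries):
    """Residual and analytic jacobian in x = (A, gamma, omega, phi, y)."""
    t, v = series.times, series.values
    shape, dshape = _SHAPES[kind]

    def resid(x: np.ndarray) -> np.ndarray:
        A, g, w, phi, y = x
        return A * np.exp(g * t / 2.0) * shape(w * t + phi) + y - v

    def jac(x: np.ndarray) -> np.ndarray:
        A, g, w, phi, y = x
        env = np.exp(g * t / 2.0)
        a = w * t + phi
        s, ds = shape(a), dshape(a)
        J = np.empty((t.size, 5))
        J[:, 0] = env * s
        J[:, 1] = A * (t / 2.0) * env * s
        J[:, 2] = A * env * ds * t
        J[:, 3] = A * env * ds
        J[:, 4] = 1.0
        return J

    return resid, jac


def _value_envelope(series: TimeSeries) -> tuple[float, float, float, float]:
    """(A_hi, y_lo, y_hi, spread) box derived from the data range."""
    v_lo, v_hi = float(np.min(series.values)), float(np.max(series.values))
    spread = max(v_hi - v_lo, 1e-9)
    return max(4.0 * spread, 1e-6), v_lo - 2.0 * spread, v_hi + 2.0 * spread, spread


def _oscillatory_starts_and_bounds(
    series: TimeSeries, config: FitConfig
) -> tuple[list[np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Deterministic multi-start phase grid and box bounds (A, gamma, omega, phi, y)."""
    v = series.values
    w_lo, w_hi = config.omega_bounds()
    w0 = TWO_PI / config.expected_period
    A0 = (float(np.max(v)) - float(np.min(v))) / 2.0
    y0 = float(np.mean(v))
    g_max = config.effective_gamma_max(float(series.times[-1]) or config.expected_period)
    A_hi, y_lo, y_hi = _value_envelope(series)[:3]
    lo = np.array([0.0, -g_max, w_lo, -TWO_PI, y_lo])
    hi = np.array([A_hi, g_max, w_hi, 2.0 * TWO_PI, y_hi])
    starts = [
        np.array([max(A0, 1e-6), 0.0, w0, phi0, y0])
        for phi0 in np.linspace(0.0, TWO_PI, config.n_phase_starts, endpoint=False)
    ]
    return starts, (lo, hi)


def _transient_candidates(series: TimeSeries, config: FitConfig) -> list[float]:
    """Impulse-offset candidates: observed timepoints of the per-cycle maximum."""
    T = config.expected_period
    u = np.mod(series.times, T)
    dt = _sampling_interval(series)
    n_cycles = max(1, int(math.ceil((series.times[-1] + dt) / T)))
    cands: list[float] = []
    for c in range(n_cycles):
        in_cycle = np.flatnonzero((series.times >= c * T) & (series.times < (c + 1) * T))
        if in_cycle.size:
            idx = in_cycle[np.argmax(series.values[in_cycle])]
            cands.append(float(u[idx]))
    out: list[float] = []
    for c in cands:
        if all(abs(c - s) > 1e-9 for s in out):
            out.append(c)
    return out


def _fit_transient(series: TimeSeries, config: FitConfig) -> FitResult:
    """Profile fit of the transient family.

    The onset gate makes the objective discontinuous in p_tau, so p_tau is
    never handed to the gradient-based optimiser: the four smooth
    parameters (A, omega, sigma, y) are fitted with p_tau frozen at each
    candidate, and p_tau is then refined on a fine local grid (step dt/20
    around the winning candidate, where dt is the sampling interval).  The
    true onset lies at most one sampling interval before the per-cycle
    maximum, so the refinement window [cand - dt, cand + dt/2] covers it.
    """
    kind = WaveformKind.TRANSIENT
    t, v = series.times, series.values
    w_lo, w_hi = config.omega_bounds()
    w0 = TWO_PI / config.expected_period
    dt = _sampling_interval(series)
    T = config.expected_period
    A_hi, y_lo, y_hi = _value_envelope(series)[:3]
    sig_lo, sig_hi = dt / 2.0, T / 4.0
    sig0 = min(max(dt, sig_lo), sig_hi)
    lo = np.array([0.0, w_lo, sig_lo, y_lo])
    hi = np.array([A_hi, w_hi, sig_hi, y_hi])
    A0 = max(float(np.max(v)) - float(np.mean(v)), 1e-3)
    y0 = float(np.clip(np.median(v), y_lo, y_hi))

    def solve(p_tau: float, x0: np.ndarray):
        def parts(x: np.ndarray):
            A, w, sig, y = x
            period = TWO_PI / w
            cycle = np.floor(t / period)
            d = t - cycle * period - p_tau
            g = np.where(d >= 0.0, np.exp(-0.5 * (d / sig) ** 2), 0.0)
            return A, w, sig, y, cycle, d, g

        def resid(x: np.ndarray) -> np.ndarray:
            A, w, sig, y, _, _, g = parts(x)
            return A * g + y - v

        def jac(x: np.ndarray) -> np.ndarray:
            # Analytic away from the gate/modulo discontinuities (measure zero).
            A, w, sig, y, cycle, d, g = parts(x)
            J = np.empty((t.size, 4))
            J[:, 0] = g
            J[:, 1] = A * g * (-d / sig**2) * cycle * (TWO_PI / w**2)
            J[:, 2] = A * g * d**2 / sig**3
            J[:, 3] = 1.0
            return J

        try:
            sol = least_squares(
                resid, np.clip(x0, lo, hi), jac=jac, bounds=(lo, hi), method="trf",
                xtol=config.xtol, ftol=config.ftol, gtol=config.xtol,
                max_nfev=max_nfev or config.max_nfev,
            )
        except Exception as exc:  # pragma: no cover
            logger.warning("%s/transient: p_tau=%.3g start failed: %s", series.feature_id, p_tau, exc)
            return None
        return sol if sol.success else None

    x_init = np.array([A0, w0, sig0, y0])
    max_nfev = 0  # full budget for the candidate starts
    best: tuple[float, float, np.ndarray] | None = None  # (ssr, p_tau, x)
    for cand in _transient_candidates(series, config):
        sol = solve(cand, x_init)
        if sol is not None and (best is None or 2.0 * sol.cost < best[0]):
            best = (2.0 * sol.cost, cand, sol.x)
    if best is None:
        return _constant_fit(series, kind, config, converged=False)

    # Coarse-to-fine local search over p_tau around the winning candidate,
    # warm-started and iteration-capped (refits start near the optimum).
    ssr_best, p_best, x_best = best
    max_nfev = 100
    for step in (dt / 4.0, dt / 16.0):
        if ssr_best <= 1e-20:
            break
        for k in (-4, -3, -2, -1, 1, 2):
            p_cand = p_best + k * step
            if p_cand < 0.0:
                continue
            sol = solve(float(p_cand), x_best)
            if sol is not None and 2.0 * sol.cost < ssr_best - 1e-15:
                ssr_best, p_best, x_best = 2.0 * sol.cost, float(p_cand), sol.x

    # Final polish with p_tau free: within the open region between gate
    # crossings the objective is smooth, so an analytic-jacobian solve
    # sharpens p_tau beyond the grid resolution.
    if ssr_best > 1e-20:
        p_hi = T * (1.0 + config.period_tolerance)
        lo5 = np.array([0.0, w_lo, 0.0, sig_lo, y_lo])
        hi5 = np.array([A_hi, w_hi, p_hi, sig_hi, y_hi])

        def resid5(x: np.ndarray) -> np.ndarray:
            A, w, p_tau, sig, y = x
            period = TWO_PI / w
            d = t - np.floor(t / period) * period - p_tau
            g = np.where(d >= 0.0, np.exp(-0.5 * (d / sig) ** 2), 0.0)
            return A * g + y - v

        def jac5(x: np.ndarray) -> np.ndarray:
            A, w, p_tau, sig, y = x
            period = TWO_PI / w
            cycle = np.floor(t / period)
            d = t - cycle * period - p_tau
            g = np.where(d >= 0.0, np.exp(-0.5 * (d / sig) ** 2), 0.0)
            J = np.empty((t.size, 5))
            J[:, 0] = g
            J[:, 1] = A * g * (-d / sig**2) * cycle * (TWO_PI / w**2)
            J[:, 2] = A * g * d / sig**2
            J[:, 3] = A * g * d**2 / sig**3
            J[:, 4] = 1.0
            return J

        x5 = np.clip(
            np.array([x_best[0], x_best[1], p_best, x_best[2], x_best[3]]), lo5, hi5
        )
        try:
            sol5 = least_squares(
                resid5, x5, jac=jac5, bounds=(lo5, hi5), method="trf",
                xtol=config.xtol, ftol=config.ftol, gtol=config.xtol,
                max_nfev=200,
            )
            if sol5.success and 2.0 * sol5.cost < ssr_best:
                ssr_best = 2.0 * sol5.cost
                x_best = np.array([sol5.x[0], sol5.x[1], sol5.x[3], sol5.x[4]])
                p_best = float(sol5.x[2])
        except Exception:  # pragma: no cover
            pass

    params = ModelParameters(
        A=float(x_best[0]), gamma=0.0, omega=float(x_best[1]), phi=0.0,
        y=float(x_best[3]), p_tau=p_best, sigma=float(x_best[2]),
    )
    if params.p_tau >= params.period:
        params = params.replace(p_tau=params.p_tau % params.period)
    return FitResult.from_params(kind, params, series, converged=True)


def fit_model(series: TimeSeries, kind: WaveformKind | str, config: FitConfig | None = None) -> FitResult:
    """Fit one waveform family to one series, multi-starting deterministically.

    Returns the best converged local optimum over the start grid.  A flat
    (all-constant) series short-circuits to an exact zero-amplitude fit.
    If no start converges the constant-mean model is returned with
    ``converged=False``.

    Raises
    ------
    ValueError
        If the series has fewer observations than ``config.min_obs`` or
        than the model's parameter count plus one.
    """
    kind = WaveformKind(kind)
    config = config or FitConfig()
    n_min = max(config.min_obs, N_PARAMS[kind] + 1)
    if series.n_obs < n_min:
        raise ValueError(
            f"{series.feature_id}: {series.n_obs} observations < required minimum {n_min} "
            f"to fit the {kind.value} model"
        )
    if not np.all(np.isfinite(series.values)):
        raise ValueError(f"{series.feature_id}: non-finite values")
    if series.span < config.expected_period:
        warnings.warn(
            f"{series.feature_id}: time span {series.span:g} h is shorter than the "
            f"expected period {config.expected_period:g} h",
            stacklevel=2,
        )

    if np.ptp(series.values) == 0.0:
        return _constant_fit(series, kind, config, converged=True)

    if kind is WaveformKind.TRANSIENT:
        result = _fit_transient(series, config)
        if result.ssr <= 1e-20:
            result.perfect_fit = True
        return result

    resid, jac = _residual_and_jac(kind, series)
    starts, (lo, hi) = _oscillatory_starts_and_bounds(series, config)

    best_x: np.ndarray | None = None
    best_cost = math.inf
    for x0 in starts:
        x0c = np.clip(x0, lo, hi)
        try:
            sol = least_squares(
                resid, x0c, jac=jac, bounds=(lo, hi), method="trf",
                xtol=config.xtol, ftol=config.ftol, gtol=config.xtol,
                max_nfev=config.max_nfev,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failures
            logger.warning("%s/%s: start failed: %s", series.feature_id, kind.value, exc)
            continue
        if sol.success and sol.cost < best_cost:
            best_cost = sol.cost
            best_x = sol.x
            if best_cost < 1e-24:  # exact fit; later starts cannot improve
                break

    if best_x is None:
        return _constant_fit(series, kind, config, converged=False)

    params = _unpack(kind, best_x)
    result = FitResult.from_params(kind, params, series, converged=True)
    if result.ssr <= 1e-20:
        result.perfect_fit = True
    return result


def fit_all_models(series: TimeSeries, config: FitConfig | None = None) -> list[FitResult]:
    """Fit all four families; always returns four results in canonical order.

    A family whose fit raises is replaced by a non-converged constant-mean
    fallback so the remaining families are still fitted.
    """
    config = config or FitConfig()
    results: list[FitResult] = []
    for kind in KIND_ORDER:
        try:
            results.append(fit_model(series, kind, config))
        except ValueError:
            raise  # input-contract violations abort the feature, not silently
        except Exception as exc:  # pragma: no cover
            logger.warning("%s/%s: fit failed (%s); constant fallback", series.feature_id, kind.value, exc)
            results.append(_constant_fit(series, kind, config, converged=False))
    return results


def select_best(fits: list[FitResult]) -> FitResult:
    """Pick the fit with minimal SSR among converged fits.

    Ties break toward fewer parameters, then toward the fixed family order
    harmonic > square > cycloid > transient (simplest interpretation
    first).  With no converged fit, the first (constant-mean) result is
    returned for downstream flagging as non-rhythmic.
    """
    if not fits:
        raise ValueError("select_best requires at least one fit")
    converged = [f for f in fits if f.converged]
    if not converged:
        return fits[0]
    order = {k: i for i, k in enumerate(KIND_ORDER)}
    return min(converged, key=lambda f: (f.ssr, f.n_params, order[f.kind]))
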