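"""Waveform model evaluators.

Four bounded waveform families describe rhythmic abundance profiles:

``harmonic``
    The extended harmonic oscillator, a cosine under an exponential
    amplitude envelope: ``A * exp(g*t/2) * cos(w*t + phi) + y``.  The
    amplitude-change coefficient ``g`` (gamma) damps (g < 0) or forces
    (g > 0) the oscillation.

``square``
    Pseudo-square wave: carrier sinusoid plus a third-harmonic term of
    fixed relative weight 0.25, flattening crests and troughs toward a
    digital waveform.  Same envelope, applied to the whole two-component
    sum.

``cycloid``
    Fundamental plus second harmonic combined as
    ``-0.5 * (cos(2wt + 2phi) - 2 cos(wt + phi))``, producing asymmetric
    crest/trough shapes from a circadian plus ultradian pair.

``transient``
    Periodic impulse: within each cycle of length ``2*pi/w`` a gated
    Gaussian bump of height ``A`` and width ``sigma`` rises at phase
    offset ``p_tau`` hours from a stable baseline ``y``.  No gamma
    envelope; the onset gate is one-sided (baseline before the impulse
    centre within each cycle).

The component frequency ratios (3w for the square, 2w for the cycloid)
and the mixing coefficients (0.25; -0.5 and 2) are constants of the
model families, never fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "WaveformKind",
    "ModelParameters",
    "evaluate",
    "evaluate_harmonic",
    "evaluate_square",
    "evaluate_cycloid",
    "evaluate_transient",
    "N_PARAMS",
    "PARAM_NAMES",
]

TWO_PI = 2.0 * math.pi


class WaveformKind(str, Enum):
    """The four admissible waveform families, in canonical order."""

    HARMONIC = "harmonic"
    SQUARE = "square"
    CYCLOID = "cycloid"
    TRANSIENT = "transient"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Free parameters per family (all families fit five).
PARAM_NAMES: dict[WaveformKind, tuple[str, ...]] = {
    WaveformKind.HARMONIC: ("A", "gamma", "omega", "phi", "y"),
    WaveformKind.SQUARE: ("A", "gamma", "omega", "phi", "y"),
    WaveformKind.CYCLOID: ("A", "gamma", "omega", "phi", "y"),
    WaveformKind.TRANSIENT: ("A", "omega", "p_tau", "sigma", "y"),
}

N_PARAMS: dict[WaveformKind, int] = {k: len(v) for k, v in PARAM_NAMES.items()}


@dataclass(frozen=True)
class ModelParameters:
    """Parameter set shared by all waveform families.

    Attributes
    ----------
    A : float
        Initial amplitude (t = 0), signal units.  Non-negative; the sign
        of the oscillation is absorbed into the phase.
    gamma : float
        Amplitude-change coefficient, per hour.  Negative values damp the
        oscillation, positive values force it.  Unused by the transient
        family.
    omega : float
        Angular frequency, radians per hour (period = 2*pi/omega).
    phi : float
        Phase shift, radians.  Unused by the transient family.
    y : float
        Equilibrium (baseline) value, signal units.
    p_tau : float
        Impulse offset within one cycle, hours (transient only).
    sigma : float
        Impulse width, hours (transient only).
    """

    A: float
    gamma: float = 0.0
    omega: float = TWO_PI / 24.0
    phi: float = 0.0
    y: float = 0.0
    p_tau: float = 0.0
    sigma: float = 1.0

    @property
    def period(self) -> float:
        """Oscillation period in hours (2*pi/omega)."""
        return TWO_PI / self.omega

    def validate(self, kind: WaveformKind | None = None) -> None:
        """Reject non-finite or out-of-domain parameters.

        Raises
        ------
        ValueError
            Naming the offending symbol.
        """
        for name in ("A", "gamma", "omega", "phi", "y", "p_tau", "sigma"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name!r} is not finite: {v!r}")
        if self.omega <= 0:
            raise ValueError(f"parameter 'omega' must be positive, got {self.omega}")
        if self.A < 0:
            raise ValueError(f"parameter 'A' must be non-negative, got {self.A}")
        if kind is WaveformKind.TRANSIENT:
            if self.sigma <= 0:
                raise ValueError(f"parameter 'sigma' must be positive, got {self.sigma}")
            if not (0.0 <= self.p_tau < self.period):
                raise ValueError(
                    f"parameter 'p_tau' must lie in [0, period={self.period:g}), got {self.p_tau}"
                )

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


def _envelope(p: ModelParameters, t: np.ndarray) -> np.ndarray:
    return np.exp(p.gamma * t / 2.0)


def evaluate_harmonic(params: ModelParameters, t) -> np.ndarray:
    """Extended harmonic oscillator: A*exp(g*t/2)*cos(w*t+phi) + y."""
    params.validate()
    t = np.asarray(t, dtype=float)
    return params.A * _envelope(params, t) * np.cos(params.omega * t + params.phi) + params.y


def evaluate_square(params: ModelParameters, t) -> np.ndarray:
    """Pseudo-square wave: carrier sine plus 0.25-weighted third harmonic.

    The exponential envelope multiplies the full two-component sum so that
    gamma modulates overall amplitude uniformly.
    """
    params.validate()
    t = np.asarray(t, dtype=float)
    arg = params.omega * t + params.phi
    shape = np.sin(arg) + 0.25 * np.sin(3.0 * arg)
    return params.A * _envelope(params, t) * shape + params.y


def evaluate_cycloid(params: ModelParameters, t) -> np.ndarray:
    """Pseudo-cycloid wave: -0.5*(cos(2wt+2phi) - 2*cos(wt+phi)) under the envelope."""
    params.validate()
    t = np.asarray(t, dtype=float)
    arg = params.omega * t + params.phi
    shape = -0.5 * (np.cos(2.0 * arg) - 2.0 * np.cos(arg))
    return params.A * _envelope(params, t) * shape + params.y


def evaluate_transient(params: ModelParameters, t) -> np.ndarray:
    """Periodic gated Gaussian impulse.

    With u = t mod (2*pi/omega): returns ``A*exp(-((u - p_tau)/sigma)**2 / 2) + y``
    where ``u - p_tau >= 0``, and the baseline ``y`` otherwise.
    """
    params.validate(WaveformKind.TRANSIENT)
    t = np.asarray(t, dtype=float)
    u = np.mod(t, params.period)
    d = u - params.p_tau
    bump = params.A * np.exp(-0.5 * (d / params.sigma) ** 2)
    return np.where(d >= 0.0, bump, 0.0) + params.y


_EVALUATORS = {
    WaveformKind.HARMONIC: evaluate_harmonic,
    WaveformKind.SQUARE: evaluate_square,
    WaveformKind.CYCLOID: evaluate_cycloid,
    WaveformKind.TRANSIENT: evaluate_transient,
}


def evaluate(kind: WaveformKind | str, params: ModelParameters, t) -> np.ndarray:
    """Evaluate waveform family `kind` at times `t` (hours)."""
    kind = WaveformKind(kind)
    return _EVALUATORS[kind](params, t)
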