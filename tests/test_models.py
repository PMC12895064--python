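"""Waveform evaluators against direct-arithmetic oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmfit.models import (
    ModelParameters,
    WaveformKind,
    evaluate,
    evaluate_cycloid,
    evaluate_harmonic,
    evaluate_square,
    evaluate_transient,
)

W24 = math.pi / 12.0  # omega for a 24-h period


# --- independent scalar transcriptions of the model equations -----------

def oracle(kind: str, p: ModelParameters, t: float) -> float:
    env = math.exp(p.gamma * t / 2.0)
    if kind == "harmonic":
        return p.A * env * math.cos(p.omega * t + p.phi) + p.y
    if kind == "square":
        a = p.omega * t + p.phi
        return p.A * env * (math.sin(a) + 0.25 * math.sin(3 * a)) + p.y
    if kind == "cycloid":
        a = p.omega * t + p.phi
        return p.A * env * (-0.5) * (math.cos(2 * a) - 2 * math.cos(a)) + p.y
    if kind == "transient":
        period = 2 * math.pi / p.omega
        u = math.fmod(t, period)
        if u < 0:
            u += period
        d = u - p.p_tau
        if d >= 0:
            return p.A * math.exp(-0.5 * (d / p.sigma) ** 2) + p.y
        return p.y
    raise AssertionError(kind)


def random_params(kind: str, rng: np.random.Generator) -> ModelParameters:
    period = rng.uniform(18.0, 30.0)
    omega = 2 * math.pi / period
    return ModelParameters(
        A=rng.uniform(0.0, 3.0),
        gamma=rng.uniform(-0.05, 0.05) if kind != "transient" else 0.0,
        omega=omega,
        phi=rng.uniform(0.0, 2 * math.pi),
        y=rng.uniform(-2.0, 2.0),
        p_tau=rng.uniform(0.0, period * 0.999),
        sigma=rng.uniform(0.5, 3.0),
    )


CASES = [
    # (kind, params, t, expected)
    ("harmonic", dict(A=1, gamma=0, omega=W24, phi=0, y=0), 0.0, 1.0),
    ("harmonic", dict(A=1, gamma=0, omega=W24, phi=0, y=0), 6.0, 0.0),
    ("harmonic", dict(A=2, gamma=0.1, omega=W24, phi=0, y=0.5), 12.0,
     2 * math.exp(0.6) * math.cos(math.pi) + 0.5),  # ~ -3.1442376
    ("square", dict(A=1, gamma=0, omega=W24, phi=0, y=0), 0.0, 0.0),
    ("square", dict(A=0, gamma=0.3, omega=W24, phi=1.1, y=3.2), 17.0, 3.2),
    ("square", dict(A=1, gamma=0, omega=W24, phi=0, y=0), 6.0, 0.75),
    ("cycloid", dict(A=1, gamma=0, omega=W24, phi=0, y=0), 0.0, 0.5),
    ("cycloid", dict(A=1, gamma=0, omega=W24, phi=0, y=0), 12.0, -1.5),
    ("cycloid", dict(A=0, gamma=0, omega=W24, phi=0, y=-1), 7.3, -1.0),
    ("transient", dict(A=2, omega=W24, y=1, p_tau=6, sigma=1), 6.0, 3.0),
    ("transient", dict(A=2, omega=W24, y=1, p_tau=6, sigma=1), 5.0, 1.0),
    ("transient", dict(A=2, omega=W24, y=1, p_tau=6, sigma=1), 8.0,
     2 * math.exp(-2.0) + 1.0),  # ~ 1.2706706
    ("transient", dict(A=2, omega=W24, y=1, p_tau=6, sigma=1), 30.0, 3.0),
]


@pytest.mark.parametrize("kind,pkw,t,expected", CASES)
def test_evaluator_worked_examples(kind, pkw, t, expected):
    p = ModelParameters(**pkw)
    assert evaluate(kind, p, t) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("kind", ["harmonic", "square", "cycloid", "transient"])
def test_oracle_equivalence_random_draws(kind):
    """Each evaluator matches an independent scalar transcription of its equation."""
    rng = np.random.default_rng(20240601)
    for _ in range(100):
        p = random_params(kind, rng)
        t = float(rng.uniform(0.0, 72.0))
        assert evaluate(kind, p, t) == pytest.approx(oracle(kind, p, t), abs=1e-9)


@pytest.mark.parametrize("kind", ["harmonic", "square", "cycloid", "transient"])
def test_periodicity_at_gamma_zero(kind):
    """With gamma = 0 every family repeats after one period 2*pi/omega."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        p = random_params(kind, rng).replace(gamma=0.0)
        t = float(rng.uniform(0.0, 48.0))
        a, b = evaluate(kind, p, t), evaluate(kind, p, t + p.period)
        assert a == pytest.approx(b, abs=1e-9)


@pytest.mark.parametrize("kind", ["harmonic", "square", "cycloid", "transient"])
def test_zero_amplitude_collapses_to_baseline(kind):
    rng = np.random.default_rng(11)
    for _ in range(50):
        p = random_params(kind, rng).replace(A=0.0)
        t = rng.uniform(0.0, 72.0, size=16)
        assert np.all(evaluate(kind, p, t) == p.y)


@pytest.mark.parametrize("kind", ["harmonic", "square", "cycloid"])
def test_envelope_factorizes(kind):
    """x(t; gamma) - y == exp(gamma*t/2) * (x(t; 0) - y) for oscillatory families."""
    rng = np.random.default_rng(13)
    for _ in range(50):
        p = random_params(kind, rng)
        t = rng.uniform(0.0, 48.0, size=8)
        with_env = evaluate(kind, p, t) - p.y
        flat = evaluate(kind, p.replace(gamma=0.0), t) - p.y
        assert np.allclose(with_env, np.exp(p.gamma * t / 2.0) * flat, atol=1e-9)


@settings(derandomize=True, max_examples=200)
@given(
    kind=st.sampled_from(["harmonic", "square", "cycloid", "transient"]),
    y=st.floats(-3.0, 3.0),
    period=st.floats(12.0, 36.0),
    t=st.floats(0.0, 96.0),
)
def test_zero_amplitude_collapse_property(kind, y, period, t):
    """For every family and any time, A=0 forces x(t) == y exactly."""
    p = ModelParameters(A=0.0, gamma=0.01, omega=2 * math.pi / period, phi=1.0,
                        y=y, p_tau=period / 3, sigma=1.5)
    assert float(evaluate(kind, p, t)) == y


def test_pseudo_square_is_flatter_than_sine():
    """The third-harmonic term lowers the crest factor versus a pure sinusoid."""
    p = ModelParameters(A=1.0, gamma=0.0, omega=W24, phi=0.0, y=0.0)
    t = np.linspace(0.0, 24.0, 4096, endpoint=False)
    sq = evaluate_square(p, t)
    sine = np.sin(p.omega * t)
    crest = lambda x: np.max(np.abs(x)) / np.sqrt(np.mean(x**2))
    assert crest(sq) < crest(sine)


@pytest.mark.parametrize(
    "pkw,symbol",
    [
        (dict(A=float("nan")), "A"),
        (dict(A=1.0, omega=-0.1), "omega"),
        (dict(A=1.0, y=float("inf")), "y"),
        (dict(A=-0.5), "A"),
    ],
)
def test_invalid_parameters_rejected_with_symbol(pkw, symbol):
    p = ModelParameters(**{"A": 1.0, **pkw})
    with pytest.raises(ValueError, match=symbol):
        evaluate_harmonic(p, 0.0)


def test_transient_rejects_bad_sigma_and_p_tau():
    with pytest.raises(ValueError, match="sigma"):
        evaluate_transient(ModelParameters(A=1, omega=W24, sigma=0.0), 1.0)
    with pytest.raises(ValueError, match="p_tau"):
        evaluate_transient(ModelParameters(A=1, omega=W24, p_tau=25.0, sigma=1.0), 1.0)
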