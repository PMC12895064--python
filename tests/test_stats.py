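"""Rhythm statistics: F-test arithmetic, Kendall and BH oracles, regulation."""

import itertools
import math

import numpy as np
import pytest
from scipy import special

import rhythmfit as rf
from rhythmfit.fitting import FitResult
from rhythmfit.models import ModelParameters, WaveformKind
from rhythmfit.stats import Regulation


def make_f_inputs(n, ssr0, ssr1, y=0.0, n_params=5):
    """Series and FitResult with prescribed null/model SSR around baseline y."""
    # values with sum((v - y)^2) == ssr0
    v = np.full(n, y)
    v[0] += math.sqrt(ssr0)
    series = rf.TimeSeries("f", np.arange(float(n)), v)
    fit = FitResult(
        kind=WaveformKind.HARMONIC,
        params=ModelParameters(A=1.0, y=y),
        ssr=ssr1, rmse=math.sqrt(ssr1 / n), fitted=np.zeros(n),
        converged=True, n_obs=n, n_params=n_params,
    )
    return series, fit


def f_sf_oracle(f, d1, d2):
    """Independent F-distribution tail via the regularized incomplete beta."""
    x = d1 * f / (d1 * f + d2)
    return 1.0 - special.betainc(d1 / 2.0, d2 / 2.0, x)


def test_f_test_worked_example():
    """n=8, p=5, SSR0=10, SSR1=2 -> F = ((10-2)/4) / (2/3) = 3 exactly."""
    series, fit = make_f_inputs(8, ssr0=10.0, ssr1=2.0)
    f_stat, f_p = rf.zero_amplitude_f_test(series, fit)
    assert f_stat == pytest.approx(3.0, abs=1e-12)
    assert f_p == pytest.approx(f_sf_oracle(3.0, 4, 3), abs=1e-9)


def test_f_test_no_improvement_and_perfect_fit():
    series, fit = make_f_inputs(8, ssr0=4.0, ssr1=4.0)  # no amplitude improvement
    assert rf.zero_amplitude_f_test(series, fit) == (0.0, 1.0)

    series, fit = make_f_inputs(8, ssr0=1.0, ssr1=5.0)  # worse than null: clamp
    assert rf.zero_amplitude_f_test(series, fit) == (0.0, 1.0)

    series, fit = make_f_inputs(8, ssr0=16.0, ssr1=0.0)  # noiseless perfect fit
    f_stat, f_p = rf.zero_amplitude_f_test(series, fit)
    assert f_p == 0.0


def test_f_stat_monotone_in_model_ssr():
    """Increasing SSR1 at fixed SSR0 never increases the F statistic."""
    prev = math.inf
    for ssr1 in np.linspace(0.5, 9.5, 19):
        series, fit = make_f_inputs(12, ssr0=10.0, ssr1=float(ssr1))
        f_stat, _ = rf.zero_amplitude_f_test(series, fit)
        assert f_stat <= prev + 1e-12
        prev = f_stat


def test_f_test_requires_error_degrees_of_freedom():
    series, fit = make_f_inputs(5, ssr0=10.0, ssr1=2.0)
    with pytest.raises(ValueError, match="n_obs"):
        rf.zero_amplitude_f_test(series, fit)


# --- Kendall tau ----------------------------------------------------------

def tau_b_oracle(x, y):
    """Brute-force pair enumeration with tie correction (tau-b)."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom


def test_kendall_worked_examples():
    tau, _ = rf.kendall_agreement([1, 2, 3], [10, 20, 30])
    assert tau == pytest.approx(1.0)
    tau, _ = rf.kendall_agreement([1, 2, 3], [3, 2, 1])
    assert tau == pytest.approx(-1.0)
    tau, _ = rf.kendall_agreement([1, 2, 3, 4], [1, 3, 2, 4])
    assert tau == pytest.approx(4.0 / 6.0)


def test_kendall_matches_brute_force_pair_counting():
    rng = np.random.default_rng(99)
    for _ in range(200):
        n = int(rng.integers(3, 13))
        x = rng.integers(0, 6, size=n).astype(float)
        y = rng.integers(0, 6, size=n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        tau, _ = rf.kendall_agreement(x, y)
        assert tau == pytest.approx(tau_b_oracle(x, y), abs=1e-12)


def test_kendall_degenerate_inputs_flagged():
    tau, p = rf.kendall_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert (tau, p) == (0.0, 1.0)
    with pytest.raises(ValueError):
        rf.kendall_agreement([1.0, 2.0], [1.0, 2.0])


# --- Benjamini-Hochberg ---------------------------------------------------

def bh_oracle(p):
    """Hand-coded step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return np.minimum(adj, 1.0)


def test_bh_worked_examples():
    assert rf.bh_adjust([0.04]) == pytest.approx([0.04])
    assert rf.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert rf.bh_adjust([0.005, 0.5]) == pytest.approx([0.01, 0.5])


def test_bh_matches_step_up_oracle_and_properties():
    rng = np.random.default_rng(4)
    for _ in range(100):
        m = int(rng.integers(1, 40))
        p = rng.uniform(0, 1, size=m)
        q = rf.bh_adjust(p)
        assert q == pytest.approx(bh_oracle(p), abs=1e-12)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
        # invariant under permutation-then-unpermutation
        perm = rng.permutation(m)
        assert rf.bh_adjust(p[perm])[np.argsort(perm)] == pytest.approx(q, abs=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        rf.bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        rf.bh_adjust([-0.1])


# --- regulation classification --------------------------------------------

@pytest.mark.parametrize(
    "kind,gamma,expected",
    [
        ("harmonic", 0.005, Regulation.STABLE),
        ("harmonic", -0.05, Regulation.DAMPED),
        ("square", 0.05, Regulation.FORCED),
        ("cycloid", -0.009, Regulation.STABLE),
        ("transient", -0.5, Regulation.NOT_APPLICABLE),
        ("transient", 0.0, Regulation.NOT_APPLICABLE),
    ],
)
def test_classify_regulation(kind, gamma, expected):
    p = ModelParameters(A=1.0, gamma=gamma, sigma=1.0)
    assert rf.classify_regulation(p, kind, threshold=0.01) == expected


def test_classify_regulation_requires_positive_threshold():
    with pytest.raises(ValueError):
        rf.classify_regulation(ModelParameters(A=1.0), "harmonic", threshold=0.0)
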