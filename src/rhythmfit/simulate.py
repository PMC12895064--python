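"""Seeded generator of ground-truth labelled synthetic omics time courses.

Panels emulate a dense circadian design: a 24 h rhythm sampled every 2 h
over 48 h with two replicates, i.i.d. Gaussian observation noise, and a
mixture of the four waveform classes plus flat null features.  Every
panel is a deterministic function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import TimeSeries
from .io import Dataset
from .models import TWO_PI, ModelParameters, WaveformKind, evaluate

__all__ = ["SimulationSpec", "simulate_feature", "simulate_panel", "write_panel", "NULL_KIND"]

#: Label for flat (non-rhythmic) features in panel specs and truth tables.
NULL_KIND = "null"

DEFAULT_KINDS = ("harmonic", "square", "cycloid", "transient", NULL_KIND)

DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "A": (1.0, 3.0),
    "phi": (0.0, TWO_PI),
    "y": (-1.0, 1.0),
    "p_tau_frac": (0.0, 1.0),  # fraction of the period
    "sigma": (1.0, 3.0),
}

#: Amplitude-change regimes sampled with equal probability: damped / stable / forced.
DEFAULT_GAMMA_CHOICES = (-0.05, 0.0, 0.05)


@dataclass
class SimulationSpec:
    """Design of a synthetic panel.

    Attributes
    ----------
    n_per_class : int
        Features generated per waveform class (and per null).
    kinds : tuple of str
        Subset of the four waveform labels plus "null".
    period, span, interval : float
        Rhythm period, total sampling span, and sampling interval (hours).
    replicates : int
        Replicate observations per timepoint.
    noise_sd : float
        Gaussian observation noise, signal units.  May also be given as a
        fraction of each feature's amplitude via ``noise_rel``.
    noise_rel : float | None
        If set, per-feature noise sd = noise_rel * A (overrides noise_sd
        for rhythmic features; null features use noise_sd).
    param_ranges : dict
        Uniform low/high per symbol; gamma is drawn from ``gamma_choices``.
    seed : int
        Fixes the panel bit-for-bit.
    """

    n_per_class: int = 25
    kinds: tuple[str, ...] = DEFAULT_KINDS
    period: float = 24.0
    span: float = 48.0
    interval: float = 2.0
    replicates: int = 2
    noise_sd: float = 0.1
    noise_rel: float | None = None
    param_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_RANGES)
    )
    gamma_choices: tuple[float, ...] = DEFAULT_GAMMA_CHOICES
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.kinds:
            raise ValueError("kinds must be non-empty")
        for k in self.kinds:
            if k != NULL_KIND:
                WaveformKind(k)  # raises on unknown label
        if self.span < self.period:
            raise ValueError("span must cover at least one period")
        if self.interval <= 0 or self.noise_sd < 0 or self.replicates < 1:
            raise ValueError("invalid sampling design")

    @property
    def timepoints(self) -> np.ndarray:
        return np.arange(0.0, self.span, self.interval)

    def observation_times(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-resolved (times, replicate labels)."""
        tp = self.timepoints
        times = np.repeat(tp, self.replicates)
        reps = np.tile([f"r{i + 1}" for i in range(self.replicates)], tp.size)
        return times, reps


def simulate_feature(
    kind: str,
    params: ModelParameters,
    spec: SimulationSpec,
    rng: np.random.Generator,
    feature_id: str = "feature",
    noise_sd: float | None = None,
) -> tuple[TimeSeries, dict]:
    """Generate one noisy feature and its ground-truth record.

    ``kind="null"`` produces baseline-plus-noise only.
    """
    times, reps = spec.observation_times()
    if kind == NULL_KIND:
        clean = np.full(times.shape, params.y)
    else:
        clean = evaluate(WaveformKind(kind), params, times)
    sd = spec.noise_sd if noise_sd is None else noise_sd
    values = clean + rng.normal(0.0, sd, size=times.shape) if sd > 0 else clean.copy()
    truth = {
        "feature_id": feature_id,
        "kind": kind,
        "A": params.A if kind != NULL_KIND else 0.0,
        "gamma": params.gamma,
        "omega": params.omega,
        "phi": params.phi,
        "y": params.y,
        "p_tau": params.p_tau,
        "sigma": params.sigma,
        "noise_sd": sd,
    }
    return TimeSeries(feature_id, times, values, reps), truth


def _draw_params(kind: str, spec: SimulationSpec, rng: np.random.Generator) -> ModelParameters:
    r = spec.param_ranges
    u = lambda key: float(rng.uniform(*r[key]))
    omega = TWO_PI / spec.period
    if kind == NULL_KIND:
        return ModelParameters(A=0.0, omega=omega, y=u("y"))
    A = u("A")
    phi = u("phi")
    y = u("y")
    gamma = float(rng.choice(spec.gamma_choices))
    p_tau = float(rng.uniform(*r["p_tau_frac"])) * spec.period
    sigma = u("sigma")
    if kind == WaveformKind.TRANSIENT.value:
        return ModelParameters(A=A, gamma=0.0, omega=omega, phi=0.0, y=y, p_tau=p_tau, sigma=sigma)
    return ModelParameters(A=A, gamma=gamma, omega=omega, phi=phi, y=y)


def simulate_panel(spec: SimulationSpec) -> tuple[Dataset, pd.DataFrame]:
    """Generate n_per_class features per kind; returns (Dataset, truth table)."""
    rng = np.random.default_rng(spec.seed)
    features: list[TimeSeries] = []
    truths: list[dict] = []
    for kind in spec.kinds:
        for i in range(spec.n_per_class):
            fid = f"{kind}_{i + 1:03d}"
            params = _draw_params(kind, spec, rng)
            sd = spec.noise_sd
            if spec.noise_rel is not None and kind != NULL_KIND:
                sd = spec.noise_rel * params.A
            series, truth = simulate_feature(kind, params, spec, rng, feature_id=fid, noise_sd=sd)
            features.append(series)
            truths.append(truth)
    truth_df = pd.DataFrame(truths)
    return Dataset(features, source="synthetic"), truth_df


def write_panel(dataset: Dataset, path, truth: pd.DataFrame | None = None, truth_path=None) -> None:
    """Write a panel in the wide-CSV layout that ``read_table`` accepts.

    Column headers are ``ZT<t>_r<k>``; all features must share one
    sampling design (true of any generated panel).
    """
    first = dataset.features[0]
    times, reps = first.times, first.replicates

    def hdr(t: float, r: str) -> str:
        ts = f"{t:g}"
        return f"ZT{ts}_{r}"

    cols = [hdr(t, r) for t, r in zip(times, reps)]
    rows = {}
    for s in dataset:
        if s.times.shape != times.shape or not np.allclose(s.times, times):
            raise ValueError("all features must share the sampling design to write wide")
        rows[s.feature_id] = s.values
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "feature"
    df.to_csv(path, float_format="%.17g")  # exact float round trip
    if truth is not None and truth_path is not None:
        truth.to_csv(truth_path, index=False)
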