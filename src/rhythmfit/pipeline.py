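"""Batch orchestration: read -> (normalize) -> fit -> select -> test -> adjust -> classify.

`run_analysis` is the single library entry point mirrored by the CLI.
Features are independent work units fitted deterministically; the two
Benjamini-Hochberg families (F-test and Kendall tau) are computed across
the whole batch after all fits, so adjusted values depend on the batch
composition but not on feature order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .fitting import FitConfig, TimeSeries, fit_all_models, select_best
from .io import Dataset, zscore_normalize
from .models import N_PARAMS
from .stats import (
    RhythmCall,
    bh_adjust,
    classify_regulation,
    kendall_agreement,
    zero_amplitude_f_test,
)

__all__ = ["RunConfig", "run_analysis", "analyze_feature"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """End-to-end analysis options.

    alpha is the BH-adjusted significance level applied to both the
    F-test and the Kendall-tau families; a feature is rhythmic only if
    both adjusted p-values fall below it.
    """

    expected_period: float = 24.0
    period_tolerance: float = 0.25
    alpha: float = 0.05
    gamma_threshold: float = 0.01
    normalize: bool = True
    min_obs: int = 6
    fit: FitConfig = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.fit is None:
            self.fit = FitConfig(
                expected_period=self.expected_period,
                period_tolerance=self.period_tolerance,
                min_obs=self.min_obs,
            )


def analyze_feature(series: TimeSeries, config: RunConfig) -> RhythmCall:
    """Fit all four models to one feature and compute its raw statistics.

    BH adjustment and the rhythmic flag are batch-level decisions made in
    `run_analysis`; on a single feature the returned call carries raw
    p-values only.
    """
    if config.normalize:
        series = zscore_normalize(series)
    fits = fit_all_models(series, config.fit)
    best = select_best(fits)
    f_stat, f_p = zero_amplitude_f_test(series, best)
    tau, tau_p = kendall_agreement(series.values, best.fitted)
    call = RhythmCall(
        feature_id=series.feature_id,
        best=best,
        f_stat=f_stat,
        f_p=f_p,
        tau=tau,
        tau_p=tau_p,
        regulation=classify_regulation(best.params, best.kind, config.gamma_threshold),
        perfect_fit=best.perfect_fit,
    )
    return call


def run_analysis(dataset: Dataset, config: RunConfig | None = None) -> list[RhythmCall]:
    """Analyse every feature in a dataset; returns one RhythmCall per
    analysable feature, in input order.

    Features with too few observations (or other per-feature input
    defects) are skipped with a logged warning, never aborting the batch.

    Raises
    ------
    ValueError
        If no feature is analysable.
    """
    config = config or RunConfig()
    min_needed = max(config.min_obs, max(N_PARAMS.values()) + 1)
    calls: list[RhythmCall] = []
    skipped: list[tuple[str, str]] = []
    for series in dataset:
        if series.n_obs < min_needed:
            skipped.append((series.feature_id, f"{series.n_obs} obs < {min_needed}"))
            continue
        try:
            calls.append(analyze_feature(series, config))
        except ValueError as exc:
            skipped.append((series.feature_id, str(exc)))
    for fid, why in skipped:
        logger.warning("skipped %s: %s", fid, why)
    if not calls:
        raise ValueError(
            "no analysable features; skip reasons: "
            + "; ".join(f"{fid}: {why}" for fid, why in skipped[:10])
        )

    f_q = bh_adjust([c.f_p for c in calls])
    tau_q = bh_adjust([c.tau_p for c in calls])
    for c, fq, tq in zip(calls, f_q, tau_q):
        c.f_q = float(fq)
        c.tau_q = float(tq)
        c.rhythmic = bool(fq < config.alpha and tq < config.alpha)
    return calls
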