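"""Reading feature-by-time tables and writing per-feature results.

Two tabular layouts are accepted:

* **wide** — rows are molecules; the first column is the feature id and
  every remaining column name encodes a timepoint (hours) and optionally
  a replicate, e.g. ``ZT0_r1``, ``CT12_2``, ``24.5_r3`` or a bare ``36``.
* **long** — columns ``feature``, ``time``, ``replicate``, ``value``.

Time columns accept a ``ZT`` or ``CT`` prefix (zeitgeber / circadian
time, hours since lights-on) or bare numerics.  Unrecognised headers are
an error, never a silent guess.  Missing cells are dropped per feature
with a logged count; nothing is imputed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import TimeSeries
from .models import TWO_PI, WaveformKind
from .stats import RhythmCall

__all__ = [
    "Dataset",
    "read_table",
    "zscore_normalize",
    "write_results",
    "write_fitted",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

# "ZT12_r2", "CT0-1", "24.5_2", "36"
_TIME_COL_RE = re.compile(
    r"^(?:ZT|CT)?\s*([0-9]+(?:\.[0-9]+)?)(?:[_\-]r?([0-9]+))?$", re.IGNORECASE
)

RESULT_COLUMNS = [
    "feature_id", "best_model", "A", "gamma", "omega", "period_hours", "phi", "y",
    "p_tau", "sigma", "rmse", "regulation", "f_stat", "f_p", "f_q",
    "tau", "tau_p", "tau_q", "rhythmic",
]


@dataclass
class Dataset:
    """Ordered collection of TimeSeries keyed by feature identifier."""

    features: list[TimeSeries]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        ids = [s.feature_id for s in self.features]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, feature_id: str) -> TimeSeries:
        for s in self.features:
            if s.feature_id == feature_id:
                return s
        raise KeyError(feature_id)

    @property
    def feature_ids(self) -> list[str]:
        return [s.feature_id for s in self.features]


def parse_time_column(name: str) -> tuple[float, str]:
    """Parse a wide-layout column header into (time_hours, replicate label)."""
    m = _TIME_COL_RE.match(str(name).strip())
    if not m:
        raise ValueError(
            f"cannot parse time from column name {name!r}; expected e.g. "
            "'ZT0_r1', 'CT12', '24.5_2' or a bare number"
        )
    t = float(m.group(1))
    rep = f"r{m.group(2)}" if m.group(2) else "r1"
    return t, rep


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_table(
    path: str | Path,
    layout: str = "wide",
    delimiter: str | None = None,
) -> Dataset:
    """Read a feature-by-time abundance table into a Dataset.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file; the delimiter is inferred from the extension unless
        given explicitly.
    layout : {"wide", "long"}
        See module docstring for the two schemas.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if layout == "wide":
        return _from_wide(df, source=str(path))
    if layout == "long":
        return _from_long(df, source=str(path))
    raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")


def _from_wide(df: pd.DataFrame, source: str) -> Dataset:
    if df.shape[1] < 2:
        raise ValueError("wide table needs a feature-id column plus time columns")
    id_col = df.columns[0]
    parsed = [parse_time_column(c) for c in df.columns[1:]]
    times = np.array([t for t, _ in parsed])
    reps = np.array([r for _, r in parsed])
    features: list[TimeSeries] = []
    for _, row in df.iterrows():
        fid = str(row[id_col])
        vals = pd.to_numeric(row.iloc[1:], errors="coerce").to_numpy(dtype=float)
        keep = np.isfinite(vals)
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("%s: dropped %d missing cell(s)", fid, dropped)
        features.append(TimeSeries(fid, times[keep], vals[keep], reps[keep]))
    return Dataset(features, source=source)


def _from_long(df: pd.DataFrame, source: str) -> Dataset:
    cols = {c.lower(): c for c in df.columns}
    required = ["feature", "time", "value"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"long table missing column(s): {missing}")
    rep_col = cols.get("replicate")
    features: list[TimeSeries] = []
    for fid, grp in df.groupby(cols["feature"], sort=False):
        vals = pd.to_numeric(grp[cols["value"]], errors="coerce").to_numpy(dtype=float)
        times = pd.to_numeric(grp[cols["time"]], errors="coerce").to_numpy(dtype=float)
        reps = (
            grp[rep_col].astype(str).to_numpy()
            if rep_col
            else np.asarray(["r1"] * len(grp))
        )
        keep = np.isfinite(vals) & np.isfinite(times)
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("%s: dropped %d missing row(s)", fid, dropped)
        features.append(TimeSeries(str(fid), times[keep], vals[keep], reps[keep]))
    return Dataset(features, source=source)


def zscore_normalize(series: TimeSeries) -> TimeSeries:
    """Z-score a feature's values (mean 0, sd 1); times unchanged.

    Zero-variance input is returned unchanged with ``normalized_flag``
    left False — the downstream zero-amplitude fit absorbs constants.
    """
    sd = float(np.std(series.values))
    if sd == 0.0:
        return series
    z = (series.values - float(np.mean(series.values))) / sd
    return TimeSeries(
        series.feature_id, series.times.copy(), z, series.replicates.copy(), normalized_flag=True
    )


def _fmt(x: float) -> str:
    if isinstance(x, bool):
        return str(x)
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.6g}"


def calls_to_frame(calls: list[RhythmCall]) -> pd.DataFrame:
    """Flatten RhythmCalls into the results table (one row per feature)."""
    rows = []
    for c in calls:
        p = c.best.params
        transient = c.best.kind is WaveformKind.TRANSIENT
        rows.append({
            "feature_id": c.feature_id,
            "best_model": c.best.kind.value,
            "A": p.A,
            "gamma": math.nan if transient else p.gamma,
            "omega": p.omega,
            "period_hours": TWO_PI / p.omega,
            "phi": math.nan if transient else p.phi,
            "y": p.y,
            "p_tau": p.p_tau if transient else math.nan,
            "sigma": p.sigma if transient else math.nan,
            "rmse": c.best.rmse,
            "regulation": c.regulation.value,
            "f_stat": c.f_stat,
            "f_p": c.f_p,
            "f_q": c.f_q,
            "tau": c.tau,
            "tau_p": c.tau_p,
            "tau_q": c.tau_q,
            "rhythmic": bool(c.rhythmic),
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(calls: list[RhythmCall], path: str | Path) -> None:
    """Write the per-feature results CSV (deterministic column order)."""
    if not calls:
        raise ValueError("no calls to write")
    df = calls_to_frame(calls)
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_fmt)
    out.to_csv(path, index=False)


def write_fitted(calls: list[RhythmCall], dataset: Dataset, path: str | Path) -> None:
    """Companion CSV of modelled values: feature_id, time, fitted."""
    rows = []
    by_id = {s.feature_id: s for s in dataset}
    for c in calls:
        s = by_id[c.feature_id]
        for t, f in zip(s.times, c.best.fitted):
            rows.append({"feature_id": c.feature_id, "time": t, "fitted": f})
    pd.DataFrame(rows, columns=["feature_id", "time", "fitted"]).to_csv(path, index=False)
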