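"""Pulse detection and dynamic featurization of single-cell ERK activity traces.

Each trace is reduced to nine dynamic features: mean and maximum activity,
summed and average pulse duration, summed and average pulse height, average
absolute derivative, average inter-pulse interval, and the power-weighted
mean frequency of the trace's periodogram.  Pulses are interior local maxima
with a minimum topographic prominence; pulse duration is the width at half
prominence.

Per-timepoint stain-activity correlation profiles relate each endpoint stain
to the activity at every timepoint across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

FEATURE_NAMES = [
    "mean",
    "max",
    "sum_duration",
    "avg_duration",
    "sum_peak_height",
    "avg_peak_height",
    "avg_derivative",
    "avg_interpulse_interval",
    "frequency",
]


@dataclass
class PeakSet:
    """Detected pulses of one trace (indices strictly increasing)."""

    peak_index: np.ndarray     # sample indices of local maxima
    height: np.ndarray         # activity at peak
    prominence: np.ndarray     # topographic prominence
    width_min: np.ndarray      # width at half prominence, minutes
    interval_min: np.ndarray   # successive peak-to-peak times, minutes

    @property
    def n_peaks(self) -> int:
        return int(self.peak_index.size)


def _check_uniform(t_min: np.ndarray) -> float:
    dt = np.diff(t_min)
    if dt.size == 0:
        raise ValueError("trace must have >= 2 samples")
    if dt[0] <= 0 or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
        raise ValueError("trace sampling must be uniform with positive interval")
    return float(dt[0])


def qc_filter(
    traces: np.ndarray,
    t_min: np.ndarray,
    min_hours: float = 15.0,
    activity_bounds: tuple[float, float] = (-0.5, 50.0),
) -> np.ndarray:
    """Quality-control mask over cells (rows of ``traces``).

    Drops cells with fewer than ``min_hours`` of finite data or any activity
    outside the plausibility bounds.  Returns a boolean keep-mask.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.size == 0:
        raise ValueError("empty trace table")
    dt = _check_uniform(np.asarray(t_min, dtype=float))
    finite = np.isfinite(traces)
    hours = finite.sum(axis=1) * dt / 60.0
    all_finite = finite.all(axis=1)
    lo, hi = activity_bounds
    with np.errstate(invalid="ignore"):
        in_bounds = np.where(finite, (traces >= lo) & (traces <= hi), True).all(axis=1)
    return (hours >= min_hours) & all_finite & in_bounds


def detect_peaks(activity: np.ndarray, t_min: np.ndarray, min_prominence: float) -> PeakSet:
    """Interior local maxima with prominence >= ``min_prominence``.

    Widths are measured at half prominence with linear interpolation of the
    crossing points, reported in minutes.
    """
    x = np.asarray(activity, dtype=float)
    t = np.asarray(t_min, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 samples to detect interior maxima")
    dt = _check_uniform(t)
    idx, props = signal.find_peaks(x, prominence=min_prominence)
    widths, _, _, _ = signal.peak_widths(
        x, idx, rel_height=0.5,
        prominence_data=(props["prominences"], props["left_bases"], props["right_bases"]),
    )
    return PeakSet(
        peak_index=idx,
        height=x[idx],
        prominence=props["prominences"],
        width_min=widths * dt,
        interval_min=np.diff(t[idx]),
    )


def default_prominence(traces: np.ndarray, fraction: float = 0.10) -> float:
    """Default pulse-detection threshold: a fraction of the dataset activity IQR."""
    finite = np.asarray(traces, dtype=float)
    finite = finite[np.isfinite(finite)]
    q75, q25 = np.percentile(finite, [75, 25])
    return float(fraction * (q75 - q25))


def frequency_cph(activity: np.ndarray, dt_min: float) -> float:
    """Power-weighted mean frequency (cycles/hour) of the mean-subtracted trace.

    One-sided periodogram with a Hann taper (suppresses the leakage bias a
    rectangular window puts on non-integer cycle counts); a constant trace
    has zero spectrum and returns 0.
    """
    x = np.asarray(activity, dtype=float)
    x = x - x.mean()
    # rounding residue of the mean subtraction must not register as signal
    scale = max(1.0, float(np.abs(activity).max()))
    if x.var() <= (np.finfo(float).eps * scale) ** 2 * 1e4:
        return 0.0
    freqs, pxx = signal.periodogram(x, fs=1.0 / dt_min, window="hann", detrend=False)
    total = pxx.sum()
    if total <= 0:
        return 0.0
    return float((freqs * pxx).sum() / total * 60.0)


def featurize(activity: np.ndarray, t_min: np.ndarray, peaks: PeakSet) -> dict:
    """The nine dynamic features of one trace.

    ``avg_interpulse_interval`` is imputed as the observation-window length
    when fewer than two pulses exist; the ``interval_imputed`` flag records
    this so downstream users can filter.
    """
    x = np.asarray(activity, dtype=float)
    t = np.asarray(t_min, dtype=float)
    if x.size == 0:
        raise ValueError("zero-length trace")
    dt = _check_uniform(t)
    window = t[-1] - t[0]
    n = peaks.n_peaks
    feats = {
        "mean": float(x.mean()),
        "max": float(x.max()),
        "sum_duration": float(peaks.width_min.sum()),
        "avg_duration": float(peaks.width_min.sum() / n) if n else 0.0,
        "sum_peak_height": float(peaks.height.sum()),
        "avg_peak_height": float(peaks.height.sum() / n) if n else 0.0,
        "avg_derivative": float(np.abs(np.diff(x)).mean() / dt),
        "avg_interpulse_interval": float(peaks.interval_min.mean()) if n >= 2 else float(window),
        "frequency": frequency_cph(x, dt),
        "interval_imputed": n < 2,
        "n_peaks": n,
    }
    return feats


def featurize_table(
    traces: np.ndarray,
    t_min: np.ndarray,
    min_prominence: float | None = None,
    cell_ids=None,
) -> pd.DataFrame:
    """Feature table (cells x 9 features + flags) for a trace matrix."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if min_prominence is None:
        min_prominence = default_prominence(traces)
    rows = []
    for row in traces:
        peaks = detect_peaks(row, t_min, min_prominence)
        rows.append(featurize(row, t_min, peaks))
    df = pd.DataFrame(rows)
    if cell_ids is not None:
        df.index = pd.Index(cell_ids, name="cell_id")
    return df


def timepoint_correlation(panel: pd.DataFrame, traces: np.ndarray) -> pd.DataFrame:
    """Pearson r between each stain and the activity at each timepoint.

    Rows are stain targets, columns timepoint indices; computed across
    cells (rows aligned between ``panel`` and ``traces``).  Timepoints or
    targets with zero variance yield NaN, not 0.
    """
    X = np.asarray(traces, dtype=float)
    Y = panel.to_numpy(dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("panel and traces must describe the same cells")
    if X.shape[0] < 3:
        raise ValueError("need >= 3 cells for correlation")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((Yc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc.T @ Xc) / np.outer(sy, sx)
    r[:, sx == 0] = np.nan
    r[sy == 0, :] = np.nan
    return pd.DataFrame(r, index=panel.columns, columns=np.arange(X.shape[1]))
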