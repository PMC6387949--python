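"""RR-interval cleaning and LF/HF spectral power of heart-rate variability.

The inter-beat-interval (IBI) series is cleaned with physiological bounds
(HR above 200 or below 40 bpm, i.e. intervals outside [300, 1500] ms) and
an ectopic-beat rule (deviation > 20% from the running median of 11
neighbors), cubic-spline interpolated against beat time, resampled to a
uniform 4 Hz signal, and decomposed with a Hann-windowed periodogram into
LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz) band powers in ms^2.

LF power mixes sympathetic and parasympathetic cardiac influences; HF
power indexes parasympathetic (vagal) activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "RrSeries",
    "HrvPowers",
    "clean_rr",
    "resample_rr",
    "band_power",
    "hrv_by_condition",
]

LF_BAND: tuple[float, float] = (0.04, 0.15)
HF_BAND: tuple[float, float] = (0.15, 0.40)

#: Interval bounds mapped from the HR limits: 60000/200 and 60000/40 ms.
MIN_IBI_MS = 300.0
MAX_IBI_MS = 1500.0


@dataclass
class RrSeries:
    """Cleaned inter-beat intervals with cumulative beat times.

    ``beat_times`` are in seconds, one per interval (time of the beat that
    closes the interval).
    """

    intervals_ms: np.ndarray
    beat_times_s: np.ndarray
    condition: str | None = None
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.intervals_ms.shape != self.beat_times_s.shape:
            raise ValueError("intervals and beat times must align")
        if np.any(self.intervals_ms <= 0):
            raise ValueError("intervals must be positive")
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def span_s(self) -> float:
        if len(self.beat_times_s) < 2:
            return 0.0
        return float(self.beat_times_s[-1] - self.beat_times_s[0])


@dataclass
class HrvPowers:
    """LF and HF band powers (ms^2)."""

    lf: float
    hf: float

    @property
    def ratio(self) -> float:
        return self.lf / self.hf if self.hf > 0 else np.inf


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def clean_rr(
    raw_intervals_ms: np.ndarray,
    condition: str | None = None,
    ectopic_frac: float = 0.20,
    ectopic_window: int = 11,
    max_removed_frac: float = 0.50,
) -> RrSeries:
    """Apply physiological-bound and ectopic-beat cleaning rules.

    Removal passes repeat until a fixed point so cleaning is idempotent.
    Removed beats are dropped outright (downstream interpolation bridges
    the gap); every removal is logged in the exclusion table.
    """
    raw = np.asarray(raw_intervals_ms, dtype=float)
    if raw.size == 0:
        raise ValueError("empty RR series")
    times = np.cumsum(raw) / 1000.0
    keep_idx = np.arange(raw.size)
    vals = raw.copy()
    reasons: list[tuple[int, float, str]] = []
    while True:
        bad = (vals < MIN_IBI_MS) | (vals > MAX_IBI_MS)
        reason = np.where(vals < MIN_IBI_MS, "hr_above_200",
                          np.where(vals > MAX_IBI_MS, "hr_below_40", ""))
        if not bad.any():
            med = _running_median(vals, ectopic_window)
            ect = np.abs(vals - med) > ectopic_frac * med
            bad |= ect
            reason = np.where(ect, "ectopic", reason)
        if not bad.any():
            break
        for k in np.flatnonzero(bad):
            reasons.append((int(keep_idx[k]), float(vals[k]), str(reason[k])))
        vals = vals[~bad]
        keep_idx = keep_idx[~bad]
        if vals.size == 0:
            break
    n_removed = raw.size - vals.size
    if n_removed > max_removed_frac * raw.size:
        raise ValueError(
            f"unusable RR series: {n_removed}/{raw.size} intervals removed"
        )
    exclusions = pd.DataFrame(reasons, columns=["index", "interval_ms", "reason"])
    if n_removed:
        logger.info("clean_rr: removed %d of %d intervals", n_removed, raw.size)
    return RrSeries(
        intervals_ms=vals,
        beat_times_s=times[keep_idx],
        condition=condition,
        exclusions=exclusions,
    )


def resample_rr(series: RrSeries, rate: float = 4.0) -> tuple[np.ndarray, float]:
    """Cubic-spline interpolation of IBI against beat time at a uniform rate.

    Returns (signal in ms, rate). Output length is floor(span * rate) + 1.
    """
    if len(series.intervals_ms) < 4:
        raise ValueError("need at least 4 beats to interpolate")
    spline = CubicSpline(series.beat_times_s, series.intervals_ms)
    n = int(np.floor(series.span_s * rate)) + 1
    t = series.beat_times_s[0] + np.arange(n) / rate
    return spline(t), rate


def band_power(
    ibi_signal_ms: np.ndarray,
    fs: float = 4.0,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
) -> HrvPowers:
    """Hann-windowed periodogram power integrated over the LF and HF bands.

    The signal is mean-removed; periodogram density scaling is
    window-compensated so that the integral over all frequencies matches
    the signal's variance contribution (Parseval-consistent). Powers are
    in ms^2.
    """
    x = np.asarray(ibi_signal_ms, dtype=float)
    if x.size < fs / lf_band[0]:
        raise ValueError(
            "signal too short to resolve the LF band lower edge "
            f"(need >= {1 / lf_band[0]:.0f} s)"
        )
    freqs, pxx = signal.periodogram(
        x, fs=fs, window="hann", detrend="constant", scaling="density"
    )
    df = freqs[1] - freqs[0]
    lf = float(pxx[(freqs >= lf_band[0]) & (freqs <= lf_band[1])].sum() * df)
    hf = float(pxx[(freqs >= hf_band[0]) & (freqs <= hf_band[1])].sum() * df)
    return HrvPowers(lf=lf, hf=hf)


def hrv_by_condition(
    series_by_condition: dict[str, RrSeries | None],
    rate: float = 4.0,
    conditions: tuple[str, ...] = ("low", "high"),
) -> pd.DataFrame:
    """LF/HF per condition as a 2 (band) x 2 (condition) table.

    A missing or unusable condition yields NaN entries with a logged
    warning, never a silent zero.
    """
    table = pd.DataFrame(
        np.nan, index=["LF", "HF"], columns=list(conditions), dtype=float
    )
    for cond in conditions:
        series = series_by_condition.get(cond)
        if series is None:
            logger.warning("hrv_by_condition: condition %r missing", cond)
            continue
        try:
            sig, fs = resample_rr(series, rate)
            powers = band_power(sig, fs)
        except ValueError as exc:
            logger.warning("hrv_by_condition: condition %r unusable (%s)", cond, exc)
            continue
        table.loc["LF", cond] = powers.lf
        table.loc["HF", cond] = powers.hf
    return table
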