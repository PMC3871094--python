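"""Chronobiological analysis of the count time series.

The counting pipeline yields one fish count every 30 min over ~18 days, with
gaps where frames were discarded.  Rhythmicity is assessed with the
chi-square periodogram (Sokolove & Bushell): the series is folded at every
candidate period, and the variance of the column means, scaled by the series
length, follows a chi-square law with (columns - 1) degrees of freedom under
the no-rhythm null.  The mean 24-h profile (waveform) summarizes the diel
pattern: its mean level (MESOR) defines activity onset and offset, and the
share of activity inside the daytime window measures how day-active the
community is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountSeries",
    "PeriodogramResult",
    "WaveformResult",
    "chi_square_periodogram",
    "waveform",
    "turbidity_diagnostic",
]


@dataclass
class CountSeries:
    """An evenly spaced series of non-negative values with missing slots.

    ``values`` holds NaN where the slot's frame was discarded; the slot grid
    itself is always complete (one slot per acquisition time).
    """

    start: datetime
    interval_min: float
    values: np.ndarray
    label: str = "automated"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        with np.errstate(invalid="ignore"):
            if np.any(v < 0):
                raise ValueError("counts must be non-negative")
        self.values = v

    @property
    def n_slots(self) -> int:
        return self.values.size

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def timestamps(self) -> list[datetime]:
        step = timedelta(minutes=self.interval_min)
        return [self.start + i * step for i in range(self.n_slots)]

    def to_csv(self, path) -> None:
        """CSV ``timestamp_iso8601,value``; empty value marks a missing slot."""
        with open(path, "w") as fh:
            fh.write("timestamp_iso8601,value\n")
            for ts, v in zip(self.timestamps(), self.values):
                fh.write(f"{ts.isoformat()},{'' if np.isnan(v) else repr(float(v))}\n")

    @classmethod
    def from_csv(cls, path, label: str = "automated") -> "CountSeries":
        df = pd.read_csv(path, parse_dates=["timestamp_iso8601"])
        ts = df["timestamp_iso8601"]
        if len(ts) < 2:
            raise ValueError("series needs at least 2 slots")
        steps = ts.diff().dropna().dt.total_seconds() / 60.0
        if steps.nunique() != 1:
            raise ValueError("timestamps are not evenly spaced")
        return cls(
            start=ts.iloc[0].to_pydatetime(),
            interval_min=float(steps.iloc[0]),
            values=df["value"].to_numpy(dtype=float),
            label=label,
        )


@dataclass
class PeriodogramResult:
    periods_min: np.ndarray
    q: np.ndarray
    sig_line: np.ndarray            # raw p < alpha chi-square quantile per period
    sig_line_bonferroni: np.ndarray
    alpha: float
    n_points: int
    peak_period_min: float | None
    percent_variance: float | None  # 100 * Q / N at the peak

    def significant(self, corrected: bool = False) -> np.ndarray:
        line = self.sig_line_bonferroni if corrected else self.sig_line
        return self.q > line

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "period_min": self.periods_min,
            "Q": self.q,
            "sig_line": self.sig_line,
            "significant": self.significant(),
        })


@dataclass
class WaveformResult:
    bin_start_minutes: np.ndarray   # clock minutes from midnight for each bin
    bin_means: np.ndarray
    mesor: float
    onset: time | None
    offset: time | None
    daytime_activity_percent: float | None
    night_window: tuple[time, time]
    offset_convention: str = "last_above"

    def to_dict(self) -> dict:
        return {
            "bin_start_minutes": self.bin_start_minutes.tolist(),
            "bin_means": [None if np.isnan(v) else float(v) for v in self.bin_means],
            "mesor": float(self.mesor),
            "onset": None if self.onset is None else self.onset.isoformat(),
            "offset": None if self.offset is None else self.offset.isoformat(),
            "daytime_activity_percent": self.daytime_activity_percent,
            "night_window": [t.isoformat() for t in self.night_window],
            "offset_convention": self.offset_convention,
        }


def chi_square_periodogram(
    series: CountSeries,
    p_min: float = 660.0,
    p_max: float = 1500.0,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Sokolove-Bushell chi-square periodogram over an inclusive period range.

    Candidate periods are integer multiples of the sampling interval (folding
    is only defined on whole slots).  For a candidate of K slots the series is
    folded modulo K; with column means M_h over non-missing entries, grand
    mean M and N non-missing points,

        Q_P = N * (sum_h (M_h - M)^2 / K) / (sum_i (x_i - M)^2 / N),

    which under the null is asymptotically chi-square with K - 1 degrees of
    freedom.  The raw significance line is the (1 - alpha) quantile; a
    Bonferroni line across the tested periods is also reported.  The peak is
    the significant period with the largest Q.
    """
    x = series.values
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("too few non-missing points")
    if ok.mean() < 0.5:
        raise ValueError("more than 50% of slots are missing")
    k_min = int(np.ceil(p_min / series.interval_min))
    k_max = int(np.floor(p_max / series.interval_min))
    if k_min > k_max:
        raise ValueError("empty period range at this sampling interval")
    if series.n_slots < 2 * k_max:
        raise ValueError("series shorter than 2 cycles of the longest tested period")

    grand = x[ok].mean()
    total_ss = float(((x[ok] - grand) ** 2).sum())
    if total_ss == 0:
        raise ValueError("zero-variance series")
    idx = np.arange(series.n_slots)

    ks = np.arange(k_min, k_max + 1)
    q = np.empty(ks.size)
    for i, k in enumerate(ks):
        cols = idx % k
        col_sum = np.bincount(cols[ok], weights=x[ok], minlength=k)
        col_n = np.bincount(cols[ok], minlength=k)
        have = col_n > 0
        col_means = col_sum[have] / col_n[have]
        between = float(((col_means - grand) ** 2).sum()) / have.sum()
        q[i] = n * between / (total_ss / n)

    n_tests = ks.size
    sig = stats.chi2.ppf(1 - alpha, df=ks - 1)
    sig_bonf = stats.chi2.ppf(1 - alpha / n_tests, df=ks - 1)
    periods = ks * series.interval_min

    significant = q > sig
    if significant.any():
        peak_idx = int(np.argmax(np.where(significant, q, -np.inf)))
        peak = float(periods[peak_idx])
        pct = float(100.0 * q[peak_idx] / n)
    else:
        peak, pct = None, None
    return PeriodogramResult(
        periods_min=periods,
        q=q,
        sig_line=sig,
        sig_line_bonferroni=sig_bonf,
        alpha=alpha,
        n_points=n,
        peak_period_min=peak,
        percent_variance=pct,
    )


def _clock_minutes(t: time) -> float:
    return t.hour * 60 + t.minute + t.second / 60.0


def _in_window(minutes: np.ndarray, start: time, end: time) -> np.ndarray:
    s, e = _clock_minutes(start), _clock_minutes(end)
    if s <= e:
        return (minutes >= s) & (minutes < e)
    return (minutes >= s) | (minutes < e)  # window wraps midnight


def waveform(
    series: CountSeries,
    period_min: float = 1440.0,
    night_window: tuple[time, time] = (time(20, 0), time(8, 0)),
    offset_convention: str = "last_above",
) -> WaveformResult:
    """Mean 24-h profile with MESOR, activity onset/offset and daytime share.

    The series is folded on the standard day; each clock bin's mean ignores
    missing slots.  MESOR is the mean of the bin means.  Scanning from
    midnight, onset is the first bin whose mean exceeds MESOR and offset is
    the last bin of that contiguous above-MESOR phase (convention
    ``last_above``; ``first_below`` reports the following bin instead).
    The daytime activity percentage is the sum of bin means inside the
    daytime window (the complement of ``night_window``) over the sum of all
    bin means.
    """
    n_bins = int(round(period_min / series.interval_min))
    if n_bins < 2:
        raise ValueError("waveform needs at least 2 bins per day")
    if series.n_slots < 2 * n_bins:
        raise ValueError("waveform needs at least 2 complete days")
    if offset_convention not in ("last_above", "first_below"):
        raise ValueError(f"unknown offset convention {offset_convention!r}")

    start_min = series.start.hour * 60 + series.start.minute
    slot_clock = (start_min + np.arange(series.n_slots) * series.interval_min) % period_min
    bins = np.round(slot_clock / series.interval_min).astype(int) % n_bins
    x = series.values
    ok = ~np.isnan(x)
    sums = np.bincount(bins[ok], weights=x[ok], minlength=n_bins)
    counts = np.bincount(bins[ok], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    mesor = float(np.nanmean(means))
    above = means > mesor  # NaN compares False
    if not above.any() or above.all():
        onset = offset = None
    else:
        onset_bin = int(np.argmax(above))
        # walk the contiguous above phase (wrapping past midnight)
        end_bin = onset_bin
        while above[(end_bin + 1) % n_bins] and (end_bin + 1) % n_bins != onset_bin:
            end_bin = (end_bin + 1) % n_bins
        if offset_convention == "first_below":
            end_bin = (end_bin + 1) % n_bins
        onset = _bin_time(onset_bin, series.interval_min)
        offset = _bin_time(end_bin, series.interval_min)

    bin_minutes = np.arange(n_bins) * series.interval_min
    night = _in_window(bin_minutes, *night_window)
    total = np.nansum(means)
    if total > 0:
        day_pct = float(100.0 * np.nansum(means[~night]) / total)
    else:
        day_pct = None
    return WaveformResult(
        bin_start_minutes=bin_minutes,
        bin_means=means,
        mesor=mesor,
        onset=onset,
        offset=offset,
        daytime_activity_percent=day_pct,
        night_window=night_window,
        offset_convention=offset_convention,
    )


def _bin_time(bin_idx: int, interval_min: float) -> time:
    minutes = bin_idx * interval_min
    return time(int(minutes // 60) % 24, int(minutes % 60))


def turbidity_diagnostic(
    green_means: CountSeries,
    selected_mask: np.ndarray,
    night_window: tuple[time, time] = (time(20, 0), time(8, 0)),
) -> tuple[WaveformResult, np.ndarray]:
    """Green-channel turbidity proxy against the discard pattern.

    ``green_means`` is the per-slot mean G value (0-255, uncalibrated) of the
    green chart patch; ``selected_mask`` flags the slots whose frames survived
    screening.  Returns the 24-h waveform of G plus, per clock bin, the total
    number of discarded frames across the run.  Turbid daytime episodes show
    up as G dips coinciding with discard peaks.
    """
    selected_mask = np.asarray(selected_mask, dtype=bool)
    if selected_mask.size != green_means.n_slots:
        raise ValueError("selected mask length must match the series")
    wf = waveform(green_means, night_window=night_window)
    n_bins = wf.bin_means.size
    start_min = green_means.start.hour * 60 + green_means.start.minute
    slot_clock = (start_min + np.arange(green_means.n_slots) * green_means.interval_min) % 1440.0
    bins = np.round(slot_clock / green_means.interval_min).astype(int) % n_bins
    discarded = np.bincount(bins[~selected_mask], minlength=n_bins)
    return wf, discarded
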