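"""Accelerometer processing: from 15-s epoch counts to habitual MVPA.

Rules implemented:

* non-wear: maximal runs of ≥ 30 min (120 epochs) of consecutive zero
  counts, evaluated within each calendar day, are excluded;
* MVPA: an epoch is moderate-to-vigorous if its count, scaled to counts
  per minute, is at or above the Evenson cut-off of 2298 cpm — for 15-s
  epochs that is ≥ 575 counts (2298/4 = 574.5, ceiled since counts are
  integers);
* a day is valid with ≥ 8 h of weartime after non-wear exclusion;
* a child is included with ≥ 3 consecutive valid calendar days containing
  at least one weekend day; habitual MVPA is the mean over ALL valid days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EpochSeries

__all__ = ["DaySummary", "HabitualMVPA", "detect_nonwear", "summarize_day",
           "summarize_days", "habitual_mvpa", "process_series",
           "EVENSON_CPM", "epoch_count_threshold"]

EVENSON_CPM = 2298
NONWEAR_MIN_EPOCHS = 120   # 30 min of 15-s epochs
VALID_DAY_HOURS = 8.0


def epoch_count_threshold(cutoff_cpm: int = EVENSON_CPM,
                          epoch_s: int = 15) -> int:
    """Smallest integer epoch count at or above the cpm cut-off."""
    per_min = 60 // epoch_s
    return int(np.ceil(cutoff_cpm / per_min))


@dataclass
class DaySummary:
    date: object
    weartime_h: float
    mvpa_min: float
    is_weekend: bool
    is_valid: bool


@dataclass
class HabitualMVPA:
    child_id: str
    mvpa_min_per_day: float
    mean_valid_weartime_h: float
    n_valid_days: int
    included: bool


def _zero_runs_mask(counts: np.ndarray, min_run: int) -> np.ndarray:
    """True for epochs in maximal zero runs of length >= min_run."""
    z = counts == 0
    if not z.any():
        return np.zeros(len(counts), dtype=bool)
    # run-length encode the zero indicator
    edges = np.flatnonzero(np.diff(np.concatenate(([0], z.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    mask = np.zeros(len(counts), dtype=bool)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            mask[s:e] = True
    return mask


def detect_nonwear(series: EpochSeries,
                   min_run_epochs: int = NONWEAR_MIN_EPOCHS) -> np.ndarray:
    """Boolean non-wear mask per epoch; runs are evaluated within each day
    and never merged across a non-zero epoch."""
    counts = np.asarray(series.counts)
    if len(counts) == 0:
        return np.zeros(0, dtype=bool)
    dates = series.timestamps.normalize()
    mask = np.zeros(len(counts), dtype=bool)
    for _, idx in pd.Series(np.arange(len(counts)), index=dates).groupby(level=0):
        ii = idx.to_numpy()
        mask[ii] = _zero_runs_mask(counts[ii], min_run_epochs)
    return mask


def summarize_day(series: EpochSeries, day, epoch_s: int = 15,
                  cutoff_cpm: int = EVENSON_CPM,
                  reintegrate_60s: bool = False,
                  nonwear_mask: np.ndarray | None = None) -> DaySummary:
    """Weartime, MVPA minutes, and validity for one calendar day."""
    day = pd.Timestamp(day).normalize()
    if nonwear_mask is None:
        nonwear_mask = detect_nonwear(series)
    sel = np.asarray(series.timestamps.normalize() == day, dtype=bool)
    counts = np.asarray(series.counts)[sel]
    worn = ~nonwear_mask[sel]
    weartime_h = worn.sum() * epoch_s / 3600.0
    if reintegrate_60s:
        # sum counts over 60-s blocks, classify blocks against the cpm cut-off
        per_min = 60 // epoch_s
        nblk = len(counts) // per_min
        blk = counts[:nblk * per_min].reshape(nblk, per_min)
        blk_worn = worn[:nblk * per_min].reshape(nblk, per_min).all(axis=1)
        mvpa_min = float(((blk.sum(axis=1) >= cutoff_cpm) & blk_worn).sum())
    else:
        thr = epoch_count_threshold(cutoff_cpm, epoch_s)
        mvpa_epochs = int(((counts >= thr) & worn).sum())
        mvpa_min = mvpa_epochs * epoch_s / 60.0
    return DaySummary(date=day.date(), weartime_h=float(weartime_h),
                      mvpa_min=mvpa_min, is_weekend=day.dayofweek >= 5,
                      is_valid=weartime_h >= VALID_DAY_HOURS)


def summarize_days(series: EpochSeries, **kwargs) -> pd.DataFrame:
    """Per-day summaries for every calendar day in the series."""
    mask = detect_nonwear(series)
    days = sorted(set(series.timestamps.normalize()))
    rows = [summarize_day(series, d, nonwear_mask=mask, **kwargs).__dict__
            for d in days]
    return pd.DataFrame(rows)


def habitual_mvpa(day_summaries: pd.DataFrame, child_id: str = "",
                  window_only: bool = False) -> HabitualMVPA:
    """Habitual MVPA and the inclusion decision from day summaries.

    Included iff some run of ≥ 3 consecutive valid calendar days contains a
    weekend day. The average is over all valid days (set ``window_only`` to
    average only over days inside qualifying runs).
    """
    df = day_summaries.sort_values("date").reset_index(drop=True)
    valid = df[df["is_valid"]]
    included = False
    qualifying_dates: set = set()
    if len(valid):
        dates = pd.to_datetime(valid["date"]).dt.normalize().to_numpy()
        wk = valid["is_weekend"].to_numpy()
        run_start = 0
        for i in range(1, len(dates) + 1):
            is_break = (i == len(dates)
                        or (dates[i] - dates[i - 1]) != np.timedelta64(1, "D"))
            if is_break:
                run = slice(run_start, i)
                if (i - run_start) >= 3 and wk[run].any():
                    included = True
                    qualifying_dates.update(pd.Timestamp(d).date()
                                            for d in dates[run])
                run_start = i
    pool = valid
    if window_only and qualifying_dates:
        pool = valid[valid["date"].isin(qualifying_dates)]
    if len(pool):
        mvpa = float(pool["mvpa_min"].mean())
        wear = float(pool["weartime_h"].mean())
    else:
        mvpa, wear = float("nan"), float("nan")
    return HabitualMVPA(child_id=child_id, mvpa_min_per_day=mvpa,
                        mean_valid_weartime_h=wear,
                        n_valid_days=int(len(valid)), included=included)


def process_series(series: EpochSeries, **kwargs) -> tuple[pd.DataFrame, HabitualMVPA]:
    """Convenience wrapper: day summaries plus the habitual-MVPA outcome."""
    days = summarize_days(series, **kwargs)
    return days, habitual_mvpa(days, child_id=series.child_id)
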