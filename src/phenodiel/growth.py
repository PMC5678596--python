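"""Relative expansion rates from projected-rosette-area time series.

The relative expansion rate (RER) is the per-day log-area slope

    RER = (ln PRA_2 - ln PRA_1) / (t_2 - t_1)        [day^-1]

Two summaries are computed per plant:

* **daily RER** — one value per light period, from the PRA at the first and
  last VIS frame of that period;
* **diel RER** — a high-resolution series over the full 24-h cycle: the PRA
  series is first smoothed with a centred sliding median (default 10 frames,
  about 3 h at 20-min sampling, which suppresses segmentation spikes before
  the noise-amplifying difference step), then differenced between consecutive
  smoothed points.

RER is invariant to the PRA unit (px vs mm²) and to time shifts, being a
log-derivative.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import DielSession, Period

__all__ = [
    "PRASeries",
    "RERSeries",
    "rer",
    "daily_rer",
    "daily_rer_block_means",
    "diel_rer",
    "sliding_median",
    "detect_dawn_dips",
    "DEFAULT_WINDOW_FRAMES",
]

DEFAULT_WINDOW_FRAMES = 10


@dataclass
class PRASeries:
    """One plant's PRA trajectory: times in days (relative to ``origin``)."""

    plant_id: int
    times: np.ndarray        # days, strictly increasing
    values: np.ndarray       # PRA, px or mm2 (consistent within a series)
    missing: np.ndarray | None = None
    frame_index: np.ndarray | None = None
    origin: dt.datetime | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.missing is None:
            self.missing = np.zeros(self.times.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (self.values[~self.missing] < 0).any():
            raise ValueError("PRA values must be >= 0")

    @classmethod
    def from_traits(cls, traits: pd.DataFrame, plant_id: int) -> "PRASeries":
        """Build from a trait table (columns per session.TRAIT_COLUMNS)."""
        sub = traits[traits["plant_id"] == plant_id].sort_values("timestamp")
        if sub.empty:
            raise ValueError(f"no records for plant {plant_id}")
        stamps = pd.to_datetime(sub["timestamp"])
        origin = stamps.iloc[0].to_pydatetime()
        days = (stamps - stamps.iloc[0]).dt.total_seconds().to_numpy() / 86400.0
        return cls(
            plant_id=plant_id,
            times=days,
            values=sub["pra_px"].to_numpy(float),
            missing=sub["missing"].to_numpy(bool),
            frame_index=sub["frame_index"].to_numpy(int),
            origin=origin,
        )


@dataclass
class RERSeries:
    plant_id: int
    times: np.ndarray
    rer_values: np.ndarray
    window_frames: int = 1

    def __post_init__(self) -> None:
        if self.window_frames < 1:
            raise ValueError("window_frames must be >= 1")
        if not np.isfinite(self.rer_values).all():
            raise ValueError("RER values must be finite")


def rer(pra1: float, pra2: float, t1: float, t2: float) -> float:
    """Log-area slope between two observations, in day^-1 for times in days."""
    if pra1 <= 0 or pra2 <= 0:
        raise ValueError("log of non-positive PRA")
    if t1 == t2:
        raise ValueError("t1 and t2 must differ")
    return (math.log(pra2) - math.log(pra1)) / (t2 - t1)


def daily_rer(
    series: PRASeries, session: DielSession
) -> list[tuple[int, float]]:
    """One RER per light period, from the period's first and last VIS frames.

    Returns (period_index, rer) pairs; periods with a missing endpoint or
    fewer than two usable frames are skipped with a warning, as are
    incomplete periods (first-to-last frame span under half the scheduled
    photoperiod, e.g. a session ending mid-morning).  Raises if no light
    period yields a value.
    """
    if series.frame_index is None:
        raise ValueError("series lacks frame indices; build it from a trait table")
    min_span_days = 0.5 * session.schedule.light_hours / 24.0
    out = []
    for period in session.light_periods():
        sel = (
            (series.frame_index >= period.start)
            & (series.frame_index < period.stop)
            & ~series.missing
        )
        idx = np.nonzero(sel)[0]
        if idx.size < 2:
            warnings.warn(
                f"light period {period.index}: endpoint missing, skipped"
            )
            continue
        i, j = idx[0], idx[-1]
        if series.times[j] - series.times[i] < min_span_days:
            warnings.warn(
                f"light period {period.index}: incomplete "
                f"({(series.times[j] - series.times[i]) * 24:.1f} h), skipped"
            )
            continue
        out.append(
            (period.index, rer(series.values[i], series.values[j],
                               series.times[i], series.times[j]))
        )
    if not out:
        raise ValueError("no complete light period in series")
    return out


def daily_rer_block_means(
    daily: list[tuple[int, float]], block_days: int = 3
) -> list[float]:
    """Arithmetic means of consecutive daily RER values in blocks (e.g. 3-day)."""
    vals = [v for _, v in daily]
    return [
        float(np.mean(vals[i : i + block_days]))
        for i in range(0, len(vals), block_days)
    ]


def sliding_median(values: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centred sliding median; returns (kept-sample indices, medians).

    Edge samples whose window is incomplete are excluded.  For an even window
    the centre index is ``start + window // 2``.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if window < 1 or n < window:
        raise ValueError("series shorter than the median window")
    win = np.lib.stride_tricks.sliding_window_view(values, window)
    med = np.median(win, axis=1)
    centres = np.arange(n - window + 1) + window // 2
    return centres, med


def _fill_short_gaps(series: PRASeries, max_gap: int = 2):
    """Linearly interpolate missing runs of <= max_gap frames; longer runs
    split the series into independently-processed segments."""
    t, v, miss = series.times, series.values.copy(), series.missing
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    good = np.nonzero(~miss)[0]
    if good.size == 0:
        return segments
    # split where a missing run longer than max_gap separates good samples
    breaks = np.nonzero(np.diff(good) > max_gap + 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks + 1, [good.size]])
    for a, b in zip(starts, stops):
        idx = np.arange(good[a], good[b - 1] + 1)
        vv = v[idx].copy()
        mm = miss[idx]
        if mm.any():
            vv[mm] = np.interp(t[idx][mm], t[idx][~mm], vv[~mm])
        segments.append((t[idx], vv))
    return segments


def diel_rer(
    series: PRASeries, window_frames: int = DEFAULT_WINDOW_FRAMES
) -> RERSeries:
    """High-resolution RER series: sliding-median-smoothed PRA, differenced.

    The smoothed PRA is differenced between consecutive kept samples; each
    rate is reported at the midpoint of its pair.  Edge frames with an
    incomplete window are excluded.  Missing frames are interpolated when the
    gap is at most 2 frames, otherwise the series is split and each segment
    processed separately.
    """
    segments = _fill_short_gaps(series)
    times_out: list[np.ndarray] = []
    rer_out: list[np.ndarray] = []
    for t, v in segments:
        if t.size < window_frames + 1:
            continue
        centres, med = sliding_median(v, window_frames)
        tc = t[centres]
        if (med <= 0).any():
            raise ValueError("log of non-positive PRA in smoothed series")
        r = np.diff(np.log(med)) / np.diff(tc)
        times_out.append((tc[1:] + tc[:-1]) / 2.0)
        rer_out.append(r)
    if not rer_out:
        raise ValueError("series shorter than the median window")
    return RERSeries(
        plant_id=series.plant_id,
        times=np.concatenate(times_out),
        rer_values=np.concatenate(rer_out),
        window_frames=window_frames,
    )


def detect_dawn_dips(
    series: PRASeries,
    session: DielSession,
    window_hours: float = 2.0,
    smooth_frames: int = 5,
    min_depth: float = 0.02,
) -> list[dict]:
    """Test each dawn (dark→light transition) for a transient PRA dip.

    Leaf movement at the start of the light period transiently reduces the
    projected area.  For each light period preceded by a dark period, the
    median-smoothed PRA inside ``[dawn, dawn + window_hours]`` is compared to
    the straight line joining the window's endpoints; the dip depth is the
    largest relative shortfall below that baseline at an interior sample.  A
    dawn counts as dipped when depth >= ``min_depth``.

    Returns one dict per dawn: period_index, dawn_time_days, depth, dipped.
    """
    if series.frame_index is None:
        raise ValueError("series lacks frame indices; build it from a trait table")
    segments = _fill_short_gaps(series)
    if not segments:
        return []
    t_all = np.concatenate([t for t, _ in segments])
    v_all = np.concatenate([v for _, v in segments])
    if t_all.size >= smooth_frames:
        centres, med = sliding_median(v_all, smooth_frames)
        ts, vs = t_all[centres], med
    else:
        ts, vs = t_all, v_all

    results = []
    origin = series.origin or session.frames[0].timestamp
    for k, period in enumerate(session.periods):
        if period.kind != "light" or k == 0 or session.periods[k - 1].kind != "dark":
            continue
        dawn = session.frames[period.start].timestamp
        dawn_days = (dawn - origin).total_seconds() / 86400.0
        sel = (ts >= dawn_days - 1e-9) & (ts <= dawn_days + window_hours / 24.0 + 1e-9)
        idx = np.nonzero(sel)[0]
        rec = {
            "period_index": period.index,
            "dawn_time_days": dawn_days,
            "depth": 0.0,
            "dipped": False,
        }
        if idx.size >= 3:
            tw, vw = ts[idx], vs[idx]
            baseline = np.interp(tw, [tw[0], tw[-1]], [vw[0], vw[-1]])
            shortfall = (baseline[1:-1] - vw[1:-1]) / baseline[1:-1]
            depth = float(shortfall.max(initial=0.0))
            rec["depth"] = depth
            rec["dipped"] = depth >= min_depth
        results.append(rec)
    return results
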