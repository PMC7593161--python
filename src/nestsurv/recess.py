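"""Recess-bout classification and daily incubation movement metrics.

An incubating female's GPS fixes are classified as *nest* (within a buffer
of the nest bowl, default 27.5 m, chosen to absorb GPS error and trivial
off-bowl movements) or *recess* (strictly beyond the buffer).  A recess
bout is a maximal run of consecutive recess fixes within one calendar day;
daily metrics are the bout count, the off-nest duration (one hourly fix =
one hour) and the total path length summed over consecutive fixes.

The module also assembles the exposure-day table that feeds the daily
survival models: one row per nest per incubation day, with fate indicators
and behavioral covariates, applying first/last-day mean imputation and the
short-incubation (< 3 days) censoring rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Buffer radius (m) separating nest fixes from recess fixes.
DEFAULT_BUFFER_M = 27.5

#: Exposure rows from nests incubated fewer than this many days are dropped
#: from the covariate dataset (but retained for period survival).
MIN_INCUBATION_DAYS = 3


@dataclass(frozen=True)
class GpsFix:
    """One timestamped planar location of one bird (meters, local time)."""

    bird_id: str
    timestamp: pd.Timestamp
    x: float
    y: float


@dataclass(frozen=True)
class RecessBout:
    """A maximal run of consecutive off-nest fixes within one day."""

    nest_id: str
    date: object
    start: pd.Timestamp
    end: pd.Timestamp
    n_fixes: int
    max_displacement_m: float
    path_length_m: float


@dataclass
class CovariateScreenResult:
    """Pairwise Pearson correlations and the covariates dropped by the screen."""

    corr: pd.DataFrame
    dropped: list = field(default_factory=list)  # (dropped, kept, r) tuples

    @property
    def kept(self) -> list:
        gone = {d for d, _, _ in self.dropped}
        return [c for c in self.corr.columns if c not in gone]


def classify_fix(fix, nest_xy, buffer_m: float = DEFAULT_BUFFER_M) -> str:
    """Classify a single fix as ``"nest"`` or ``"recess"``.

    A fix is a recess location iff its Euclidean distance from the nest is
    strictly greater than ``buffer_m``; a fix exactly on the buffer is a
    nest location.
    """
    if isinstance(fix, GpsFix):
        xy = (fix.x, fix.y)
    else:
        xy = fix
    d = float(np.hypot(xy[0] - nest_xy[0], xy[1] - nest_xy[1]))
    if not np.isfinite(d):
        raise ValueError("non-finite fix or nest coordinates")
    return "recess" if d > buffer_m else "nest"


def _recess_mask(xy: np.ndarray, nest_xy, buffer_m: float) -> np.ndarray:
    xy = np.asarray(xy, dtype=float)
    if xy.size == 0:
        return np.zeros(0, dtype=bool)
    d = np.hypot(xy[:, 0] - nest_xy[0], xy[:, 1] - nest_xy[1])
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite coordinates in fix track")
    return d > buffer_m


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs (stop exclusive)."""
    if mask.size == 0:
        return
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    yield from zip(starts, stops)


def extract_bouts(
    times,
    xy,
    nest_xy,
    buffer_m: float = DEFAULT_BUFFER_M,
    nest_id: str = "",
    date=None,
) -> list[RecessBout]:
    """Extract maximal recess runs from one bird-day of time-ordered fixes.

    The number of bouts is the day's count of unique recesses.  Returns an
    empty list for empty input.
    """
    times = pd.DatetimeIndex(times)
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    mask = _recess_mask(xy, nest_xy, buffer_m)
    bouts = []
    for a, b in _runs(mask):
        pts = xy[a:b]
        disp = np.hypot(pts[:, 0] - nest_xy[0], pts[:, 1] - nest_xy[1])
        path = float(np.sum(np.hypot(*np.diff(pts, axis=0).T))) if b - a > 1 else 0.0
        bouts.append(
            RecessBout(
                nest_id=nest_id,
                date=date if date is not None else times[a].date(),
                start=times[a],
                end=times[b - 1],
                n_fixes=int(b - a),
                max_displacement_m=float(disp.max()),
                path_length_m=path,
            )
        )
    return bouts


def daily_metrics(
    times,
    xy,
    nest_xy,
    buffer_m: float = DEFAULT_BUFFER_M,
    night_fix_weight: float = 1.0,
) -> tuple[float, float, int]:
    """Compute (distance_m, duration_hr, n_recesses) for one bird-day.

    distance_m sums Euclidean legs between *all* consecutive fixes of the
    day, including legs between on-nest fixes (sub-buffer GPS scatter) —
    total daily distance traveled is unqualified.  duration_hr counts one
    hour per off-nest fix; the 23:59 fix, whose preceding gap is not hourly,
    contributes ``night_fix_weight`` hours when off nest (default 1).
    """
    times = pd.DatetimeIndex(times)
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        return 0.0, 0.0, 0
    mask = _recess_mask(xy, nest_xy, buffer_m)
    dist = float(np.sum(np.hypot(*np.diff(xy, axis=0).T))) if len(xy) > 1 else 0.0
    weights = np.ones(len(xy))
    # the nightly fix is the one at/after 21:00 local
    night = times.hour >= 21
    weights[night] = night_fix_weight
    duration = float(np.sum(weights[mask]))
    n_rec = sum(1 for _ in _runs(mask))
    return dist, duration, n_rec


def detect_onset(times, xy, buffer_m: float = DEFAULT_BUFFER_M, window_hr: float = 24.0):
    """Detect the onset of incubation in one bird's fix stream.

    Returns the earliest timestamp ``t`` such that every fix in
    ``[t, t + window_hr]`` lies within ``buffer_m`` of the centroid of the
    fixes in that window (locations "fixed around a central point" for a
    day), or ``None`` when no such window exists.  The clustering radius
    reuses the nest buffer.
    """
    times = pd.DatetimeIndex(times)
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(times) < 2 or times[-1] - times[0] < pd.Timedelta(hours=window_hr):
        raise ValueError(f"need at least {window_hr} hr of fixes")
    span = pd.Timedelta(hours=window_hr)
    j = 0
    for i in range(len(times)):
        if times[-1] - times[i] < span:
            break
        j = max(j, i)
        while j + 1 < len(times) and times[j + 1] - times[i] <= span:
            j += 1
        pts = xy[i : j + 1]
        centroid = pts.mean(axis=0)
        if np.hypot(*(pts - centroid).T).max() <= buffer_m:
            return times[i]
    return None


def build_exposure_table(
    nest_df: pd.DataFrame,
    fix_df: pd.DataFrame,
    range_df: pd.DataFrame | None = None,
    buffer_m: float = DEFAULT_BUFFER_M,
    night_fix_weight: float = 1.0,
    min_fix_fraction: float = 0.5,
    scheduled_fixes_per_day: int = 17,
    min_days: int = MIN_INCUBATION_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble exposure-day tables for the daily survival models.

    Returns ``(covariate_df, period_df)``:

    * ``covariate_df`` — one row per nest per incubation day for nests
      incubated at least ``min_days`` days.  The first and last incubation
      days keep their exposure rows but their behavioral covariates
      (distance, duration, recesses, range size) are replaced by the nest's
      across-day means, because movement metrics are poorly estimated on
      transition days.  Days with fewer than ``min_fix_fraction`` of the
      scheduled fixes are mean-imputed the same way.
    * ``period_df`` — the same rows for *all* nests (including those
      incubated < ``min_days`` days), intercept-only material for the
      period-survival fit.

    Fate coding: the last row of a failed nest has ``nest_alive = 0`` and
    every other row 1; hatched nests are 1 throughout.  ``female_alive`` is
    0 on the last row only when the female was killed.  Nests with no fixes
    in their incubation window are excluded with a logged warning.
    """
    fix_df = fix_df.sort_values(["bird_id", "timestamp"])
    rows = []
    behav = ["distance", "duration", "recesses"]
    have_range = range_df is not None
    if have_range:
        range_lookup = {
            (r.nest_id, pd.Timestamp(r.date).date()): r.area_ha
            for r in range_df.itertuples()
        }
    for nest in nest_df.itertuples():
        onset = pd.Timestamp(nest.onset)
        term = pd.Timestamp(nest.termination)
        if onset > term:
            raise ValueError(f"nest {nest.nest_id}: onset after termination")
        sub = fix_df[fix_df.bird_id == nest.bird_id]
        t = pd.DatetimeIndex(sub.timestamp)
        in_win = (t >= onset.normalize()) & (t < term.normalize() + pd.Timedelta(days=1))
        sub = sub[np.asarray(in_win)]
        if len(sub) == 0:
            logger.warning("nest %s has no fixes in its incubation window; excluded", nest.nest_id)
            continue
        t = pd.DatetimeIndex(sub.timestamp)
        xy = sub[["x", "y"]].to_numpy(float)
        n_days = (term.normalize() - onset.normalize()).days + 1
        dates = [onset.normalize() + pd.Timedelta(days=k) for k in range(n_days)]
        by_day = {d: [] for d in dates}
        day_keys = t.normalize()
        for d in dates:
            idx = np.flatnonzero(day_keys == d)
            by_day[d] = idx
        for j, d in enumerate(dates, start=1):
            idx = by_day[d]
            dist, dur, nrec = daily_metrics(
                t[idx], xy[idx], (nest.nest_x, nest.nest_y), buffer_m, night_fix_weight
            )
            last = j == n_days
            rows.append(
                {
                    "nest_id": nest.nest_id,
                    "bird_id": nest.bird_id,
                    "site": nest.site,
                    "year": nest.year,
                    "attempt": nest.attempt,
                    "concealment": nest.concealment_cm,
                    "day": j,
                    "nest_age": j,
                    "date": d.date(),
                    "distance": dist,
                    "duration": dur,
                    "recesses": nrec,
                    "range_size": range_lookup.get((nest.nest_id, d.date()), np.nan)
                    if have_range
                    else np.nan,
                    "n_fixes": len(idx),
                    "nest_alive": 0 if (last and nest.nest_fate != "hatched") else 1,
                    "female_alive": 0 if (last and nest.female_fate == "dead") else 1,
                    "first_or_last": j == 1 or last,
                    "sparse_day": len(idx) < min_fix_fraction * scheduled_fixes_per_day,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df, df
    # mean-impute behavioral covariates on first/last and fix-sparse days
    impute_cols = behav + (["range_size"] if have_range else [])
    df[impute_cols] = df[impute_cols].astype(float)
    for nid, grp in df.groupby("nest_id"):
        mask = grp.first_or_last | grp.sparse_day
        interior = ~mask
        means = grp.loc[interior, impute_cols].mean() if interior.any() else grp[impute_cols].mean()
        df.loc[grp.index[mask], impute_cols] = means.values
    period_df = df.copy()
    n_by_nest = df.groupby("nest_id")["day"].transform("max")
    cov_df = df[n_by_nest >= min_days].reset_index(drop=True)
    return cov_df, period_df.reset_index(drop=True)


def screen_collinearity(
    df: pd.DataFrame,
    candidates: list[str],
    threshold: float = 0.7,
    priority: list[str] | None = None,
) -> CovariateScreenResult:
    """Screen candidate covariates for pairwise collinearity.

    Computes the Pearson correlation matrix; for every pair with
    ``|r| >= threshold`` the member appearing *later* in ``priority``
    (default: the candidate order) is dropped.  In the source analysis this
    removed daily range size, which correlated with daily distance at
    r = 0.74, keeping distance.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate covariates")
    sub = df[candidates].dropna()
    if len(sub) < 3:
        raise ValueError("need at least three complete rows")
    sds = sub.std(ddof=1)
    for c in candidates:
        if sds[c] == 0 or not np.isfinite(sds[c]):
            raise ValueError(f"covariate {c!r} has zero variance")
    corr = sub.corr(method="pearson")
    priority = list(priority) if priority is not None else list(candidates)
    rank = {c: priority.index(c) if c in priority else len(priority) for c in candidates}
    dropped = []
    gone: set[str] = set()
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            if a in gone or b in gone:
                continue
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                loser, keeper = (a, b) if rank[a] > rank[b] else (b, a)
                dropped.append((loser, keeper, float(r)))
                gone.add(loser)
    return CovariateScreenResult(corr=corr, dropped=dropped)
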