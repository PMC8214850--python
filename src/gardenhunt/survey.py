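"""Camera-trap survey data handling.

This module turns raw camera-trap photo records into the objects the
abundance models consume: detection events (photo bursts collapsed with a
5-minute rule), site x visit detection histories with a paired survey-effort
matrix, site retention filters, and the site covariates that are not taken
directly from GIS layers (inverse-distance-weighted track density,
standardization).  Survey summaries (per-species detection-event counts and
the frequency-of-detection index, events per 100 camera-days) live here too.

Conventions
-----------
* Timestamps are naive local time; the event rule works at minute
  resolution or finer.  Two photos of the same species at the same camera
  belong to one event when their gap is strictly less than ``gap_minutes``;
  a gap of exactly the threshold starts a new event.
* Coordinates are planar metres in a single projected CRS chosen by the
  user; no geodesy is performed.
* A season of ``season_days`` is divided into consecutive sampling periods
  of ``period_days``; each period is cut into visits of ``visit_days`` with
  the final visit truncated at the period boundary (180-day season, 60-day
  periods, 21-day visits gives visit lengths 21/21/18 and at most 9 visits).
* Effort is days-active divided by visit length, hence always <= 1; a
  camera absent or inoperative for a whole visit yields missing effort and
  a missing detection entry (``NaN``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionEvent",
    "Deployment",
    "DetectionHistory",
    "collapse_events",
    "tabulate_detections",
    "frequency_of_detection",
    "visit_windows",
    "build_histories",
    "filter_sites",
    "subset_history",
    "track_density",
    "standardize",
    "read_photos",
    "read_deployments",
    "read_tracks",
    "history_to_frame",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DetectionEvent:
    """A burst of photos of one species at one camera.

    Consecutive photos of the same camera+species stream separated by less
    than the collapse gap belong to the same event.
    """

    camera_id: str
    species: str
    start_time: pd.Timestamp
    n_photos: int = 1


@dataclass
class Deployment:
    """A camera placement with the date intervals it was present and working.

    ``activity_intervals`` is a list of ``(start, end)`` timestamp pairs,
    half-open ``[start, end)``, non-overlapping.
    """

    camera_id: str
    x: float
    y: float
    block_id: str = ""
    activity_intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = field(
        default_factory=list
    )

    def active_days(self) -> float:
        return float(
            sum((e - s) / pd.Timedelta(days=1) for s, e in self.activity_intervals)
        )


@dataclass
class DetectionHistory:
    """Site x visit detection/non-detection data for one species.

    Attributes
    ----------
    species : str
    sites : list of camera ids (rows, i = 1..M)
    windows : list of ``(start_day, end_day)`` day offsets from season start,
        half-open (columns, j = 1..J)
    y : (M, J) float array in {0.0, 1.0, NaN}
    effort : (M, J) float array in (0, 1] or NaN; NaN exactly where y is NaN
    date : (M, J) standardized visit start offsets (same value down a column)
    """

    species: str
    sites: list[str]
    windows: list[tuple[float, float]]
    y: np.ndarray
    effort: np.ndarray
    date: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_visits(self) -> int:
        return len(self.windows)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def total_detections(self) -> int:
        """Number of site-visit cells with a detection."""
        return int(np.nansum(self.y))


# ---------------------------------------------------------------------------
# event collapsing and summaries


def _as_photo_frame(photos) -> pd.DataFrame:
    if isinstance(photos, pd.DataFrame):
        df = photos.copy()
    else:
        df = pd.DataFrame(list(photos), columns=["camera_id", "species", "timestamp"])
    missing = {"camera_id", "species", "timestamp"} - set(df.columns)
    if missing:
        raise ValueError(f"photo table missing columns: {sorted(missing)}")
    if (df["species"].astype(str).str.len() == 0).any():
        raise ValueError("empty species code in photo table")
    if not pd.api.types.is_datetime64_any_dtype(df["timestamp"]):
        parsed = pd.to_datetime(df["timestamp"], errors="coerce")
        bad = np.flatnonzero(parsed.isna() & df["timestamp"].notna())
        if bad.size:
            raise ValueError(
                f"unparseable timestamp at photo row(s) {bad.tolist()[:10]}"
            )
        if parsed.isna().any():
            raise ValueError(
                f"missing timestamp at photo row(s) "
                f"{np.flatnonzero(parsed.isna()).tolist()[:10]}"
            )
        df = df.assign(timestamp=parsed)
    return df


def collapse_events(photos, gap_minutes: float = 5.0) -> list[DetectionEvent]:
    """Collapse photo records into detection events.

    Within each camera+species stream, photos separated by strictly less
    than ``gap_minutes`` are merged into a single event; a gap of
    ``gap_minutes`` or more starts a new event.  The result is independent
    of the input row order.
    """
    df = _as_photo_frame(photos)
    events: list[DetectionEvent] = []
    gap = pd.Timedelta(minutes=gap_minutes)
    for (cam, sp), grp in df.groupby(["camera_id", "species"], sort=True):
        times = grp["timestamp"].sort_values().tolist()
        start = times[0]
        n = 1
        prev = times[0]
        for t in times[1:]:
            if t - prev >= gap:
                events.append(DetectionEvent(str(cam), str(sp), start, n))
                start, n = t, 1
            else:
                n += 1
            prev = t
        events.append(DetectionEvent(str(cam), str(sp), start, n))
    return events


def tabulate_detections(
    events: Iterable[DetectionEvent],
    species_class: Mapping[str, str] | None = None,
) -> tuple[pd.Series, dict[str, int]]:
    """Per-species detection-event counts D and totals by taxonomic class.

    Parameters
    ----------
    events : detection events, e.g. from :func:`collapse_events`.
    species_class : optional map from species code to a class label such as
        ``"mammal"`` or ``"bird"``.  Species missing from the map are counted
        under ``"unidentified"`` with a warning.

    Returns
    -------
    (D, class_totals) where ``D`` is a Series indexed by species and
    ``class_totals`` maps each class label to the sum of its members' D.
    """
    counts: dict[str, int] = {}
    for ev in events:
        counts[ev.species] = counts.get(ev.species, 0) + 1
    D = pd.Series(counts, dtype=int).sort_index()
    D.name = "D"
    totals: dict[str, int] = {}
    if species_class is not None:
        unknown = [sp for sp in D.index if sp not in species_class]
        if unknown:
            warnings.warn(
                f"species without class assignment counted as 'unidentified': "
                f"{unknown}",
                stacklevel=2,
            )
        for sp, d in D.items():
            cls = species_class.get(sp, "unidentified")
            totals[cls] = totals.get(cls, 0) + int(d)
    return D, totals


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def frequency_of_detection(
    D: float, camera_days: float, decimals: int | None = 2
) -> float:
    """Frequency-of-detection index: events per 100 camera-days.

    ``FD = 100 * D / camera_days``, rounded half-up to ``decimals`` for
    reporting (pass ``decimals=None`` for the raw value).
    """
    if camera_days <= 0:
        raise ValueError("camera_days must be positive")
    fd = 100.0 * float(D) / float(camera_days)
    if decimals is None:
        return fd
    return _round_half_up(fd, decimals)


# ---------------------------------------------------------------------------
# visit construction


def visit_windows(
    visit_days: int = 21, season_days: int = 180, period_days: int = 60
) -> list[tuple[float, float]]:
    """Half-open visit windows in day offsets from the season start.

    Each sampling period of ``period_days`` is cut into consecutive visits
    of ``visit_days``; the last visit of a period is truncated at the period
    boundary so effort stays normalized by the true window length.
    """
    if visit_days <= 0:
        raise ValueError("visit_days must be positive")
    windows: list[tuple[float, float]] = []
    for p0 in range(0, season_days, period_days):
        p1 = min(p0 + period_days, season_days)
        t = p0
        while t < p1:
            windows.append((float(t), float(min(t + visit_days, p1))))
            t += visit_days
    return windows


def _interval_overlap_days(
    intervals: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
    w_start: pd.Timestamp,
    w_end: pd.Timestamp,
) -> float:
    total = 0.0
    for s, e in intervals:
        lo, hi = max(s, w_start), min(e, w_end)
        if hi > lo:
            total += (hi - lo) / pd.Timedelta(days=1)
    return total


def build_histories(
    events: Iterable[DetectionEvent],
    deployments: Sequence[Deployment],
    season_start,
    visit_days: int = 21,
    season_days: int = 180,
    period_days: int = 60,
    species: Sequence[str] | None = None,
) -> dict[str, DetectionHistory]:
    """Build per-species detection histories from events and deployments.

    ``y[i, j]`` is 1 when at least one event of the species fell in visit j
    at site i, 0 when the camera was active part or all of the visit but
    recorded no event, and NaN when the camera was absent or inoperative for
    the entire visit.  ``effort[i, j]`` is days-active divided by the visit
    length (NaN exactly where y is NaN).  The ``date`` matrix holds the
    standardized visit start offsets, constant down each column.

    Raises
    ------
    ValueError
        If an event falls outside every activity interval of its camera, or
        names a camera with no deployment.
    """
    season_start = pd.Timestamp(season_start)
    windows = visit_windows(visit_days, season_days, period_days)
    sites = [d.camera_id for d in deployments]
    site_ix = {c: i for i, c in enumerate(sites)}
    M, J = len(sites), len(windows)

    effort = np.full((M, J), np.nan)
    for d in deployments:
        i = site_ix[d.camera_id]
        for j, (a, b) in enumerate(windows):
            w0 = season_start + pd.Timedelta(days=a)
            w1 = season_start + pd.Timedelta(days=b)
            act = _interval_overlap_days(d.activity_intervals, w0, w1)
            if act > 0:
                effort[i, j] = act / (b - a)

    events = list(events)
    if species is None:
        species = sorted({ev.species for ev in events})

    by_dep = {d.camera_id: d for d in deployments}
    histories: dict[str, DetectionHistory] = {}
    starts = np.array([a for a, _ in windows])
    date_std = standardize(starts)
    date = np.tile(date_std, (M, 1))

    per_species_events: dict[str, list[DetectionEvent]] = {sp: [] for sp in species}
    for ev in events:
        if ev.camera_id not in by_dep:
            raise ValueError(f"event at unknown camera {ev.camera_id!r}")
        dep = by_dep[ev.camera_id]
        if not any(s <= ev.start_time < e for s, e in dep.activity_intervals):
            raise ValueError(
                f"event outside deployment intervals: camera {ev.camera_id!r} "
                f"at {ev.start_time}"
            )
        if ev.species in per_species_events:
            per_species_events[ev.species].append(ev)

    for sp in species:
        y = np.where(np.isnan(effort), np.nan, 0.0)
        for ev in per_species_events[sp]:
            i = site_ix[ev.camera_id]
            off = (ev.start_time - season_start) / pd.Timedelta(days=1)
            for j, (a, b) in enumerate(windows):
                if a <= off < b:
                    if np.isnan(y[i, j]):
                        raise ValueError(
                            f"event at {ev.camera_id!r} in visit {j} but camera "
                            f"has no recorded activity in that visit"
                        )
                    y[i, j] = 1.0
                    break
        histories[sp] = DetectionHistory(
            species=sp,
            sites=list(sites),
            windows=list(windows),
            y=y,
            effort=effort.copy(),
            date=date.copy(),
        )
    return histories


def subset_history(h: DetectionHistory, sites: Sequence[str]) -> DetectionHistory:
    """Restrict a history to the given sites (e.g. after filtering)."""
    ix = [h.sites.index(s) for s in sites]
    return DetectionHistory(
        species=h.species,
        sites=list(sites),
        windows=list(h.windows),
        y=h.y[ix],
        effort=h.effort[ix],
        date=h.date[ix],
    )


def history_to_frame(h: DetectionHistory) -> pd.DataFrame:
    """Wide per-site table: y_1..y_J then eff_1..eff_J, NaN for missing."""
    J = h.n_visits
    cols = {f"y_{j + 1}": h.y[:, j] for j in range(J)}
    cols.update({f"eff_{j + 1}": h.effort[:, j] for j in range(J)})
    return pd.DataFrame(cols, index=pd.Index(h.sites, name="camera_id"))


# ---------------------------------------------------------------------------
# site filtering and covariates


def filter_sites(
    covariates: pd.DataFrame,
    deployments: Sequence[Deployment],
    min_active_days: float = 7,
    max_dist_conuco_m: float = 5000.0,
) -> tuple[list[str], pd.DataFrame]:
    """Retain sites with enough activity and within reach of a conuco.

    A site is kept when its total active days are at least
    ``min_active_days`` and its distance to the nearest conuco is at most
    ``max_dist_conuco_m``.  Returns the retained camera ids (deployment
    order) and an exclusion log with one row per dropped site and the rule
    that dropped it.
    """
    cov = covariates.set_index("camera_id") if "camera_id" in covariates else covariates
    retained: list[str] = []
    rows = []
    for d in deployments:
        reasons = []
        if d.active_days() < min_active_days:
            reasons.append("min_active_days")
        if d.camera_id in cov.index:
            if float(cov.loc[d.camera_id, "dist_conuco"]) > max_dist_conuco_m:
                reasons.append("distance")
        else:
            reasons.append("no_covariates")
        if reasons:
            rows.append({"camera_id": d.camera_id, "reason": "+".join(reasons)})
        else:
            retained.append(d.camera_id)
    log = pd.DataFrame(rows, columns=["camera_id", "reason"])
    if not retained:
        warnings.warn("no sites retained after filtering", stacklevel=2)
    return retained, log


def track_density(
    site_xy: Sequence[float],
    records,
    q: float = 0.25,
    d_floor_m: float = 1.0,
) -> float:
    """Inverse-distance-weighted sum of off-camera wildlife records.

    ``sum_j 1 / max(d_j, d_floor)**q`` over all records, with ``d_j`` the
    planar distance in metres from the site to record j.  The power ``q``
    controls the smoothing of the interpolation; the floor guards against a
    record coinciding with the camera.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    xy = _tracks_xy(records)
    if xy.shape[0] == 0:
        warnings.warn("no track records; track density set to 0", stacklevel=2)
        return 0.0
    d = np.hypot(xy[:, 0] - site_xy[0], xy[:, 1] - site_xy[1])
    d = np.maximum(d, d_floor_m)
    return float(np.sum(d**-q))


def _tracks_xy(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        xy = records[["x", "y"]].to_numpy(float)
    else:
        xy = np.asarray(
            [(r.x, r.y) if hasattr(r, "x") else (r[0], r[1]) for r in records],
            dtype=float,
        ).reshape(-1, 2)
    if xy.size and not np.isfinite(xy).all():
        raise ValueError("non-finite track coordinates")
    return xy


def standardize(values) -> np.ndarray:
    """Center to zero mean and scale to unit sample SD (n-1 denominator).

    Missing values (NaN) are ignored in the mean/SD and preserved in the
    output.  A constant vector has no scale and raises.
    """
    v = np.asarray(values, dtype=float)
    finite = v[~np.isnan(v)]
    if finite.size < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    sd = float(np.std(finite, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: cannot standardize a constant vector")
    return (v - float(np.mean(finite))) / sd


# ---------------------------------------------------------------------------
# CSV I/O


def read_photos(path) -> pd.DataFrame:
    """photos.csv: camera_id, species, timestamp (ISO-8601)."""
    df = pd.read_csv(path, dtype={"camera_id": str, "species": str})
    return _as_photo_frame(df)


def read_deployments(path) -> list[Deployment]:
    """deployments.csv: camera_id, x, y, block, start, end (one interval/row)."""
    df = pd.read_csv(path, dtype={"camera_id": str, "block": str})
    deps: dict[str, Deployment] = {}
    for _, row in df.iterrows():
        cam = str(row["camera_id"])
        if cam not in deps:
            deps[cam] = Deployment(
                camera_id=cam,
                x=float(row["x"]),
                y=float(row["y"]),
                block_id=str(row.get("block", "")),
            )
        deps[cam].activity_intervals.append(
            (pd.Timestamp(row["start"]), pd.Timestamp(row["end"]))
        )
    for d in deps.values():
        d.activity_intervals.sort()
    return list(deps.values())


def read_tracks(path) -> pd.DataFrame:
    """tracks.csv: x, y, date, note."""
    df = pd.read_csv(path)
    _tracks_xy(df)
    return df
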