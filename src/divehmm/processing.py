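"""From raw telemetry tables to HMM-ready behavioural records.

Tags compress each dive's time-depth trace to a handful of broken-stick
inflection points; hydrographic casts arrive as sparse CTD profiles; tracks
and bathymetry live in separate tables.  This module turns those pieces into
one tidy record table carrying the five model streams (duration, hunting
depth, hunting-time proportion, bathymetry-contact indicator, salinity at
hunting depth) plus the transition covariates (local solar hour, week of
year).

Hunting segments are maximal runs of inter-point intervals whose absolute
vertical speed is strictly below a threshold (default 0.5 m/s, an
accelerometry-calibrated proxy for prey-capture activity); the hunting depth
of a dive is the duration-weighted mean depth of its single longest hunting
segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SPEED_THRESHOLD = 0.5  # m/s vertical; below = hunting
BENTHIC_FRACTION = 0.97  # fraction of bathymetry counting as bottom contact
DEFAULT_CUTOFF = "2011-06-19"


# ---------------------------------------------------------------------------
# domain types


@dataclass
class DiveProfile:
    """Broken-stick time-depth points of one dive (piecewise linear)."""

    dive_id: object
    points: np.ndarray  # (k, 2): elapsed_s, depth_m
    start_time: pd.Timestamp | None = None
    duration_s: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (k, 2): elapsed_s, depth_m")
        t, d = self.points[:, 0], self.points[:, 1]
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError(f"dive {self.dive_id}: elapsed times must strictly increase")
        if np.any(d < 0):
            raise ValueError(f"dive {self.dive_id}: negative depth")
        if len(d) >= 2 and (abs(d[0]) > 2.0 or abs(d[-1]) > 2.0):
            raise ValueError(f"dive {self.dive_id}: profile must start/end near the surface")
        if self.duration_s is None and len(t):
            self.duration_s = float(t[-1])

    @property
    def max_depth(self) -> float:
        return float(self.points[:, 1].max())


@dataclass
class CtdProfile:
    """One hydrographic cast: depth levels with salinity (and temperature)."""

    profile_time: pd.Timestamp
    levels: np.ndarray  # (k, 2) or (k, 3): depth_m, salinity_psu[, temperature_C]

    def __post_init__(self) -> None:
        self.profile_time = pd.Timestamp(self.profile_time)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.ndim != 2 or self.levels.shape[1] not in (2, 3):
            raise ValueError("levels must be (k, 2) or (k, 3)")
        z, s = self.levels[:, 0], self.levels[:, 1]
        if np.any(np.diff(z) <= 0):
            raise ValueError("CTD depths must strictly increase")
        if np.any((s <= 0) | (s >= 40)):
            raise ValueError("salinity outside (0, 40) psu")

    @property
    def has_temperature(self) -> bool:
        return self.levels.shape[1] == 3

    def value_at(self, depth: float, var: str = "salinity") -> float:
        """Linear-in-depth interpolation; beyond the deepest (or shallowest)
        level the nearest level's value is used, with a logged warning for
        the deep side."""
        col = {"salinity": 1, "temperature": 2}[var]
        if col == 2 and not self.has_temperature:
            return np.nan
        z = self.levels[:, 0]
        if depth > z[-1]:
            log.warning(
                "query depth %.1f m below deepest CTD level %.1f m at %s; "
                "using nearest level", depth, z[-1], self.profile_time,
            )
        return float(np.interp(depth, z, self.levels[:, col]))


# ---------------------------------------------------------------------------
# hunting segments


def extract_hunting_segments(
    profile: DiveProfile, speed_threshold: float = SPEED_THRESHOLD
):
    """Low-vertical-speed segments of a broken-stick dive profile.

    An inter-point interval is a hunting interval when |d_depth/d_t| is
    strictly below ``speed_threshold`` (an interval at exactly the threshold
    counts as transit).  Segments are maximal runs of consecutive hunting
    intervals.

    Returns
    -------
    segments : list of (t_start, t_end, mean_depth)
        Duration-weighted mean depth per segment (trapezoid midpoints).
    hunting_time_s : float
        Total duration of all hunting intervals.
    hunting_depth_m : float
        Duration-weighted mean depth of the single longest segment.  A dive
        with no sub-threshold interval takes the mean depth of its slowest
        interval, so every dive yields a depth for the model stream.
    """
    pts = profile.points
    if len(pts) < 2:
        raise ValueError("need at least two profile points")
    t, d = pts[:, 0], pts[:, 1]
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("zero-length profile interval")
    speed = np.abs(np.diff(d)) / dt
    mid = 0.5 * (d[:-1] + d[1:])
    hunting = speed < speed_threshold

    segments = []
    i = 0
    n = len(dt)
    while i < n:
        if hunting[i]:
            j = i
            while j + 1 < n and hunting[j + 1]:
                j += 1
            dur = float(dt[i : j + 1].sum())
            mean_depth = float((mid[i : j + 1] * dt[i : j + 1]).sum() / dur)
            segments.append((float(t[i]), float(t[j + 1]), mean_depth))
            i = j + 1
        else:
            i += 1
    hunting_time = float(dt[hunting].sum())
    if segments:
        durations = [s[1] - s[0] for s in segments]
        hunting_depth = segments[int(np.argmax(durations))][2]
    else:
        hunting_depth = float(mid[int(np.argmin(speed))])
    return segments, hunting_time, hunting_depth


def squeeze_proportion(p, n: int):
    """Squeeze proportions off the boundary: (p*(n-1) + 0.5) / n.

    The beta density is undefined at 0 and 1; with n the number of dives in
    the dataset this maps [0, 1] into the open interval.
    """
    p = np.asarray(p, dtype=float)
    out = (p * (n - 1) + 0.5) / n
    return float(out) if out.ndim == 0 else out


def derive_dive_streams(
    profile: DiveProfile,
    bathymetry_m: float | None,
    n_dives: int,
    speed_threshold: float = SPEED_THRESHOLD,
    benthic_fraction: float = BENTHIC_FRACTION,
):
    """Per-dive model streams: (hunting_depth_m, prop_hunting, benthic).

    ``prop_hunting`` is hunting_time/duration squeezed into (0, 1) with the
    dataset size ``n_dives``.  ``benthic`` is 1 when the hunting depth
    reaches at least ``benthic_fraction`` of the local bathymetry (the
    depth/bathymetry ratio clamped to [0, 1] first — bathymetry grids err),
    and None when bathymetry is missing.
    """
    _, hunting_time, hunting_depth = extract_hunting_segments(
        profile, speed_threshold
    )
    duration = profile.duration_s
    prop = squeeze_proportion(min(hunting_time / duration, 1.0), n_dives)
    if bathymetry_m is None or not np.isfinite(bathymetry_m) or bathymetry_m <= 0:
        log.warning("dive %s: missing bathymetry; benthic indicator missing",
                    profile.dive_id)
        benthic = None
    else:
        ratio = min(max(hunting_depth / bathymetry_m, 0.0), 1.0)
        benthic = int(ratio >= benthic_fraction)
    return hunting_depth, prop, benthic


# ---------------------------------------------------------------------------
# CTD matching


def match_ctd(
    dive_time,
    hunting_depth: float,
    ctd_profiles: list[CtdProfile],
    max_gap_h: float = 24.0,
    var: str = "salinity",
) -> float:
    """In-situ variable at a dive's hunting depth, by two-stage interpolation.

    Within each of the two CTD casts bracketing the dive in time, the value
    is interpolated linearly in depth to the hunting depth; the two values
    are then interpolated linearly in time to the dive time.  With only one
    cast inside the ``max_gap_h`` window that cast's value is used; with
    none, NaN.
    """
    if not ctd_profiles:
        return np.nan
    dive_time = pd.Timestamp(dive_time)
    times = [p.profile_time for p in ctd_profiles]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("CTD profiles must be sorted by strictly increasing time")
    gap = pd.Timedelta(hours=max_gap_h)
    after_idx = next((i for i, t in enumerate(times) if t >= dive_time), None)
    before_idx = after_idx - 1 if after_idx is not None and after_idx > 0 else (
        len(times) - 1 if after_idx is None else None
    )
    before_ok = (
        before_idx is not None and dive_time - times[before_idx] <= gap
    )
    after_ok = after_idx is not None and times[after_idx] - dive_time <= gap
    if not before_ok and not after_ok:
        return np.nan
    if before_ok and not after_ok:
        return ctd_profiles[before_idx].value_at(hunting_depth, var)
    if after_ok and not before_ok:
        return ctd_profiles[after_idx].value_at(hunting_depth, var)
    p0, p1 = ctd_profiles[before_idx], ctd_profiles[after_idx]
    v0 = p0.value_at(hunting_depth, var)
    v1 = p1.value_at(hunting_depth, var)
    span = (p1.profile_time - p0.profile_time).total_seconds()
    if span == 0:
        return v0
    w = (dive_time - p0.profile_time).total_seconds() / span
    return float((1.0 - w) * v0 + w * v1)


# ---------------------------------------------------------------------------
# covariates


def local_solar_time(utc, lon) -> float | np.ndarray:
    """Local solar hour in [0, 24): UTC hour + lon/15, wrapped.

    ``utc`` may be a Timestamp/datetime, an array of them, or epoch seconds.
    """
    ts = pd.to_datetime(utc, utc=True, format="ISO8601")
    if isinstance(ts, pd.Timestamp):
        hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    else:
        ts = pd.DatetimeIndex(ts)
        hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
        hours = np.asarray(hours, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(lon < -180) or np.any(lon > 180):
        raise ValueError("longitude must lie in [-180, 180]")
    out = np.mod(hours + lon / 15.0, 24.0)
    return float(out) if out.ndim == 0 else out


def iso_week(times) -> np.ndarray:
    """ISO week of year for an array-like of timestamps."""
    idx = pd.DatetimeIndex(pd.to_datetime(times, utc=True, format="ISO8601"))
    return idx.isocalendar().week.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# bathymetry


class BathymetryGrid:
    """Regular lon/lat grid of water depth (m, positive down), bilinear lookup."""

    def __init__(self, lons: np.ndarray, lats: np.ndarray, depth: np.ndarray):
        self.lons = np.asarray(lons, dtype=float)
        self.lats = np.asarray(lats, dtype=float)
        self.depth = np.asarray(depth, dtype=float)
        if self.depth.shape != (self.lats.size, self.lons.size):
            raise ValueError("depth must have shape (n_lat, n_lon)")
        if np.any(np.diff(self.lons) <= 0) or np.any(np.diff(self.lats) <= 0):
            raise ValueError("grid axes must strictly increase")

    def at(self, lon, lat):
        """Bilinear interpolation, clamped to the grid edges."""
        lon = np.clip(np.asarray(lon, dtype=float), self.lons[0], self.lons[-1])
        lat = np.clip(np.asarray(lat, dtype=float), self.lats[0], self.lats[-1])
        i = np.clip(np.searchsorted(self.lons, lon) - 1, 0, self.lons.size - 2)
        j = np.clip(np.searchsorted(self.lats, lat) - 1, 0, self.lats.size - 2)
        x = (lon - self.lons[i]) / (self.lons[i + 1] - self.lons[i])
        y = (lat - self.lats[j]) / (self.lats[j + 1] - self.lats[j])
        d = self.depth
        out = (
            d[j, i] * (1 - x) * (1 - y)
            + d[j, i + 1] * x * (1 - y)
            + d[j + 1, i] * (1 - x) * y
            + d[j + 1, i + 1] * x * y
        )
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_csv(cls, path) -> "BathymetryGrid":
        """Long-format CSV with columns lon, lat, bathymetry_m."""
        df = pd.read_csv(path)
        pivot = df.pivot_table(index="lat", columns="lon", values="bathymetry_m")
        return cls(pivot.columns.to_numpy(), pivot.index.to_numpy(), pivot.to_numpy())

    @classmethod
    def from_netcdf(cls, path, var: str = "bathymetry_m") -> "BathymetryGrid":
        import xarray as xr  # optional dependency

        ds = xr.open_dataset(path)
        da = ds[var]
        return cls(da["lon"].to_numpy(), da["lat"].to_numpy(), da.to_numpy())


# ---------------------------------------------------------------------------
# record assembly


def _parse_profiles(dive_table: pd.DataFrame) -> list[DiveProfile]:
    """Wide-format dive table -> DiveProfile list.

    Point columns are ``point_elapsed_s_<k>`` / ``point_depth_m_<k>``
    (NaN-padded); surface endpoints (0, 0) and (duration, 0) are appended
    automatically when absent.
    """
    elapsed_cols = sorted(
        (c for c in dive_table.columns if c.startswith("point_elapsed_s_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    depth_cols = sorted(
        (c for c in dive_table.columns if c.startswith("point_depth_m_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if len(elapsed_cols) != len(depth_cols) or not elapsed_cols:
        raise ValueError("dive table needs matching point_elapsed_s_*/point_depth_m_* columns")
    profiles = []
    for idx, row in dive_table.iterrows():
        t = row[elapsed_cols].to_numpy(dtype=float)
        d = row[depth_cols].to_numpy(dtype=float)
        keep = np.isfinite(t) & np.isfinite(d)
        t, d = t[keep], d[keep]
        dur = float(row["duration_s"])
        pts = list(zip(t, d))
        if not pts or pts[0][0] > 0:
            pts.insert(0, (0.0, 0.0))
        if pts[-1][0] < dur:
            pts.append((dur, 0.0))
        profiles.append(
            DiveProfile(
                dive_id=row.get("dive_id", idx),
                points=np.array(pts),
                start_time=pd.Timestamp(row["start_time"]),
                duration_s=dur,
            )
        )
    return profiles


def ctd_profiles_from_table(ctd_table: pd.DataFrame) -> list[CtdProfile]:
    """Long-format CTD CSV (one row per level) -> sorted CtdProfile list.

    Columns: profile_time, depth_m, salinity_psu[, temperature_C].
    """
    profiles = []
    has_temp = "temperature_C" in ctd_table.columns
    for t, grp in ctd_table.groupby("profile_time"):
        grp = grp.sort_values("depth_m")
        cols = ["depth_m", "salinity_psu"] + (["temperature_C"] if has_temp else [])
        profiles.append(CtdProfile(pd.Timestamp(t), grp[cols].to_numpy()))
    profiles.sort(key=lambda p: p.profile_time)
    return profiles


def _interp_track(track: pd.DataFrame, times: pd.Series) -> pd.DataFrame:
    tt = pd.DatetimeIndex(pd.to_datetime(track["time"], utc=True, format="ISO8601")).asi8 / 1e9
    qt = pd.DatetimeIndex(pd.to_datetime(times, utc=True, format="ISO8601")).asi8 / 1e9
    return pd.DataFrame(
        {
            "lon": np.interp(qt, tt, track["lon"].to_numpy(dtype=float)),
            "lat": np.interp(qt, tt, track["lat"].to_numpy(dtype=float)),
        },
        index=times.index,
    )


def assemble_records(
    dive_table: pd.DataFrame,
    haulout_table: pd.DataFrame | None = None,
    surface_table: pd.DataFrame | None = None,
    ctd_table: pd.DataFrame | None = None,
    track: pd.DataFrame | None = None,
    bathymetry=None,
    cutoff: str | None = DEFAULT_CUTOFF,
    speed_threshold: float = SPEED_THRESHOLD,
    benthic_fraction: float = BENTHIC_FRACTION,
    max_gap_h: float = 24.0,
) -> pd.DataFrame:
    """Combine dive/haulout/surface tables into one tidy record table.

    Produces one row per behavioural record, sorted by start time within
    individual, with the five model streams and the covariates filled in.
    Records starting after ``cutoff`` (a date; default 2011-06-19, where
    transmission throughput collapses in the reference deployment) are
    dropped; overlapping records keep the earlier one.  ``bathymetry`` may
    be a :class:`BathymetryGrid`, a scalar depth, or a track-lookup
    DataFrame (time, bathymetry_m) matched by nearest time.
    """
    frames = []
    for tbl, rtype in ((haulout_table, "haulout"), (surface_table, "surface"),
                       (dive_table, "dive")):
        if tbl is None or len(tbl) == 0:
            continue
        f = tbl[["individual_id", "start_time", "duration_s"]].copy()
        f["start_time"] = pd.to_datetime(f["start_time"], utc=True, format="ISO8601")
        f["record_type"] = rtype
        f["_row"] = np.arange(len(tbl))
        f["lon"] = tbl["lon"].to_numpy(dtype=float) if "lon" in tbl else 0.0
        f["lat"] = tbl["lat"].to_numpy(dtype=float) if "lat" in tbl else np.nan
        frames.append(f)
    if not frames:
        raise ValueError("no input records")
    rec = pd.concat(frames, ignore_index=True)
    if cutoff is not None:
        rec = rec[rec["start_time"] <= pd.Timestamp(cutoff, tz="UTC")]
    rec = rec.sort_values(["individual_id", "start_time"], kind="stable")

    # drop overlaps, keeping the earlier record
    keep = []
    for _, grp in rec.groupby("individual_id", sort=False):
        end = None
        for idx, row in grp.iterrows():
            # 1 s tolerance: tag clocks and float rounding jitter at that scale
            if end is not None and row["start_time"] < end - pd.Timedelta(seconds=1):
                log.warning(
                    "overlapping record at %s (%s); keeping the earlier one",
                    row["start_time"], row["individual_id"],
                )
                continue
            keep.append(idx)
            end = row["start_time"] + pd.Timedelta(seconds=row["duration_s"])
    rec = rec.loc[keep].reset_index(drop=True)

    # track positions
    if track is not None:
        parts = []
        for ind, grp in rec.groupby("individual_id", sort=False):
            tr = track[track["individual_id"] == ind]
            if len(tr) == 0:
                raise ValueError(f"no track for individual {ind}")
            parts.append(_interp_track(tr, grp["start_time"]))
        pos = pd.concat(parts)
        rec["lon"] = pos["lon"]
        rec["lat"] = pos["lat"]

    rec["local_hour"] = local_solar_time(
        rec["start_time"], rec["lon"].to_numpy()
    )
    rec["week_of_year"] = iso_week(rec["start_time"])

    # dive streams
    dive_rows = rec["record_type"] == "dive"
    n_dives = int(dive_rows.sum())
    for col in ("hunting_depth_m", "prop_hunting", "benthic", "salinity_psu",
                "temperature_C", "bathymetry_m", "max_depth_m"):
        rec[col] = np.nan
    if n_dives:
        profiles = _parse_profiles(dive_table)
        ctd_profiles = (
            ctd_profiles_from_table(ctd_table) if ctd_table is not None else []
        )
        has_temp = bool(ctd_profiles) and ctd_profiles[0].has_temperature
        for idx in rec.index[dive_rows]:
            prof = profiles[int(rec.at[idx, "_row"])]
            bathy = _lookup_bathymetry(
                bathymetry, rec.at[idx, "lon"], rec.at[idx, "lat"],
                rec.at[idx, "start_time"],
            )
            depth, prop, benthic = derive_dive_streams(
                prof, bathy, n_dives, speed_threshold, benthic_fraction
            )
            mid_time = rec.at[idx, "start_time"] + pd.Timedelta(
                seconds=float(rec.at[idx, "duration_s"]) / 2.0
            )
            rec.at[idx, "hunting_depth_m"] = depth
            rec.at[idx, "prop_hunting"] = prop
            rec.at[idx, "benthic"] = np.nan if benthic is None else benthic
            rec.at[idx, "bathymetry_m"] = np.nan if bathy is None else bathy
            rec.at[idx, "max_depth_m"] = prof.max_depth
            if ctd_profiles:
                rec.at[idx, "salinity_psu"] = match_ctd(
                    mid_time, depth, ctd_profiles, max_gap_h, "salinity"
                )
                if has_temp:
                    rec.at[idx, "temperature_C"] = match_ctd(
                        mid_time, depth, ctd_profiles, max_gap_h, "temperature"
                    )
    return rec.drop(columns="_row").reset_index(drop=True)


def _lookup_bathymetry(bathymetry, lon, lat, time):
    if bathymetry is None:
        return None
    if isinstance(bathymetry, BathymetryGrid):
        return bathymetry.at(lon, lat)
    if isinstance(bathymetry, pd.DataFrame):
        tt = pd.DatetimeIndex(
            pd.to_datetime(bathymetry["time"], utc=True, format="ISO8601")
        ).asi8
        i = int(np.argmin(np.abs(tt - pd.Timestamp(time).value)))
        return float(bathymetry["bathymetry_m"].iloc[i])
    return float(bathymetry)
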