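"""Synthetic behavioural sequences, dive profiles, CTD casts and bathymetry.

The generator emulates the statistical structure the analysis assumes: a
covariate-driven (or homogeneous) Markov chain over behavioural states with
mixed-family state-dependent distributions, broken-stick dive profiles with
fast transit and a slow hunting segment, time-indexed CTD casts with
depth-varying salinity, and bathymetry along the track.  Reference scenarios
carry state-dependent values representative of adult Weddell seal telemetry
from the southern Weddell Sea (six behavioural states for females including
a pelagic dive type, five for males).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import (
    HmmParams,
    beta_ab,
    coefs_from_matrix,
    gamma_shape_rate,
    persistence_matrix,
    stationary_distribution,
    transition_matrix_from_logits,
)
from .processing import CtdProfile, DiveProfile, iso_week, local_solar_time
from .spec import HmmSpec, spec_for_sex

#: long-run state-occupancy proportions used by the reference scenarios
FEMALE_OCCUPANCY = np.array([0.13, 0.21, 0.17, 0.24, 0.15, 0.09])
MALE_OCCUPANCY = np.array([0.13, 0.20, 0.31, 0.19, 0.17])


@dataclass
class GeneratingScenario:
    """Everything needed to simulate behavioural sequences.

    ``params`` carries the emission values and transition coefficients (use
    :func:`divehmm.params.coefs_from_matrix` with an intercept-only spec for
    a homogeneous chain).  Timestamps advance by each record's duration; the
    covariates of a record are evaluated at its start time.
    """

    spec: HmmSpec
    params: HmmParams
    start_time: pd.Timestamp = pd.Timestamp("2011-02-15T00:00:00Z")
    lon: float = -40.0
    lat: float = -75.0
    n_individuals: int = 1
    salinity_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time.tzinfo is None:
            self.start_time = self.start_time.tz_localize("UTC")
        self.validate()

    def validate(self) -> None:
        self.params.validate(self.spec)
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not 0.0 <= self.salinity_missing_rate < 1.0:
            raise ValueError("salinity_missing_rate must lie in [0, 1)")

    @classmethod
    def from_matrix(
        cls, spec_like, params: HmmParams, transition_matrix: np.ndarray, **kw
    ) -> "GeneratingScenario":
        """Scenario with a fixed homogeneous transition matrix.

        The spec is switched to an intercept-only covariate design and the
        matrix converted exactly to diagonal-reference logits.
        """
        spec = replace(spec_like, covariate_design="intercept")
        params = replace(params, tpm_coefs=coefs_from_matrix(transition_matrix))
        return cls(spec=spec, params=params, **kw)


def _reference_values(sex: str):
    """Per-state generating values for the two reference scenarios.

    Means follow published field estimates for southern Weddell Sea adults;
    spread parameters (sds, beta precisions) are representative choices at
    field-realistic scale, documented in the methods note.
    """
    if sex == "F":
        return dict(
            duration_mean=[2.8 * 3600, 37.9 * 60, 1.0 * 60, 7.4 * 60, 14.1 * 60, 19.0 * 60],
            duration_sd=[1.4 * 3600, 19.0 * 60, 0.4 * 60, 3.0 * 60, 4.2 * 60, 5.0 * 60],
            depth_mean=[8.8, 38.5, 193.8, 413.1],
            depth_sd=[3.0, 12.0, 35.0, 50.0],
            hunt_mean=[0.51, 0.55, 0.49, 0.43],
            hunt_precision=[30.0, 30.0, 30.0, 30.0],
            benthic_p=[0.005, 0.005, 0.005, 0.89],
            salinity_mean=[34.18, 34.29, 34.44, 34.61],
            salinity_sd=[0.04, 0.04, 0.04, 0.04],
            occupancy=FEMALE_OCCUPANCY,
        )
    return dict(
        duration_mean=[3.5 * 3600, 34.3 * 60, 2.3 * 60, 11.0 * 60, 18.2 * 60],
        duration_sd=[1.7 * 3600, 17.0 * 60, 0.9 * 60, 4.0 * 60, 5.0 * 60],
        depth_mean=[10.2, 90.0, 411.8],
        depth_sd=[3.5, 25.0, 50.0],
        hunt_mean=[0.53, 0.46, 0.42],
        hunt_precision=[30.0, 30.0, 30.0],
        benthic_p=[0.005, 0.005, 0.91],
        salinity_mean=[34.23, 34.36, 34.59],
        salinity_sd=[0.04, 0.04, 0.04],
        occupancy=MALE_OCCUPANCY,
    )


def reference_scenario(
    sex: str = "F", self_transition: float = 0.8, **kw
) -> GeneratingScenario:
    """Reference generating scenario for one sex, homogeneous transitions.

    The transition matrix has self-transition ``self_transition`` with the
    off-diagonal mass of each row spread proportionally to the long-run
    state-occupancy proportions.
    """
    sex = sex.upper()[:1]
    v = _reference_values(sex)
    occupancy = v.pop("occupancy")
    spec = spec_for_sex(sex, covariate_design="intercept")
    P = persistence_matrix(occupancy, self_transition)
    params = HmmParams(tpm_coefs=coefs_from_matrix(P), **v)
    return GeneratingScenario(spec=spec, params=params, **kw)


# ---------------------------------------------------------------------------
# behavioural sequences


def simulate_sequence(
    scenario: GeneratingScenario, n_records: int, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a behavioural sequence; returns (records, true_states).

    Records carry a type consistent with their state (haulout/surface states
    emit only a duration; dive states emit all five streams), timestamps
    advance by each record's duration, and covariates (local solar hour, ISO
    week) are evaluated at each record's start time.  With several
    individuals the records are split evenly and each sequence restarts at
    the scenario start time.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    scenario.validate()
    spec, params = scenario.spec, scenario.params
    rng = np.random.default_rng(seed)
    N = spec.n_states
    homogeneous = spec.covariate_design == "intercept"

    counts = [len(a) for a in np.array_split(np.arange(n_records), scenario.n_individuals)]
    frames = []
    states_all = []
    for ind, count in enumerate(counts):
        if homogeneous:
            states, starts = _simulate_chain_homogeneous(
                scenario, count, rng
            )
        else:
            states, starts = _simulate_chain_covariate(scenario, count, rng)
        frame = _emit_streams(states, starts, params, scenario, rng)
        frame["individual_id"] = f"ind{ind:02d}"
        frames.append(frame)
        states_all.append(states)
    records = pd.concat(frames, ignore_index=True)
    cols = [
        "individual_id", "record_type", "start_time", "duration_s",
        "hunting_depth_m", "prop_hunting", "benthic", "salinity_psu",
        "local_hour", "week_of_year", "lon", "lat",
    ]
    return records[cols], np.concatenate(states_all)


def _initial_delta(scenario, Gamma):
    spec, params = scenario.spec, scenario.params
    N = spec.n_states
    if spec.initial == "uniform":
        return np.full(N, 1.0 / N)
    if spec.initial == "estimated":
        z = np.concatenate([[0.0], params.init_logits])
        e = np.exp(z - z.max())
        return e / e.sum()
    return stationary_distribution(Gamma)


def _draw_durations(states, params, rng):
    k, r = gamma_shape_rate(params.duration_mean, params.duration_sd)
    return rng.gamma(k[states], 1.0 / r[states])


def _simulate_chain_homogeneous(scenario, count, rng):
    """State path and start times when transitions do not depend on time."""
    params, spec = scenario.params, scenario.spec
    N = spec.n_states
    Gamma = transition_matrix_from_logits(params.tpm_coefs[:, 0], N)
    cum = np.cumsum(Gamma, axis=1)
    states = np.empty(count, dtype=np.int64)
    u = rng.random(count)
    states[0] = int(rng.choice(N, p=_initial_delta(scenario, Gamma)))
    for t in range(1, count):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    durations = _draw_durations(states, params, rng)
    elapsed = np.concatenate([[0.0], np.cumsum(durations[:-1])])
    starts = scenario.start_time + pd.to_timedelta(elapsed, unit="s")
    return states, (starts, durations)


def _simulate_chain_covariate(scenario, count, rng):
    """Sequential simulation when transition probabilities vary in time.

    Durations must be drawn in step with the chain because each record's
    start time (hence its covariates) depends on the previous durations.
    """
    params, spec = scenario.params, scenario.spec
    N = spec.n_states
    kdur, rdur = gamma_shape_rate(params.duration_mean, params.duration_sd)
    t0 = scenario.start_time
    t_sec = 0.0
    utc_hour0 = t0.hour + t0.minute / 60.0 + t0.second / 3600.0
    day_cache = (-1, np.nan)
    states = np.empty(count, dtype=np.int64)
    elapsed = np.empty(count)
    state = -1
    for t in range(count):
        hour = (utc_hour0 + t_sec / 3600.0 + scenario.lon / 15.0) % 24.0
        day = int(t_sec // 86400)
        if day != day_cache[0]:
            week = float(iso_week([t0 + pd.Timedelta(seconds=t_sec)])[0])
            day_cache = (day, week)
        week = day_cache[1]
        eta = spec.design_row(hour, week) @ params.tpm_coefs.T
        Gamma = transition_matrix_from_logits(eta, N)
        if state < 0:
            state = int(rng.choice(N, p=_initial_delta(scenario, Gamma)))
        else:
            state = int(rng.choice(N, p=Gamma[state]))
        states[t] = state
        elapsed[t] = t_sec
        t_sec += rng.gamma(kdur[state], 1.0 / rdur[state])
    starts = t0 + pd.to_timedelta(elapsed, unit="s")
    # durations are the inter-start gaps used above
    durations = np.append(np.diff(elapsed), t_sec - elapsed[-1])
    return states, (starts, durations)


def _emit_streams(states, starts, params, scenario, rng):
    """Vectorised stream draws given the state path and start times."""
    starts, durations = starts
    rec = pd.DataFrame(
        {
            "record_type": np.where(
                states == 0, "haulout", np.where(states == 1, "surface", "dive")
            ),
            "start_time": starts,
            "duration_s": durations,
            "hunting_depth_m": np.nan,
            "prop_hunting": np.nan,
            "benthic": np.nan,
            "salinity_psu": np.nan,
        }
    )
    dive = states >= 2
    if dive.any():
        d = states[dive] - 2
        kz, rz = gamma_shape_rate(params.depth_mean, params.depth_sd)
        rec.loc[dive, "hunting_depth_m"] = rng.gamma(kz[d], 1.0 / rz[d])
        a, b = beta_ab(params.hunt_mean, params.hunt_precision)
        rec.loc[dive, "prop_hunting"] = rng.beta(a[d], b[d])
        rec.loc[dive, "benthic"] = (
            rng.random(d.size) < params.benthic_p[d]
        ).astype(float)
        sal = rng.normal(params.salinity_mean[d], params.salinity_sd[d])
        if scenario.salinity_missing_rate > 0:
            sal[rng.random(d.size) < scenario.salinity_missing_rate] = np.nan
        rec.loc[dive, "salinity_psu"] = sal
    rec["local_hour"] = local_solar_time(rec["start_time"], scenario.lon)
    rec["week_of_year"] = iso_week(rec["start_time"])
    rec["lon"] = scenario.lon
    rec["lat"] = scenario.lat
    return rec


def _emit_record(state, params, spec, rng, scenario) -> dict:
    k, r = gamma_shape_rate(params.duration_mean[state], params.duration_sd[state])
    dur = float(rng.gamma(k, 1.0 / r))
    if state < 2:
        rtype = ("haulout", "surface")[state]
        return dict(record_type=rtype, duration_s=dur, hunting_depth_m=np.nan,
                    prop_hunting=np.nan, benthic=np.nan, salinity_psu=np.nan)
    d = state - 2
    kz, rz = gamma_shape_rate(params.depth_mean[d], params.depth_sd[d])
    a, b = beta_ab(params.hunt_mean[d], params.hunt_precision[d])
    sal = rng.normal(params.salinity_mean[d], params.salinity_sd[d])
    if scenario.salinity_missing_rate > 0 and rng.random() < scenario.salinity_missing_rate:
        sal = np.nan
    return dict(
        record_type="dive",
        duration_s=dur,
        hunting_depth_m=float(rng.gamma(kz, 1.0 / rz)),
        prop_hunting=float(rng.beta(a, b)),
        benthic=float(rng.random() < params.benthic_p[d]),
        salinity_psu=sal,
    )


# ---------------------------------------------------------------------------
# dive profiles


def simulate_dive_profile(
    hunting_depth: float,
    total_duration: float,
    hunting_duration: float,
    max_depth: float,
    n_points: int = 6,
    seed: int | None = None,
    speed_threshold: float = 0.5,
    max_transit_speed: float = 4.0,
) -> DiveProfile:
    """Broken-stick profile with one slow hunting segment at depth.

    The profile descends to ``hunting_depth``, holds there (vertical speed 0)
    for exactly ``hunting_duration``, visits ``max_depth`` and returns to the
    surface.  Transit legs run at a common vertical speed above the hunting
    threshold; when the dive geometry leaves more transit time than a direct
    path needs, transit legs weave (sawtooth at 1 m/s) so that no transit
    interval drops below the threshold.  ``n_points`` is a minimum; extra
    points are inserted collinearly.
    """
    if not 0 < hunting_depth <= max_depth:
        raise ValueError("need 0 < hunting_depth <= max_depth")
    if not 0 <= hunting_duration < total_duration:
        raise ValueError("hunting_duration must lie in [0, total_duration)")
    if n_points < 4:
        raise ValueError("n_points must be >= 4")

    transit_time = total_duration - hunting_duration
    # leg net displacements: surface -> hold depth [-> max depth] -> surface
    legs: list[tuple[float, float]]  # (d_from, d_to)
    if hunting_duration > 0:
        if max_depth > hunting_depth:
            legs = [(0.0, hunting_depth), (hunting_depth, max_depth), (max_depth, 0.0)]
        else:
            legs = [(0.0, hunting_depth), (hunting_depth, 0.0)]
    else:
        legs = [(0.0, max_depth), (max_depth, 0.0)]
    dist = sum(abs(b - a) for a, b in legs)
    v_req = dist / transit_time
    if v_req > max_transit_speed:
        raise ValueError(
            f"infeasible dive geometry: required transit speed {v_req:.2f} m/s "
            f"exceeds the physical cap {max_transit_speed} m/s"
        )
    weave = v_req < 1.2 * speed_threshold
    v = 1.0 if weave else v_req

    pts: list[tuple[float, float]] = [(0.0, 0.0)]
    t = 0.0
    hold_inserted = hunting_duration <= 0
    for d0, d1 in legs:
        tau = transit_time * abs(d1 - d0) / dist
        if weave:
            seg = _weave_leg(d0, d1, tau, v, lo=0.0, hi=max_depth)
        else:
            seg = [(tau, d1)]
        for dt, dd in seg:
            t += dt
            pts.append((t, dd))
        if not hold_inserted and abs(d1 - hunting_depth) < 1e-9:
            t += hunting_duration
            pts.append((t, hunting_depth))
            hold_inserted = True
    # collinear refinement up to n_points
    pts_arr = [list(p) for p in pts]
    while len(pts_arr) < n_points:
        gaps = [pts_arr[i + 1][0] - pts_arr[i][0] for i in range(len(pts_arr) - 1)]
        i = int(np.argmax(gaps))
        tm = 0.5 * (pts_arr[i][0] + pts_arr[i + 1][0])
        dm = 0.5 * (pts_arr[i][1] + pts_arr[i + 1][1])
        pts_arr.insert(i + 1, [tm, dm])
    return DiveProfile(
        dive_id=None, points=np.array(pts_arr), duration_s=total_duration
    )


def _weave_leg(d0, d1, tau, v, lo, hi) -> list[tuple[float, float]]:
    """Sawtooth leg from d0 to d1 over time tau at constant speed v.

    Covers path length v*tau (> |d1-d0|) with bounces inside [lo, hi],
    keeping every interval's vertical speed equal to v.  Returns a list of
    (dt, depth) waypoints excluding the start point.
    """
    net = abs(d1 - d0)
    excess = v * tau - net
    if excess <= 1e-9 or net == 0:
        return [(tau, d1)]
    m = 0.5 * (d0 + d1)
    a_max = min(0.9 * 2.0 * min(m - lo, hi - m), net)
    if a_max <= 1e-6:
        return [(tau, d1)]  # degenerate band: fall back to a straight leg
    k = max(1, math.ceil(excess / (2.0 * a_max)))
    a = excess / (2.0 * k)
    sgn = 1.0 if d1 > d0 else -1.0
    base = m - sgn * a / 2.0
    out = [(abs(base - d0) / v, base)]
    for _ in range(k):
        out.append((a / v, base + sgn * a))
        out.append((a / v, base))
    out.append((abs(d1 - base) / v, d1))
    return [(dt, dd) for dt, dd in out if dt > 1e-12]


# ---------------------------------------------------------------------------
# CTD casts and bathymetry


def simulate_ctd_profiles(
    times,
    depth_grid,
    salinity_model,
    seed: int | None = None,
    noise_sd: float = 0.0,
    temperature_model=None,
) -> list[CtdProfile]:
    """CTD casts with salinity linear in depth at each cast time.

    ``salinity_model`` is one (intercept, slope_per_m) pair applied to every
    cast, or one pair per cast time.  ``temperature_model`` works the same
    way; when given, casts carry a temperature column.  Optional white noise
    with sd ``noise_sd`` psu is added to salinity.
    """
    times = [pd.Timestamp(t) for t in times]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("cast times must strictly increase")
    depth_grid = np.asarray(depth_grid, dtype=float)
    if np.any(np.diff(depth_grid) <= 0):
        raise ValueError("depth grid must strictly increase")
    sal_models = _per_time(salinity_model, len(times))
    temp_models = _per_time(temperature_model, len(times)) if temperature_model else None
    rng = np.random.default_rng(seed)
    profiles = []
    for i, t in enumerate(times):
        a, b = sal_models[i]
        sal = a + b * depth_grid
        if noise_sd > 0:
            sal = sal + rng.normal(0.0, noise_sd, size=depth_grid.size)
        cols = [depth_grid, sal]
        if temp_models is not None:
            ta, tb = temp_models[i]
            cols.append(ta + tb * depth_grid)
        profiles.append(CtdProfile(t, np.column_stack(cols)))
    return profiles


def _per_time(model, n):
    model = np.asarray(model, dtype=float)
    if model.ndim == 1:
        return [tuple(model)] * n
    if model.shape[0] != n:
        raise ValueError("need one (intercept, slope) pair per cast time")
    return [tuple(row) for row in model]


def synthetic_bathymetry(lon, lat) -> np.ndarray:
    """Smooth synthetic shelf bathymetry (m): deepens offshore with a trough."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    depth = (
        500.0
        + 2500.0 / (1.0 + np.exp(-(lat + 73.0) * 2.0))  # shelf break
        + 600.0 * np.exp(-((lon + 40.0) ** 2) / 8.0)  # trough at 40W
    )
    return depth if depth.ndim else float(depth)


# ---------------------------------------------------------------------------
# dataset writer (CSV surface for the prepare stage)


def write_dataset(scenario, records, states, out_dir, seed: int = 0) -> dict:
    """Write a simulated sequence as SMRU-style CSV tables.

    Produces behaviour/haulout/surface/dive tables, a CTD table, a track, a
    per-dive bathymetry lookup and the truth states, constructed so that the
    prepare stage recovers the simulated streams: each dive gets a
    broken-stick profile whose hunting segment matches its simulated
    proportion and depth, the CTD field reproduces the simulated salinities
    at hunting depth, and bathymetry is set from the simulated contact
    indicator.  Returns the paths written.  The records table written to
    ``records.csv`` carries the environment-consistent streams.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = records.copy().reset_index(drop=True)
    benthic_fraction = 0.97

    dive_rows = rec[rec["record_type"] == "dive"]
    n_dives = len(dive_rows)
    dives, ctd_rows, bathy_rows = [], [], []
    max_pts = 0
    for i, (idx, row) in enumerate(dive_rows.iterrows()):
        dur = float(row["duration_s"])
        h = float(row["hunting_depth_m"])
        # invert the prepare-stage squeeze so the round trip is exact
        hd = min((float(row["prop_hunting"]) * n_dives - 0.5) / (n_dives - 1), 1.0) * dur
        hd = min(max(hd, 0.0), dur * 0.9)
        maxd = h * 1.02
        # keep the implied transit speed physical for extreme draws
        dist = 2.0 * maxd + (maxd - h)
        hd = min(hd, max(dur - dist / 3.5, 0.0))
        prof = simulate_dive_profile(h, dur, hd, maxd, n_points=4)
        pts = prof.points
        max_pts = max(max_pts, len(pts))
        d = {
            "individual_id": row["individual_id"],
            "start_time": row["start_time"],
            "duration_s": dur,
            "dive_id": i,
        }
        for k, (te, de) in enumerate(pts, start=1):
            d[f"point_elapsed_s_{k}"] = te
            d[f"point_depth_m_{k}"] = de
        dives.append(d)
        if bool(row["benthic"]):
            bathy = h / benthic_fraction * 0.999
        else:
            bathy = max(3.0 * maxd, 3000.0)
        bathy_rows.append({"time": row["start_time"], "bathymetry_m": bathy})

    dive_table = pd.DataFrame(dives)
    haulout_table = rec.loc[
        rec["record_type"] == "haulout",
        ["individual_id", "start_time", "duration_s"],
    ]
    surface_table = rec.loc[
        rec["record_type"] == "surface",
        ["individual_id", "start_time", "duration_s"],
    ]

    # CTD casts: one cast at each dive's midpoint, constant-in-depth salinity
    # equal to the simulated value, so depth+time interpolation returns it.
    depth_grid = [5.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0]
    for _, row in dive_rows.iterrows():
        if not np.isfinite(row["salinity_psu"]):
            continue
        mid = row["start_time"] + pd.Timedelta(seconds=row["duration_s"] / 2.0)
        for z in depth_grid:
            ctd_rows.append(
                {"profile_time": mid, "depth_m": z,
                 "salinity_psu": row["salinity_psu"], "temperature_C": -1.8}
            )
    ctd_table = pd.DataFrame(ctd_rows)

    t0, t1 = rec["start_time"].min(), rec["start_time"].max()
    track = pd.DataFrame(
        {
            "individual_id": rec["individual_id"].iloc[0],
            "time": [t0, t1],
            "lon": [scenario.lon, scenario.lon],
            "lat": [scenario.lat, scenario.lat],
        }
    )
    truth = pd.DataFrame({"state": states})

    paths = {}
    for name, df in (
        ("records", rec),
        ("dives", dive_table),
        ("haulout", haulout_table),
        ("surface", surface_table),
        ("ctd", ctd_table),
        ("track", track),
        ("bathymetry", pd.DataFrame(bathy_rows)),
        ("truth_states", truth),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
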