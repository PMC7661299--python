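"""Hunting-segment extraction, CTD matching, covariates and assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import divehmm as dh
from divehmm.processing import (
    BathymetryGrid,
    CtdProfile,
    DiveProfile,
    assemble_records,
    derive_dive_streams,
    extract_hunting_segments,
    local_solar_time,
    match_ctd,
    squeeze_proportion,
)


def profile(points, dive_id="d"):
    return DiveProfile(dive_id=dive_id, points=np.array(points, dtype=float))


class TestHuntingSegments:
    def test_hand_worked_profile(self):
        # interval speeds: 2.0, 0.017, 2.05 m/s -> one hunting segment
        p = profile([(0, 0), (200, 400), (800, 410), (1000, 0)])
        segs, htime, hdepth = extract_hunting_segments(p)
        assert segs == [(200.0, 800.0, 405.0)]
        assert htime == 600.0
        assert hdepth == 405.0

    def test_v_shape_has_no_hunting(self):
        p = profile([(0, 0), (300, 450), (600, 0)])
        segs, htime, hdepth = extract_hunting_segments(p)
        assert segs == [] and htime == 0.0
        # fallback depth: slowest interval's mean depth (both at 1.5 m/s)
        assert hdepth == 225.0

    def test_exact_threshold_counts_as_transit(self):
        p = profile([(0, 0), (100, 50), (200, 100), (300, 0)])
        # middle interval speed exactly 0.5: strict < means transit
        segs, htime, _ = extract_hunting_segments(p)
        assert htime == 0.0 and segs == []

    def test_two_segments_longest_wins(self):
        p = profile(
            [(0, 0), (100, 200), (200, 210), (250, 300), (550, 310), (700, 0)]
        )
        segs, htime, hdepth = extract_hunting_segments(p)
        assert len(segs) == 2
        assert htime == pytest.approx(100.0 + 300.0)
        assert hdepth == pytest.approx(305.0)  # longest (300 s) segment

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValueError, match="strictly increase"):
            profile([(0, 0), (0, 10), (100, 0)])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_collinear_points_do_not_change_metrics(self, seed):
        rng = np.random.default_rng(seed)
        p = dh.simulate_dive_profile(
            float(rng.uniform(50, 400)), 1200.0, float(rng.uniform(100, 800)),
            float(rng.uniform(400, 450)),
        )
        _, htime, hdepth = extract_hunting_segments(p)
        pts = p.points
        # insert a collinear midpoint into every interval
        mids = 0.5 * (pts[:-1] + pts[1:])
        refined = np.empty((len(pts) + len(mids), 2))
        refined[0::2] = pts
        refined[1::2] = mids
        p2 = DiveProfile(dive_id="r", points=refined, duration_s=p.duration_s)
        _, htime2, hdepth2 = extract_hunting_segments(p2)
        assert htime2 == pytest.approx(htime, abs=1e-9)
        assert hdepth2 == pytest.approx(hdepth, abs=1e-9)


class TestDiveStreams:
    def test_squeeze_formula(self):
        assert squeeze_proportion(0.6, 1000) == pytest.approx(0.5999)
        assert 0.0 < squeeze_proportion(0.0, 50) < squeeze_proportion(1.0, 50) < 1.0

    def test_benthic_indicator_thresholds(self):
        p = dh.simulate_dive_profile(405.0, 1200.0, 600.0, 410.0)
        hdepth, prop, benthic = derive_dive_streams(p, 410.0, n_dives=100)
        assert benthic == 1  # 405/410 = 0.988 >= 0.97
        _, _, benthic = derive_dive_streams(p, 3000.0, n_dives=100)
        assert benthic == 0
        _, _, benthic = derive_dive_streams(p, None, n_dives=100)
        assert benthic is None

    def test_ratio_clamped_when_grid_errs(self):
        # hunting depth deeper than the (erroneous) bathymetry still gives 1
        p = dh.simulate_dive_profile(405.0, 1200.0, 600.0, 410.0)
        _, _, benthic = derive_dive_streams(p, 350.0, n_dives=100)
        assert benthic == 1

    def test_prop_strictly_inside_unit_interval(self):
        p = dh.simulate_dive_profile(100.0, 600.0, 0.0, 120.0)
        _, prop, _ = derive_dive_streams(p, 500.0, n_dives=10)
        assert 0.0 < prop < 1.0


class TestMatchCtd:
    def make_profiles(self):
        return [
            CtdProfile("2011-03-01T00:00Z", [[10, 34.30], [400, 34.40]]),
            CtdProfile("2011-03-01T06:00Z", [[10, 34.36], [400, 34.46]]),
        ]

    def test_exact_time_and_level(self):
        profiles = self.make_profiles()
        assert match_ctd("2011-03-01T00:00Z", 10.0, profiles) == pytest.approx(34.30)

    def test_equal_distance_midpoint(self):
        profiles = self.make_profiles()
        assert match_ctd("2011-03-01T03:00Z", 10.0, profiles) == pytest.approx(34.33)

    def test_two_stage_hand_value(self):
        # vertical values 34.30 and 34.36 at 10 m; dive 2 h into a 6 h gap
        profiles = self.make_profiles()
        assert match_ctd("2011-03-01T02:00Z", 10.0, profiles) == pytest.approx(34.32)

    def test_missing_outside_gap_window(self):
        profiles = self.make_profiles()
        assert np.isnan(match_ctd("2011-03-05T00:00Z", 10.0, profiles, max_gap_h=24))

    def test_single_bracket_uses_nearest_cast(self):
        profiles = self.make_profiles()
        val = match_ctd("2011-02-28T20:00Z", 10.0, profiles, max_gap_h=24)
        assert val == pytest.approx(34.30)

    def test_deep_extrapolation_uses_nearest_level(self, caplog):
        profiles = self.make_profiles()
        with caplog.at_level("WARNING"):
            val = match_ctd("2011-03-01T00:00Z", 800.0, profiles)
        assert val == pytest.approx(34.40)
        assert "deepest" in caplog.text


class TestSolarTime:
    @pytest.mark.parametrize(
        "utc, lon, expected",
        [
            ("2011-03-01T12:00Z", 0.0, 12.0),
            ("2011-03-01T12:00Z", -45.0, 9.0),
            ("2011-03-01T01:00Z", -60.0, 21.0),
            ("2011-03-01T23:30Z", 30.0, 1.5),
        ],
    )
    def test_examples(self, utc, lon, expected):
        assert local_solar_time(utc, lon) == pytest.approx(expected)

    def test_bad_longitude(self):
        with pytest.raises(ValueError):
            local_solar_time("2011-03-01T00:00Z", 200.0)


class TestBathymetryGrid:
    def test_bilinear_interpolation(self):
        grid = BathymetryGrid(
            np.array([0.0, 1.0]), np.array([0.0, 1.0]),
            np.array([[100.0, 200.0], [300.0, 400.0]]),
        )
        assert grid.at(0.5, 0.5) == pytest.approx(250.0)
        assert grid.at(-5.0, 0.0) == pytest.approx(100.0)  # clamped

    def test_csv_round_trip(self, tmp_path):
        rows = [
            {"lon": lo, "lat": la, "bathymetry_m": 100 + 10 * lo + la}
            for lo in (0.0, 1.0, 2.0)
            for la in (0.0, 1.0)
        ]
        path = tmp_path / "bathy.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        grid = BathymetryGrid.from_csv(path)
        assert grid.at(1.0, 1.0) == pytest.approx(111.0)


class TestAssembleRecords:
    def test_round_trip_recovers_simulated_streams(self, tmp_path, female_scenario):
        from divehmm.simulate import write_dataset

        rec, states = dh.simulate_sequence(female_scenario, 250, seed=7)
        paths = write_dataset(female_scenario, rec, states, tmp_path)
        out = assemble_records(
            dive_table=pd.read_csv(paths["dives"]),
            haulout_table=pd.read_csv(paths["haulout"]),
            surface_table=pd.read_csv(paths["surface"]),
            ctd_table=pd.read_csv(paths["ctd"]),
            track=pd.read_csv(paths["track"]),
            bathymetry=pd.read_csv(paths["bathymetry"]),
            cutoff=None,
        )
        assert len(out) == len(rec)
        sim = rec[rec.record_type == "dive"].reset_index(drop=True)
        got = out[out.record_type == "dive"].reset_index(drop=True)
        np.testing.assert_allclose(got.hunting_depth_m, sim.hunting_depth_m, atol=1e-9)
        np.testing.assert_allclose(got.salinity_psu, sim.salinity_psu, atol=1e-9)
        np.testing.assert_allclose(got.prop_hunting, sim.prop_hunting, atol=0.01)
        assert (got.benthic == sim.benthic).all()
        np.testing.assert_allclose(got.local_hour, sim.local_hour, atol=1e-9)

    def test_cutoff_drops_late_records(self):
        dive = pd.DataFrame(
            {
                "individual_id": ["a", "a"],
                "start_time": ["2011-06-10T00:00Z", "2011-06-25T00:00Z"],
                "duration_s": [600.0, 600.0],
                "point_elapsed_s_1": [100.0, 100.0],
                "point_depth_m_1": [200.0, 200.0],
                "point_elapsed_s_2": [500.0, 500.0],
                "point_depth_m_2": [210.0, 210.0],
            }
        )
        out = assemble_records(dive, cutoff="2011-06-19")
        assert len(out) == 1
        assert out["start_time"].iloc[0] < pd.Timestamp("2011-06-19", tz="UTC")

    def test_interleaved_individuals_are_grouped(self):
        dive = pd.DataFrame(
            {
                "individual_id": ["b", "a", "b", "a"],
                "start_time": [
                    "2011-03-01T00:00Z", "2011-03-01T00:00Z",
                    "2011-03-01T01:00Z", "2011-03-01T01:00Z",
                ],
                "duration_s": [600.0] * 4,
                "point_elapsed_s_1": [100.0] * 4,
                "point_depth_m_1": [200.0] * 4,
                "point_elapsed_s_2": [500.0] * 4,
                "point_depth_m_2": [210.0] * 4,
            }
        )
        out = assemble_records(dive, cutoff=None)
        assert list(out["individual_id"]) == ["a", "a", "b", "b"]
        assert out.groupby("individual_id")["start_time"].is_monotonic_increasing.all()

    def test_overlapping_records_keep_first(self, caplog):
        haulout = pd.DataFrame(
            {
                "individual_id": ["a", "a"],
                "start_time": ["2011-03-01T00:00Z", "2011-03-01T00:30Z"],
                "duration_s": [7200.0, 600.0],
            }
        )
        dive = pd.DataFrame(
            {
                "individual_id": ["a"],
                "start_time": ["2011-03-01T06:00Z"],
                "duration_s": [600.0],
                "point_elapsed_s_1": [100.0],
                "point_depth_m_1": [200.0],
                "point_elapsed_s_2": [500.0],
                "point_depth_m_2": [210.0],
            }
        )
        with caplog.at_level("WARNING"):
            out = assemble_records(dive, haulout_table=haulout, cutoff=None)
        assert len(out) == 2
        assert "overlapping" in caplog.text
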