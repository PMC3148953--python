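import numpy as np
import pandas as pd
import pytest

from lagclust.histories import (
    DataIntegrityError,
    apply_inclusion_filters,
    build_lagged_points,
    project_lonlat,
    read_boundary,
    select_lag_residence,
    write_boundary,
)


def _subject(sid="s1", ref=2000, case=1):
    return pd.DataFrame({
        "subject_id": [sid], "case": [case], "center": ["c1"],
        "reference_year": [ref], "age": [60], "sex": ["male"], "race": ["white"],
        "education": ["b_highschool"], "termite_pre1988": [False],
    })


def _residence(sid, a, b, match="exact", in_area=True, x=1.0, y=1.0):
    return {"subject_id": sid, "move_in_year": a, "move_out_year": b,
            "x": x, "y": y, "match_level": match, "in_area": in_area}


class TestLagSelection:
    def test_lag_20_selects_earlier_home(self, simple_residences):
        r = select_lag_residence(simple_residences, 2000, 20)  # target 1980
        assert r["move_in_year"] == 1975

    def test_lag_0_selects_current_home(self, simple_residences):
        r = select_lag_residence(simple_residences, 2000, 0)  # target 2000
        assert r["move_in_year"] == 1985

    def test_boundary_year_goes_to_later_move_in(self, simple_residences):
        r = select_lag_residence(simple_residences, 2000, 15)  # target 1985
        assert r["move_in_year"] == 1985  # the home moved to that year

    def test_overlapping_summer_home_longest_duration_wins(self):
        res = pd.DataFrame([_residence("s1", 1980, 2000), _residence("s1", 1998, 2000)])
        r = select_lag_residence(res, 2000, 1)  # target 1999, both claim
        assert r["move_in_year"] == 1980  # primary residence: longest duration

    def test_exact_duplicate_claim_is_integrity_failure(self):
        res = pd.DataFrame([_residence("s1", 1990, 2000, x=1.0),
                            _residence("s1", 1990, 2000, x=9.0)])
        with pytest.raises(DataIntegrityError):
            select_lag_residence(res, 2000, 5)

    def test_no_claim_returns_none(self):
        res = pd.DataFrame([_residence("s1", 1990, 2000)])
        assert select_lag_residence(res, 2000, 20) is None


class TestInclusionFilters:
    def _study(self):
        subs = pd.concat([_subject("good"), _subject("gap"), _subject("badgeo")],
                         ignore_index=True)
        res = pd.DataFrame([
            _residence("good", 1980, 1995), _residence("good", 1995, 2000),
            # 3-year hole 1988-1990 inside the 20-year window
            _residence("gap", 1980, 1987), _residence("gap", 1991, 2000),
            # 20-year coverage but one segment geocoded to a county centroid
            _residence("badgeo", 1980, 1990, match="county_centroid"),
            _residence("badgeo", 1990, 2000),
        ])
        return subs, res

    def test_filters_apply_rules_and_conserve_counts(self):
        subs, res = self._study()
        s, r, rep = apply_inclusion_filters(subs, res, window_years=20)
        assert list(s["subject_id"]) == ["good"]
        assert rep.residences_removed["excluded_match_level"] == 1
        assert rep.n_subjects_retained + rep.n_subjects_removed_incomplete_coverage \
            == rep.n_subjects_in
        # badgeo loses coverage once its county-centroid segment is dropped
        assert "badgeo" not in set(s["subject_id"])

    def test_zip_centroid_retained(self):
        subs = _subject("s1")
        res = pd.DataFrame([_residence("s1", 1980, 2000, match="zip_centroid")])
        s, r, rep = apply_inclusion_filters(subs, res, window_years=20)
        assert len(s) == 1 and len(r) == 1

    @pytest.mark.parametrize("level", ["place", "county_centroid", "state_centroid"])
    def test_coarse_match_levels_excluded(self, level):
        subs = _subject("s1")
        res = pd.DataFrame([_residence("s1", 1980, 2000, match=level)])
        s, _, rep = apply_inclusion_filters(subs, res, window_years=20)
        assert len(s) == 0
        assert rep.residences_removed["excluded_match_level"] == 1

    def test_missing_match_level_rejected_with_reason(self):
        subs = _subject("s1")
        res = pd.DataFrame([_residence("s1", 1980, 2000, match=None)])
        s, _, rep = apply_inclusion_filters(subs, res, window_years=20)
        assert len(s) == 0
        assert rep.residences_removed["missing_match_level"] == 1

    def test_idempotent(self):
        subs, res = self._study()
        s1, r1, _ = apply_inclusion_filters(subs, res, window_years=20)
        s2, r2, rep2 = apply_inclusion_filters(s1, r1, window_years=20)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(r1, r2)
        assert rep2.n_subjects_removed_incomplete_coverage == 0

    def test_boundary_polygon_with_buffer(self, tmp_path):
        from shapely.geometry import box

        poly = box(0.0, 0.0, 10.0, 10.0)
        path = tmp_path / "boundary.geojson"
        write_boundary(poly, path)
        poly2 = read_boundary(path)
        subs = pd.concat([_subject("in"), _subject("near"), _subject("far")],
                         ignore_index=True)
        res = pd.DataFrame([
            _residence("in", 1980, 2000, x=5.0, y=5.0),
            _residence("near", 1980, 2000, x=11.0, y=5.0),   # within 2-unit buffer
            _residence("far", 1980, 2000, x=20.0, y=5.0),
        ])
        s, _, rep = apply_inclusion_filters(subs, res, buffer_distance=2.0,
                                            window_years=20, boundary=poly2)
        assert set(s["subject_id"]) == {"in", "near"}
        assert rep.residences_removed["outside_area"] == 1


class TestLaggedPointSet:
    def test_lag0_equals_reference_residence_and_uniqueness(self, tiny_study):
        _, subjects, residences = tiny_study
        pts = build_lagged_points(subjects, residences, 0)
        assert pts["subject_id"].is_unique
        assert len(pts) == len(subjects)
        # lag-0 location is the residence whose interval contains the reference year
        row = pts.iloc[0]
        g = residences[residences["subject_id"] == row["subject_id"]]
        expected = select_lag_residence(g, row["reference_year"], 0)
        assert row["x"] == expected["x"] and row["y"] == expected["y"]

    def test_counts_conserved_when_filters_bypassed(self):
        subs = pd.concat([_subject("s1"), _subject("s2")], ignore_index=True)
        res = pd.DataFrame([_residence("s1", 1980, 2000)])  # s2 has no residence
        pts = build_lagged_points(subs, res, 0)
        assert len(pts) == 1
        assert pts.attrs["n_missing"] == 1


def test_project_lonlat_scale():
    x, y = project_lonlat(-122.0, 47.0, origin_lon=-122.0, origin_lat=47.0)
    assert x == 0.0 and y == 0.0
    _, y1 = project_lonlat(-122.0, 48.0, origin_lon=-122.0, origin_lat=47.0)
    assert y1 == pytest.approx(111.2, abs=0.5)  # one degree of latitude in km
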