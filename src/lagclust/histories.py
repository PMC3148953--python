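"""Subject / residential-history data model, inclusion filters, lag selection.

Subjects carry case status, study center, a reference year (diagnosis date for
cases, a similar reference date for controls) and the adjustment covariates.
Residences carry move-in/move-out calendar years, planar coordinates and a
geocoding match level.  The analysis retains subjects whose usable residences
(match level exact / intersection / ZIP centroid) continuously cover the study
window inside the study area plus a boundary buffer, and represents each
retained subject by one residence per lag: the home occupied ``lag`` years
before the reference year.

All decisions operate on whole calendar years — sub-annual gaps are invisible
at the data's resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MATCH_LEVELS",
    "RETAINED_MATCH_LEVELS",
    "EXCLUDED_MATCH_LEVELS",
    "FilterReport",
    "DataIntegrityError",
    "apply_inclusion_filters",
    "select_lag_residence",
    "build_lagged_points",
    "read_subjects",
    "read_residences",
    "write_subjects",
    "write_residences",
    "read_boundary",
    "write_boundary",
    "project_lonlat",
]

MATCH_LEVELS = (
    "exact",
    "intersection",
    "zip_centroid",
    "place",
    "county_centroid",
    "state_centroid",
)
#: match levels whose coordinates are precise enough for the spatial analysis
RETAINED_MATCH_LEVELS = frozenset({"exact", "intersection", "zip_centroid"})
EXCLUDED_MATCH_LEVELS = frozenset({"place", "county_centroid", "state_centroid"})

SUBJECT_COLUMNS = ["subject_id", "case", "center", "reference_year",
                   "age", "sex", "race", "education", "termite_pre1988"]
RESIDENCE_COLUMNS = ["subject_id", "move_in_year", "move_out_year",
                     "x", "y", "match_level", "in_area"]


class DataIntegrityError(ValueError):
    """Two residences claim the same lag year even after tie-breaking."""


@dataclass
class FilterReport:
    """Machine-readable accounting of the inclusion filters.

    Counts are conserved: retained subjects + subjects removed for incomplete
    coverage = input subjects; likewise for residences.
    """

    n_subjects_in: int = 0
    n_residences_in: int = 0
    residences_removed: dict = field(default_factory=dict)
    n_subjects_removed_incomplete_coverage: int = 0
    n_subjects_retained: int = 0
    n_residences_retained: int = 0
    buffer_distance: float = 0.0
    window_years: int = 20

    def to_dict(self) -> dict:
        return {
            "n_subjects_in": self.n_subjects_in,
            "n_residences_in": self.n_residences_in,
            "residences_removed": dict(self.residences_removed),
            "n_subjects_removed_incomplete_coverage": self.n_subjects_removed_incomplete_coverage,
            "n_subjects_retained": self.n_subjects_retained,
            "n_residences_retained": self.n_residences_retained,
            "buffer_distance": self.buffer_distance,
            "window_years": self.window_years,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# I/O


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subjects file missing columns: {sorted(missing)}")
    return df


def read_residences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"residences file missing columns: {sorted(missing)}")
    return df


def write_subjects(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_residences(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_boundary(path):
    """Read a study-area boundary polygon from a GeoJSON file."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
        from shapely.ops import unary_union

        return unary_union(geoms)
    if gj.get("type") == "Feature":
        return shape(gj["geometry"])
    return shape(gj)


def write_boundary(geom, path) -> None:
    from shapely.geometry import mapping

    with open(path, "w") as fh:
        json.dump({"type": "Feature", "properties": {}, "geometry": mapping(geom)},
                  fh, sort_keys=True)


def project_lonlat(lon, lat, origin_lon: float, origin_lat: float,
                   radius_km: float = 6371.0088):
    """Project longitude/latitude to planar kilometres about a local origin.

    Azimuthal-equidistant small-area approximation on a sphere: adequate for
    study areas a few hundred kilometres across.  The statistical core only
    ever consumes the resulting planar coordinates (loess distances must be
    Euclidean).
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    lon0, lat0 = np.radians(origin_lon), np.radians(origin_lat)
    x = radius_km * (lon - lon0) * np.cos(0.5 * (lat + lat0))
    y = radius_km * (lat - lat0)
    return x, y


# ---------------------------------------------------------------------------
# Inclusion filters


def apply_inclusion_filters(subjects: pd.DataFrame, residences: pd.DataFrame,
                            buffer_distance: float = 0.0, window_years: int = 20,
                            boundary=None):
    """Apply the analysis inclusion filters.

    Residence-level: drop records with missing match level, records matched
    only to a populated place / county centroid / state centroid, and records
    outside the study area plus ``buffer_distance`` (evaluated against
    ``boundary`` when given, else the ``in_area`` flag).  Subject-level: keep
    subjects whose remaining residences continuously cover the whole-calendar-
    year window ``[reference_year - window_years, reference_year]``.

    Returns ``(subjects_retained, residences_retained, FilterReport)``.
    Filtering is idempotent.
    """
    report = FilterReport(
        n_subjects_in=len(subjects),
        n_residences_in=len(residences),
        buffer_distance=float(buffer_distance),
        window_years=int(window_years),
    )
    res = residences.copy()

    missing = res["match_level"].isna() | ~res["match_level"].isin(MATCH_LEVELS)
    report.residences_removed["missing_match_level"] = int(missing.sum())
    res = res[~missing]

    bad_level = res["match_level"].isin(EXCLUDED_MATCH_LEVELS)
    report.residences_removed["excluded_match_level"] = int(bad_level.sum())
    res = res[~bad_level]

    if boundary is not None:
        from shapely import contains_xy

        buffered = boundary.buffer(buffer_distance) if buffer_distance else boundary
        inside = contains_xy(buffered, res["x"].to_numpy(float), res["y"].to_numpy(float))
        inside = pd.Series(inside, index=res.index)
    else:
        inside = res["in_area"].astype(bool)
    report.residences_removed["outside_area"] = int((~inside).sum())
    res = res[inside]

    bad_coords = ~(np.isfinite(res["x"].to_numpy(float)) & np.isfinite(res["y"].to_numpy(float)))
    report.residences_removed["nonfinite_coordinates"] = int(bad_coords.sum())
    res = res[~bad_coords]

    # subject-level: continuous whole-year coverage of the study window
    ref = subjects.set_index("subject_id")["reference_year"]
    covered = _covers_window(res, ref, window_years)
    keep_ids = covered[covered].index
    subjects_out = subjects[subjects["subject_id"].isin(keep_ids)].reset_index(drop=True)
    res_out = res[res["subject_id"].isin(keep_ids)].reset_index(drop=True)
    report.n_subjects_removed_incomplete_coverage = len(subjects) - len(subjects_out)
    report.n_subjects_retained = len(subjects_out)
    report.n_residences_retained = len(res_out)
    return subjects_out, res_out, report


def _covers_window(res: pd.DataFrame, reference_year: pd.Series, window_years: int) -> pd.Series:
    """True per subject iff residence intervals cover every calendar year of
    [reference - window, reference] with no gaps."""
    out = {}
    grouped = dict(tuple(res.groupby("subject_id")))
    for sid, ref in reference_year.items():
        g = grouped.get(sid)
        if g is None:
            out[sid] = False
            continue
        start, end = int(ref) - int(window_years), int(ref)
        ivals = sorted(zip(g["move_in_year"].astype(int), g["move_out_year"].astype(int)))
        cover = start
        for a, b in ivals:
            if a > cover:
                break
            cover = max(cover, b + 1)  # year b is covered; next needed year b+1
            if cover > end:
                break
        out[sid] = cover > end
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Lag-residence selection


def _rank_candidates(g: pd.DataFrame, target: int) -> pd.DataFrame:
    """Order candidate residences claiming the target year by the documented
    tie rules: at an abutting move boundary the later move-in wins (the home
    moved *to* that year); among properly overlapping residences (temporary or
    summer homes) the primary residence — longest duration — wins, then later
    move-in."""
    dur = g["move_out_year"].astype(int) - g["move_in_year"].astype(int)
    boundary_movein = (g["move_in_year"].astype(int) == target).astype(int)
    order = pd.DataFrame({
        "_boundary": boundary_movein,
        "_dur": dur,
        "_movein": g["move_in_year"].astype(int),
    }, index=g.index)
    idx = order.sort_values(["_boundary", "_dur", "_movein"],
                            ascending=[False, False, False], kind="mergesort").index
    ranked = g.loc[idx]
    if len(ranked) >= 2:
        a, b = idx[0], idx[1]
        if (order.loc[a] == order.loc[b]).all():
            raise DataIntegrityError(
                f"subject {g['subject_id'].iloc[0]}: two residences claim year "
                f"{target} and tie on every tie-break key"
            )
    return ranked


def select_lag_residence(residences: pd.DataFrame, reference_year: int, lag_years: int):
    """The residence occupied ``lag_years`` before the reference year.

    Returns the residence row (pd.Series) or None if no interval contains the
    target year (only possible when the inclusion filters were bypassed).
    """
    target = int(reference_year) - int(lag_years)
    cand = residences[(residences["move_in_year"].astype(int) <= target)
                      & (residences["move_out_year"].astype(int) >= target)]
    if cand.empty:
        return None
    if len(cand) == 1:
        return cand.iloc[0]
    return _rank_candidates(cand, target).iloc[0]


def build_lagged_points(subjects: pd.DataFrame, residences: pd.DataFrame,
                        lag_years: int) -> pd.DataFrame:
    """One planar location per subject at the given lag (the LaggedPointSet).

    Every subject appears at most once; subjects without a residence at the
    target year (filters bypassed) are dropped with a count in the result's
    ``attrs['n_missing']``.
    """
    rows = []
    missing = 0
    res_by_subject = dict(tuple(residences.groupby("subject_id")))
    for _, subj in subjects.iterrows():
        g = res_by_subject.get(subj["subject_id"])
        if g is None:
            missing += 1
            continue
        r = select_lag_residence(g, subj["reference_year"], lag_years)
        if r is None:
            missing += 1
            continue
        row = subj.to_dict()
        row["x"] = float(r["x"])
        row["y"] = float(r["y"])
        row["lag_years"] = int(lag_years)
        rows.append(row)
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.attrs["n_missing"] = missing
    out.attrs["lag_years"] = int(lag_years)
    return out
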