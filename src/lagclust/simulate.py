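"""Seeded synthetic case-control studies with residential mobility.

The generator emulates the statistical structure the analysis assumes: a
multi-center case-control study with frequency-matched controls, 20-year
residential histories with a handful of moves per subject (median two
addresses), geocoding match-level labels, five adjustment covariates, and a
known spatially localized log-odds elevation (a sum of Gaussian bumps) that
acts on the residence occupied at a configurable lag before the reference
year.

Mechanics: a pool of ``n_cases + n_controls`` subjects is drawn from the
population model and labelled case/non-case with probability
``logistic(baseline + covariate effects + surface(lag residence))``, the
baseline chosen so the expected case fraction equals
``n_cases / (n_cases + n_controls)``.  The realized cases define the study's
case series.  Controls are then frequency-matched to the realized case margins
on the matching strata (largest-remainder apportionment of the requested
control count): per stratum, candidate subjects are drawn with the stratum
variables fixed and accepted with probability ``1 - p`` — population members
verified disease-free — so case/control spatial density ratios reproduce the
generating odds surface exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "GaussianBump",
    "TrueSurface",
    "CovariateEffects",
    "ScenarioConfig",
    "MatchingError",
    "evaluate_true_surface",
    "generate_study",
    "largest_remainder",
]

DEFAULT_CENTERS = ("detroit", "iowa", "los_angeles", "seattle")
#: rough geocoding match-level proportions: 8.8% intersections, 5% ZIP
#: centroids, the remainder split between exact matches and the excluded
#: place/county/state centroid levels
DEFAULT_MATCH_LEVEL_PROBS = {
    "exact": 0.80,
    "intersection": 0.088,
    "zip_centroid": 0.05,
    "place": 0.040,
    "county_centroid": 0.015,
    "state_centroid": 0.007,
}
#: residences-per-subject distribution with median 2
DEFAULT_MOBILITY = {1: 0.25, 2: 0.50, 3: 0.25}

_EDUCATION_LEVELS = ("a_lt_highschool", "b_highschool", "c_college")
_EDUCATION_PROBS = (0.20, 0.45, 0.35)
AGE_MIN, AGE_MAX = 20, 74


class MatchingError(ValueError):
    """Requested control count cannot be met in a matching stratum."""


@dataclass(frozen=True)
class GaussianBump:
    """Radially decaying log-odds elevation: amp * exp(-d^2 / (2 r^2))."""

    x: float
    y: float
    radius: float
    amplitude: float

    def __post_init__(self):
        if not (self.radius > 0):
            raise ValueError("bump radius must be > 0")
        if not np.isfinite(self.amplitude):
            raise ValueError("bump amplitude must be finite")


@dataclass(frozen=True)
class TrueSurface:
    """Known spatial log-odds offset: sum of Gaussian bumps.

    Zero far from all bump centers; the offset at a bump center equals its
    amplitude (for non-overlapping bumps).
    """

    bumps: tuple[GaussianBump, ...] = ()

    def evaluate(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        z = np.zeros(len(pts))
        for b in self.bumps:
            d2 = (pts[:, 0] - b.x) ** 2 + (pts[:, 1] - b.y) ** 2
            z += b.amplitude * np.exp(-d2 / (2.0 * b.radius**2))
        return z


def evaluate_true_surface(surface: TrueSurface, points) -> np.ndarray:
    """Log-odds offsets of the generating surface at planar points."""
    return surface.evaluate(points)


@dataclass(frozen=True)
class CovariateEffects:
    """Log-odds coefficients of the five adjustment covariates.

    Defaults are modest effects in the direction of the known epidemiology
    (risk rising with age, male sex, white race, termite treatment; falling
    with education).
    """

    age_per_decade: float = 0.15
    male: float = 0.20
    white: float = 0.30
    education_highschool: float = -0.10
    education_college: float = -0.20
    termite: float = 0.30

    @classmethod
    def null(cls) -> "CovariateEffects":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic study scenario."""

    n_cases: int = 840
    n_controls: int = 680
    study_window_years: int = 20
    reference_year: int = 2000
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0)
    mobility: dict = field(default_factory=lambda: dict(DEFAULT_MOBILITY))
    bumps: tuple[GaussianBump, ...] = ()
    active_lag_years: int = 20
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    matching_strata: tuple[str, ...] = ("age_group", "sex", "race", "center")
    centers: tuple[str, ...] = DEFAULT_CENTERS
    match_level_probs: dict = field(default_factory=lambda: dict(DEFAULT_MATCH_LEVEL_PROBS))
    seed: int = 0

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        x0, y0, x1, y1 = self.bbox
        if not (x1 > x0 and y1 > y0):
            raise ValueError("bbox must be non-degenerate")
        if not 0 <= self.active_lag_years <= self.study_window_years:
            raise ValueError("active_lag_years must lie within the study window")
        if abs(sum(self.mobility.values()) - 1.0) > 1e-9:
            raise ValueError("mobility probabilities must sum to 1")
        if abs(sum(self.match_level_probs.values()) - 1.0) > 1e-9:
            raise ValueError("match_level probabilities must sum to 1")
        for b in self.bumps:
            if b.radius <= 0 or not np.isfinite(b.amplitude):
                raise ValueError("invalid bump")

    @property
    def surface(self) -> TrueSurface:
        return TrueSurface(tuple(self.bumps))

    @property
    def baseline_logodds(self) -> float:
        return float(logit(self.n_cases / (self.n_cases + self.n_controls)))

    def null_variant(self) -> "ScenarioConfig":
        """Same scenario with no spatial effect and zero covariate effects."""
        return replace(self, bumps=(), covariate_effects=CovariateEffects.null())


# ---------------------------------------------------------------------------
# population model


def _age_group(age: np.ndarray) -> np.ndarray:
    lo = 5 * (np.asarray(age, int) // 5)
    return np.array([f"{a:02d}-{a + 4:02d}" for a in lo])


def _draw_covariates(rng: np.random.Generator, n: int, config: ScenarioConfig,
                     fixed: dict | None = None) -> pd.DataFrame:
    """Draw covariates for n subjects; ``fixed`` pins matching-stratum values
    (age is drawn uniformly within a pinned 5-year group)."""
    fixed = fixed or {}
    if "age_group" in fixed:
        lo = int(fixed["age_group"].split("-")[0])
        hi = min(lo + 4, AGE_MAX)
        age = rng.integers(max(lo, AGE_MIN), hi + 1, size=n)
    else:
        age = np.clip(np.rint(rng.normal(60.0, 10.0, size=n)), AGE_MIN, AGE_MAX).astype(int)
    sex = np.full(n, fixed["sex"]) if "sex" in fixed else np.where(
        rng.random(n) < 0.52, "male", "female")
    race = np.full(n, fixed["race"]) if "race" in fixed else np.where(
        rng.random(n) < 0.85, "white", "other")
    center = np.full(n, fixed["center"]) if "center" in fixed else rng.choice(
        np.array(config.centers), size=n)
    education = rng.choice(np.array(_EDUCATION_LEVELS), size=n, p=_EDUCATION_PROBS)
    termite = rng.random(n) < 0.15
    return pd.DataFrame({
        "age": age,
        "age_group": _age_group(age),
        "sex": sex,
        "race": race,
        "center": center,
        "education": education,
        "termite_pre1988": termite,
    })


def _covariate_logodds(df: pd.DataFrame, eff: CovariateEffects) -> np.ndarray:
    z = eff.age_per_decade * (df["age"].to_numpy(float) - 60.0) / 10.0
    z = z + eff.male * (df["sex"].to_numpy() == "male")
    z = z + eff.white * (df["race"].to_numpy() == "white")
    z = z + eff.education_highschool * (df["education"].to_numpy() == "b_highschool")
    z = z + eff.education_college * (df["education"].to_numpy() == "c_college")
    z = z + eff.termite * df["termite_pre1988"].to_numpy(bool)
    return z


def _draw_histories(rng: np.random.Generator, n: int, config: ScenarioConfig):
    """Residential histories tiling the study window with no gaps.

    Each subject's window is cut into ``n_res`` whole-year intervals (>= 1
    year each; consecutive residences share the boundary year: the move-out
    year of one home is the move-in year of the next).  Each residence is
    placed uniformly in the bbox.  Returns (per-residence frame without
    subject ids, residence counts per subject, lag-active locations (n, 2)).
    """
    ref = config.reference_year
    w = config.study_window_years
    x0, y0, x1, y1 = config.bbox
    counts = rng.choice(np.array(sorted(config.mobility)), size=n,
                        p=[config.mobility[k] for k in sorted(config.mobility)])
    levels = sorted(config.match_level_probs)
    level_p = [config.match_level_probs[k] for k in levels]
    rows_in, rows_out, subj_idx = [], [], []
    for i in range(n):
        k = int(counts[i])
        cuts = np.sort(rng.choice(np.arange(ref - w + 1, ref), size=k - 1,
                                  replace=False)) if k > 1 else np.array([], int)
        bounds = np.concatenate([[ref - w], cuts, [ref]])
        rows_in.append(bounds[:-1])
        rows_out.append(bounds[1:])
        subj_idx.append(np.full(k, i))
    move_in = np.concatenate(rows_in).astype(int)
    move_out = np.concatenate(rows_out).astype(int)
    subj_idx = np.concatenate(subj_idx)
    m = len(move_in)
    xs = rng.uniform(x0, x1, size=m)
    ys = rng.uniform(y0, y1, size=m)
    match = rng.choice(np.array(levels), size=m, p=level_p)
    res = pd.DataFrame({
        "_subject_index": subj_idx,
        "move_in_year": move_in,
        "move_out_year": move_out,
        "x": xs,
        "y": ys,
        "match_level": match,
        "in_area": True,
    })
    # residence occupied at the active lag (later move-in wins at a boundary)
    target = ref - config.active_lag_years
    claims = res[(res["move_in_year"] <= target) & (res["move_out_year"] >= target)]
    best = claims.sort_values(["_subject_index", "move_in_year"], kind="mergesort") \
                 .groupby("_subject_index").tail(1)
    lag_xy = np.column_stack([best["x"].to_numpy(), best["y"].to_numpy()])
    return res, counts, lag_xy


def largest_remainder(total: int, counts: dict) -> dict:
    """Apportion ``total`` over strata proportional to ``counts`` (cases),
    deterministically: floors plus remainders assigned by largest fractional
    part, ties broken by stratum key order."""
    keys = sorted(counts)
    weights = np.array([counts[k] for k in keys], dtype=float)
    if weights.sum() == 0:
        raise ValueError("cannot apportion against all-zero margins")
    ideal = total * weights / weights.sum()
    base = np.floor(ideal).astype(int)
    rem = total - base.sum()
    frac_order = sorted(range(len(keys)), key=lambda i: (-(ideal[i] - base[i]), keys[i]))
    for i in frac_order[:rem]:
        base[i] += 1
    return {k: int(b) for k, b in zip(keys, base)}


# ---------------------------------------------------------------------------
# study generation


def _stratum_key(df: pd.DataFrame, strata: tuple[str, ...]):
    return list(zip(*(df[s].astype(str) for s in strata)))


def generate_study(config: ScenarioConfig):
    """Generate one synthetic study.

    Returns ``(subjects, residences)`` data frames in the documented CSV
    schemas.  Identical config (including seed) gives byte-identical tables.

    Raises :class:`MatchingError` when a matching stratum cannot supply its
    apportioned control count.
    """
    rng = np.random.default_rng(config.seed)
    n_pool = config.n_cases + config.n_controls
    b0 = config.baseline_logodds
    surface = config.surface

    pool = _draw_covariates(rng, n_pool, config)
    res_pool, _, lag_xy = _draw_histories(rng, n_pool, config)
    eta = b0 + _covariate_logodds(pool, config.covariate_effects) + surface.evaluate(lag_xy)
    y = rng.random(n_pool) < expit(eta)

    cases = pool[y].reset_index(drop=True)
    case_res = res_pool[res_pool["_subject_index"].isin(np.flatnonzero(y))]
    case_margins: dict = {}
    for key in _stratum_key(cases, config.matching_strata):
        case_margins[key] = case_margins.get(key, 0) + 1
    quotas = largest_remainder(config.n_controls, case_margins)

    ctrl_frames, ctrl_res_frames = [], []
    for key in sorted(quotas):
        quota = quotas[key]
        if quota == 0:
            continue
        fixed = dict(zip(config.matching_strata, key))
        got_cov, got_res = [], []
        n_got = 0
        for _ in range(60):  # rejection-sampling rounds
            if n_got >= quota:
                break
            batch = max(2 * (quota - n_got), 16)
            cand = _draw_covariates(rng, batch, config, fixed=fixed)
            cand_res, _, cand_lag = _draw_histories(rng, batch, config)
            p = expit(b0 + _covariate_logodds(cand, config.covariate_effects)
                      + surface.evaluate(cand_lag))
            accept = rng.random(batch) < (1.0 - p)
            take = np.flatnonzero(accept)[: quota - n_got]
            if take.size:
                got_cov.append(cand.iloc[take])
                got_res.append(cand_res[cand_res["_subject_index"].isin(take)]
                               .assign(_batch=len(got_cov)))
            n_got += take.size
        if n_got < quota:
            raise MatchingError(
                f"stratum {dict(zip(config.matching_strata, key))}: requested "
                f"{quota} matched controls but only {n_got} could be generated"
            )
        ctrl_frames.append(pd.concat(got_cov, ignore_index=False))
        ctrl_res_frames.append(got_res)

    # assemble subjects (cases first, then controls by stratum order) with
    # fresh sequential ids, and remap residence subject indices accordingly
    subj_rows = []
    res_rows = []
    next_id = 0

    def _sid(i: int) -> str:
        return f"S{i:06d}"

    case_index_map = {old: _sid(i) for i, old in enumerate(np.flatnonzero(y))}
    next_id = len(case_index_map)
    cases = cases.copy()
    cases.insert(0, "subject_id", [case_index_map[o] for o in np.flatnonzero(y)])
    cases.insert(1, "case", 1)
    subj_rows.append(cases)
    cr = case_res.copy()
    cr.insert(0, "subject_id", cr["_subject_index"].map(case_index_map))
    res_rows.append(cr.drop(columns="_subject_index"))

    for frame, res_chunks in zip(ctrl_frames, ctrl_res_frames):
        ids = [_sid(next_id + i) for i in range(len(frame))]
        next_id += len(frame)
        f = frame.copy().reset_index(drop=True)
        f.insert(0, "subject_id", ids)
        f.insert(1, "case", 0)
        subj_rows.append(f)
        offset = 0
        for chunk in res_chunks:
            local = chunk.copy()
            picked = sorted(local["_subject_index"].unique())
            id_map = {old: ids[offset + j] for j, old in enumerate(picked)}
            offset += len(picked)
            local.insert(0, "subject_id", local["_subject_index"].map(id_map))
            res_rows.append(local.drop(columns=["_subject_index", "_batch"]))

    subjects = pd.concat(subj_rows, ignore_index=True)
    subjects["reference_year"] = config.reference_year
    subjects = subjects[["subject_id", "case", "center", "reference_year", "age",
                         "age_group", "sex", "race", "education", "termite_pre1988"]]
    residences = pd.concat(res_rows, ignore_index=True)
    residences = residences[["subject_id", "move_in_year", "move_out_year",
                             "x", "y", "match_level", "in_area"]]
    residences = residences.sort_values(["subject_id", "move_in_year"],
                                        kind="mergesort").reset_index(drop=True)
    return subjects, residences
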