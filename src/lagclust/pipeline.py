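"""Per-center orchestration: lag models, ANODEV, lag selection, mapping.

For one study center the pipeline applies the inclusion filters, builds a
lagged point set per candidate lag (default 0/5/10/15/20 years before the
reference date), selects a loess span per lag by the AIC rule, fits crude and
covariate-adjusted spatial models, tests each smooth by analysis of deviance
against its no-smooth reduction, selects the lag with the smallest ANODEV
p-value, and runs the permutation cluster mapping at the selected lag.

The ANODEV chi-square uses the *effective* degrees-of-freedom difference
(non-integer df handled by the continuous chi-square); these p-values are
reported with the caveat that chi-square tests of smooth terms tend to have
inflated type-I error rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cluster as _cluster
from .gam import GAMResults, NullFit, SpatialLogitGAM, fit_null
from .histories import apply_inclusion_filters, build_lagged_points
from .span import DEFAULT_DELTA_AIC, SpanProfile, build_span_profile

__all__ = [
    "AnodevResult",
    "AnalysisConfig",
    "LagRecord",
    "CenterReport",
    "ComparisonReport",
    "anodev",
    "select_lag",
    "run_center_analysis",
    "compare_subpopulations",
]

ANODEV_CAVEAT = ("chi-square p-values for smoothed terms tend to have inflated "
                 "type I error rates; interpret with caution")


@dataclass(frozen=True)
class AnodevResult:
    """Deviance test of a spatial smooth against its no-smooth reduction."""

    lag: int
    deviance_with: float
    deviance_without: float
    df_diff: float
    p_value: float
    caveat: str = ANODEV_CAVEAT

    @property
    def deviance_diff(self) -> float:
        return self.deviance_without - self.deviance_with


def anodev(fit_with: GAMResults, fit_without, lag: int | None = None,
           tol: float = 1e-6) -> AnodevResult:
    """Analysis of deviance for nested models (smooth vs no smooth).

    ``fit_without`` may be a :class:`NullFit` (crude comparison) or a
    covariates-only :class:`GAMResults`.  The deviance difference is referred
    to a chi-square with df equal to the effective-df difference; non-integer
    df uses the continuous chi-square (gamma) distribution.
    """
    dev_w = float(fit_with.deviance)
    dev_wo = float(fit_without.deviance)
    edf_w = float(fit_with.edf_total)
    edf_wo = float(fit_without.edf_total)
    diff = dev_wo - dev_w
    if diff < -tol * (abs(dev_wo) + 1.0):
        raise RuntimeError(
            f"deviance increased by {-diff:.6g} when adding the smooth; "
            "convergence problem in the nested fits"
        )
    diff = max(diff, 0.0)
    df = edf_w - edf_wo
    if df <= 0:
        raise ValueError(f"non-positive effective-df difference ({df:.4g})")
    p = float(stats.chi2.sf(diff, df))
    if lag is None:
        lag = -1
    return AnodevResult(lag=int(lag), deviance_with=dev_w, deviance_without=dev_wo,
                        df_diff=df, p_value=p)


def select_lag(results) -> int:
    """Lag whose ANODEV p-value is smallest; ties go to the smallest lag.

    ``results`` is a mapping lag -> AnodevResult (or an iterable of
    AnodevResult).  The smallest p-value identifies the residential time
    period that best explains disease risk.
    """
    if isinstance(results, dict):
        items = [(int(lag), r.p_value) for lag, r in results.items()]
    else:
        items = [(int(r.lag), r.p_value) for r in results]
    if not items:
        raise ValueError("no ANODEV results to select from")
    return min(items, key=lambda t: (t[1], t[0]))[0]


# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Configuration of a per-center analysis run."""

    lags: tuple[int, ...] = (0, 5, 10, 15, 20)
    covariates: tuple[str, ...] = ("age", "sex", "race", "education", "termite_pre1988")
    window_years: int = 20
    buffer_distance: float = 0.0
    span_grid: tuple[float, ...] | None = None
    span_delta: float = DEFAULT_DELTA_AIC
    span_override: float | None = None
    degree: int = 1
    grid_nx: int = 50
    grid_ny: int = 50
    n_perm: int = 999
    alpha: float = 0.025
    seed: int = 0
    adjusted: bool = True
    #: compare the adjusted smooth against the covariates-only reduction
    #: ("covariates") or against the intercept-only null ("null")
    anodev_reference: str = "covariates"
    map_all_lags: bool = False

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class LagRecord:
    """Everything computed at one lag for one center."""

    lag: int
    n_subjects: int
    crude_span_profile: SpanProfile
    crude_fit: GAMResults
    crude_anodev: AnodevResult
    adjusted_span_profile: SpanProfile | None = None
    adjusted_fit: GAMResults | None = None
    adjusted_anodev: AnodevResult | None = None


@dataclass
class CenterReport:
    """Full per-center analysis output."""

    center: str
    config: AnalysisConfig
    filter_report: object
    lag_records: dict = field(default_factory=dict)
    selected_lag_crude: int | None = None
    selected_lag_adjusted: int | None = None
    selected_lag: int | None = None
    null_fit: NullFit | None = None
    permutation: _cluster.PermutationResult | None = None
    classification: np.ndarray | None = None
    contours: list = field(default_factory=list)
    per_lag_permutations: dict = field(default_factory=dict)
    failure: str | None = None
    note: str = _cluster.POINTWISE_NOTE

    def span_table(self) -> pd.DataFrame:
        rows = []
        for lag, rec in sorted(self.lag_records.items()):
            prof = rec.crude_span_profile
            rows.append({"lag": lag, "model": "crude",
                         "span": (prof.selected_span if prof is not None
                                  else rec.crude_fit.model.span),
                         "rationale": prof.rationale if prof is not None else "override",
                         "aic": rec.crude_fit.aic})
            if rec.adjusted_fit is not None:
                prof = rec.adjusted_span_profile
                rows.append({"lag": lag, "model": "adjusted",
                             "span": (prof.selected_span if prof is not None
                                      else rec.adjusted_fit.model.span),
                             "rationale": prof.rationale if prof is not None else "override",
                             "aic": rec.adjusted_fit.aic})
        return pd.DataFrame(rows)

    def anodev_table(self) -> pd.DataFrame:
        rows = []
        for lag, rec in sorted(self.lag_records.items()):
            rows.append({"lag": lag, "model": "crude",
                         "deviance_with": rec.crude_anodev.deviance_with,
                         "deviance_without": rec.crude_anodev.deviance_without,
                         "df": rec.crude_anodev.df_diff,
                         "p_value": rec.crude_anodev.p_value})
            if rec.adjusted_anodev is not None:
                rows.append({"lag": lag, "model": "adjusted",
                             "deviance_with": rec.adjusted_anodev.deviance_with,
                             "deviance_without": rec.adjusted_anodev.deviance_without,
                             "df": rec.adjusted_anodev.df_diff,
                             "p_value": rec.adjusted_anodev.p_value})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = {
            "center": self.center,
            "config": self.config.to_dict(),
            "filters": self.filter_report.to_dict() if self.filter_report is not None else None,
            "selected_lag": self.selected_lag,
            "selected_lag_crude": self.selected_lag_crude,
            "selected_lag_adjusted": self.selected_lag_adjusted,
            "spans": self.span_table().to_dict(orient="records"),
            "anodev": self.anodev_table().to_dict(orient="records"),
            "anodev_caveat": ANODEV_CAVEAT,
            "inference_note": self.note,
            "failure": self.failure,
        }
        if self.permutation is not None:
            cls = self.classification
            d["permutation"] = {
                "n_perm": self.permutation.n_perm,
                "seed": self.permutation.seed,
                "alpha": self.permutation.alpha,
                "n_hot_cells": int((cls == 1).sum()),
                "n_cold_cells": int((cls == -1).sum()),
                "n_cells": int(cls.size),
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _fit_at_lag(points: pd.DataFrame, covariates, config: AnalysisConfig,
                span_grid, fit_kwargs=None):
    """Span profile + fit for one lag; returns (profile, results, model)."""
    model0 = SpatialLogitGAM.from_dataframe(points, covariates=covariates,
                                            span=0.5, degree=config.degree)
    if config.span_override is not None:
        profile = None
        span = config.span_override
    else:
        profile = build_span_profile(model0.endog, model0.coords, exog=model0.exog,
                                     span_grid=span_grid, degree=config.degree,
                                     delta=config.span_delta,
                                     exog_names=model0.exog_names,
                                     fit_kwargs=fit_kwargs)
        span = profile.selected_span
    model = SpatialLogitGAM(model0.endog, model0.coords, exog=model0.exog,
                            span=span, degree=config.degree,
                            exog_names=model0.exog_names)
    model.exog_profile_default = model0.exog_profile_default
    res = model.fit(**(fit_kwargs or {}))
    return profile, res, model


def run_center_analysis(subjects: pd.DataFrame, residences: pd.DataFrame,
                        config: AnalysisConfig, boundary=None,
                        center: str | None = None) -> CenterReport:
    """Run the full single-center analysis.

    Any stage failure after filtering yields a partial report with the
    failure recorded rather than an exception.  Fully deterministic given the
    config (including its seed).
    """
    if center is not None:
        subjects = subjects[subjects["center"] == center]
        residences = residences[residences["subject_id"].isin(subjects["subject_id"])]
    name = center if center is not None else "all"
    subj_f, res_f, freport = apply_inclusion_filters(
        subjects, residences, buffer_distance=config.buffer_distance,
        window_years=config.window_years, boundary=boundary)
    report = CenterReport(center=name, config=config, filter_report=freport)
    try:
        covs = list(config.covariates) if config.adjusted else []
        crude_anodevs, adjusted_anodevs = {}, {}
        for lag in config.lags:
            pts = build_lagged_points(subj_f, res_f, lag)
            null = fit_null(pts["case"].to_numpy())
            c_profile, c_fit, _ = _fit_at_lag(pts, (), config, config.span_grid)
            rec = LagRecord(lag=lag, n_subjects=len(pts),
                            crude_span_profile=c_profile, crude_fit=c_fit,
                            crude_anodev=anodev(c_fit, null, lag=lag))
            crude_anodevs[lag] = rec.crude_anodev
            if covs:
                a_profile, a_fit, a_model = _fit_at_lag(pts, covs, config,
                                                        config.span_grid)
                if config.anodev_reference == "null":
                    reduction = null
                else:
                    red_model = SpatialLogitGAM(a_model.endog, a_model.coords,
                                                exog=a_model.exog, span=None,
                                                exog_names=a_model.exog_names)
                    reduction = red_model.fit()
                rec.adjusted_span_profile = a_profile
                rec.adjusted_fit = a_fit
                rec.adjusted_anodev = anodev(a_fit, reduction, lag=lag)
                adjusted_anodevs[lag] = rec.adjusted_anodev
            report.lag_records[lag] = rec
        report.selected_lag_crude = select_lag(crude_anodevs)
        if adjusted_anodevs:
            report.selected_lag_adjusted = select_lag(adjusted_anodevs)
        report.selected_lag = (report.selected_lag_adjusted
                               if report.selected_lag_adjusted is not None
                               else report.selected_lag_crude)

        map_lags = list(config.lags) if config.map_all_lags else [report.selected_lag]
        for lag in map_lags:
            rec = report.lag_records[lag]
            pts = build_lagged_points(subj_f, res_f, lag)
            use_adjusted = rec.adjusted_fit is not None
            fit = rec.adjusted_fit if use_adjusted else rec.crude_fit
            model = fit.model
            grid = _cluster.make_grid(model.coords, nx=config.grid_nx,
                                      ny=config.grid_ny, boundary=boundary)
            perm = _cluster.permutation_null(
                model.endog, model.coords, grid, span=model.span,
                exog=model.exog, exog_names=model.exog_names,
                covariate_profile=model.exog_profile_default,
                n_perm=config.n_perm, seed=config.seed, degree=config.degree,
                alpha=config.alpha)
            report.per_lag_permutations[lag] = perm
            if lag == report.selected_lag:
                report.permutation = perm
                report.null_fit = fit_null(model.endog)
                report.classification = _cluster.classify_cells(perm)
                report.contours = _cluster.extract_contours(report.classification, grid)
    except Exception as exc:  # noqa: BLE001 - partial report with failure record
        report.failure = f"{type(exc).__name__}: {exc}"
    return report


# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Two-population comparison (e.g. participants vs all eligible)."""

    report_a: CenterReport
    report_b: CenterReport
    hot_overlap_jaccard: float
    hot_overlap_frac_a: float

    def to_dict(self) -> dict:
        return {
            "a": self.report_a.to_dict(),
            "b": self.report_b.to_dict(),
            "hot_overlap_jaccard": self.hot_overlap_jaccard,
            "hot_overlap_frac_a": self.hot_overlap_frac_a,
        }


def compare_subpopulations(subjects_a: pd.DataFrame, residences_a: pd.DataFrame,
                           subjects_b: pd.DataFrame, residences_b: pd.DataFrame,
                           config: AnalysisConfig | None = None,
                           boundary=None) -> ComparisonReport:
    """Selection-bias check: single-time-point cluster analyses of two
    populations on one shared grid, reporting hot-contour overlap.

    Runs the lag-0, age+gender-adjusted analysis on each population; overlap
    is the Jaccard index of the hot cell sets plus the fraction of A's hot
    cells also hot in B.
    """
    base = config or AnalysisConfig()
    from dataclasses import replace

    cfg = replace(base, lags=(0,), covariates=("age", "sex"), map_all_lags=False)

    # shared grid over the union of both populations' lag-0 locations
    def _lag0_coords(subjects, residences):
        s, r, _ = apply_inclusion_filters(subjects, residences,
                                          buffer_distance=cfg.buffer_distance,
                                          window_years=cfg.window_years,
                                          boundary=boundary)
        pts = build_lagged_points(s, r, 0)
        return pts[["x", "y"]].to_numpy(float)

    all_xy = np.vstack([_lag0_coords(subjects_a, residences_a),
                        _lag0_coords(subjects_b, residences_b)])
    bbox = (all_xy[:, 0].min(), all_xy[:, 1].min(),
            all_xy[:, 0].max(), all_xy[:, 1].max())

    def _run(subjects, residences):
        rep = run_center_analysis(subjects, residences, cfg, boundary=boundary)
        if rep.failure:
            raise RuntimeError(f"subpopulation analysis failed: {rep.failure}")
        # re-map on the shared grid so classifications are comparable
        rec = rep.lag_records[0]
        fit = rec.adjusted_fit if rec.adjusted_fit is not None else rec.crude_fit
        model = fit.model
        grid = _cluster.make_grid(None, nx=cfg.grid_nx, ny=cfg.grid_ny,
                                  boundary=boundary, bbox=bbox)
        perm = _cluster.permutation_null(
            model.endog, model.coords, grid, span=model.span, exog=model.exog,
            exog_names=model.exog_names,
            covariate_profile=model.exog_profile_default,
            n_perm=cfg.n_perm, seed=cfg.seed, degree=cfg.degree, alpha=cfg.alpha)
        rep.permutation = perm
        rep.classification = _cluster.classify_cells(perm)
        rep.contours = _cluster.extract_contours(rep.classification, grid)
        return rep

    rep_a = _run(subjects_a, residences_a)
    rep_b = _run(subjects_b, residences_b)
    hot_a = rep_a.classification == 1
    hot_b = rep_b.classification == 1
    union = int((hot_a | hot_b).sum())
    inter = int((hot_a & hot_b).sum())
    jaccard = inter / union if union else 1.0
    frac_a = inter / int(hot_a.sum()) if hot_a.sum() else 1.0
    return ComparisonReport(report_a=rep_a, report_b=rep_b,
                            hot_overlap_jaccard=jaccard,
                            hot_overlap_frac_a=frac_a)
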