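"""Logistic generalized additive model with one bivariate loess smooth.

The model for subject *i* with binary outcome :math:`y_i` (case status),
covariates :math:`x_i` and planar residential location :math:`s_i` is

.. math::

    \\operatorname{logit} P(y_i = 1) = \\alpha + x_i \\beta + Z(s_i),

where :math:`Z` is a bivariate loess smooth of the locations, identified by
centering (mean zero over the data points).  Dropping the smooth gives an
ordinary logistic regression; dropping the covariates gives a crude spatial
model; dropping both gives the intercept-only null model.

Fitting is by local scoring with backfitting: iterate working response
``z = eta + (y - p)/(p(1-p))`` and weights ``w = p(1-p)``, backfit the linear
part (weighted least squares) against the loess smooth until the deviance
stabilizes.  The effective degrees of freedom of the smooth are the trace of
the loess smoother matrix at the converged weights minus one for the centering
constraint; ``aic = deviance + 2 * edf_total``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .loess import Loess2D, LoessWorkspace

__all__ = ["SpatialLogitGAM", "GAMResults", "NullFit", "fit_null"]

_CLIP = 1e-10


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    return float(-2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _wls(X: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, np.newaxis], t * sw, rcond=None)
    return beta


@dataclass(frozen=True)
class NullFit:
    """Intercept-only logistic model: the whole-study-area reference.

    ``deviance = -2 [ m ln(pbar) + (n - m) ln(1 - pbar) ]`` for m cases of n.
    """

    n: int
    n_cases: int
    pbar: float
    deviance: float
    aic: float
    edf_total: float = 1.0

    @property
    def odds(self) -> float:
        return self.pbar / (1.0 - self.pbar)


def fit_null(y) -> NullFit:
    y = np.asarray(y, dtype=float)
    n = y.size
    m = int(y.sum())
    pbar = m / n
    dev = _binomial_deviance(y, np.full(n, pbar))
    return NullFit(n=n, n_cases=m, pbar=pbar, deviance=dev, aic=dev + 2.0)


class SpatialLogitGAM:
    """Logistic GAM with linear covariates and one bivariate spatial smooth.

    Parameters
    ----------
    endog : array-like of {0, 1}
        Case status per subject.
    coords : (n, 2) array
        Planar (projected) residential locations at the chosen lag.  Distances
        are Euclidean; never pass longitude/latitude directly.
    exog : (n, q) array or None
        Covariate matrix *without* an intercept column (added internally).
        ``None`` gives the crude spatial model.
    span : float in (0, 1] or None
        Loess span.  ``None`` disables the smooth, giving plain logistic
        regression (or the null model if ``exog`` is also None).
    degree : {1, 2}
        Local polynomial degree of the loess smooth.
    """

    def __init__(self, endog, coords, exog=None, span: float | None = 0.5,
                 degree: int = 1, exog_names=None):
        y = np.asarray(endog, dtype=float)
        if y.ndim != 1:
            raise ValueError("endog must be one-dimensional")
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("endog must be binary 0/1")
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (y.size, 2):
            raise ValueError("coords must be (n, 2)")
        self.endog = y
        self.coords = coords
        if exog is None:
            self.exog = None
            self.exog_names: list[str] = []
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[:, np.newaxis]
            if X.shape[0] != y.size:
                raise ValueError("exog and endog lengths differ")
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
                raise ValueError("covariates are rank-deficient after adding an intercept")
            self.exog = X
            if exog_names is None:
                exog_names = [f"x{j}" for j in range(X.shape[1])]
            self.exog_names = list(exog_names)
        self.span = None if span is None else float(span)
        self.degree = int(degree)
        self.exog_profile_default: np.ndarray | None = None  # set by from_dataframe

    # ------------------------------------------------------------------

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str = "case",
                       coord_cols=("x", "y"), covariates=(), span=0.5, degree=1):
        """Build the model from a lagged-point-set data frame.

        Categorical covariates (object/category/bool dtype) are one-hot
        encoded against a reference level (first category in sorted order);
        the default grid prediction profile holds continuous covariates at
        their analysis-population mean and categoricals at the reference.
        """
        y = data[outcome].to_numpy()
        coords = data[list(coord_cols)].to_numpy(dtype=float)
        cols, names, profile = [], [], []
        for cov in covariates:
            s = data[cov]
            if s.dtype == bool or s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                levels = sorted(pd.unique(s.astype(str)))
                for lev in levels[1:]:  # first sorted level is the reference
                    cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                    names.append(f"{cov}[{lev}]")
                    profile.append(0.0)
            else:
                v = s.to_numpy(dtype=float)
                cols.append(v)
                names.append(cov)
                profile.append(float(v.mean()))
        exog = np.column_stack(cols) if cols else None
        model = cls(y, coords, exog=exog, span=span, degree=degree, exog_names=names)
        model.exog_profile_default = np.asarray(profile) if profile else None
        return model

    # ------------------------------------------------------------------

    def _linear_design(self) -> np.ndarray:
        n = self.endog.size
        if self.exog is None:
            return np.ones((n, 1))
        return np.column_stack([np.ones(n), self.exog])

    def fit(self, tol: float = 1e-8, maxiter: int = 25, inner_tol: float = 1e-10,
            inner_maxiter: int = 50, compute_edf: bool = True,
            workspace: LoessWorkspace | None = None,
            start: "GAMResults | None" = None) -> "GAMResults":
        """Fit by local scoring with backfitting.

        ``workspace`` may supply precomputed loess neighbourhoods over the
        model's coordinates (exact reuse across refits on fixed locations,
        e.g. permutation tests).  ``start`` warm-starts the local scoring from
        a previous fit's state (e.g. to verify the converged fixed point).
        """
        y = self.endog
        n = y.size
        X = self._linear_design()
        use_smooth = self.span is not None
        if use_smooth:
            smoother = Loess2D(self.span, self.degree)
            ws = workspace if workspace is not None else smoother.workspace(self.coords)
            if ws.n_train != n:
                raise ValueError("workspace does not match the model's coordinates")
        else:
            ws = None

        pbar = y.mean()
        if start is not None:
            eta = start.linpred.copy()
            f = start.smooth.copy() if start.smooth is not None else np.zeros(n)
            beta = start.params.copy()
        else:
            eta = np.full(n, logit(np.clip(pbar, _CLIP, 1 - _CLIP)))
            f = np.zeros(n)
            beta = np.zeros(X.shape[1])
            beta[0] = eta[0]
        f_raw = np.zeros(n)
        center = 0.0
        dev = _binomial_deviance(y, expit(eta))
        converged = False
        it = 0
        resid_fit = None  # partial residual the final smooth was computed from
        w_fit = None      # working weights of that same smoothing step
        for it in range(1, maxiter + 1):
            p = np.clip(expit(eta), _CLIP, 1.0 - _CLIP)
            w = p * (1.0 - p)
            z = eta + (y - p) / w
            if use_smooth:
                for _ in range(inner_maxiter):
                    beta = _wls(X, z - f, w)
                    resid = z - X @ beta
                    f_raw = ws.smooth(resid, w)
                    f_new = f_raw - f_raw.mean()
                    delta = np.max(np.abs(f_new - f))
                    f = f_new
                    if delta < inner_tol:
                        break
                center = f_raw.mean()
                resid_fit, w_fit = resid, w
            else:
                beta = _wls(X, z, w)
            eta = X @ beta + f
            dev_new = _binomial_deviance(y, expit(eta))
            if abs(dev_new - dev) < tol * (abs(dev) + 0.1):
                dev = dev_new
                converged = True
                break
            dev = dev_new
        p = np.clip(expit(eta), _CLIP, 1.0 - _CLIP)
        pinned = np.mean((p <= _CLIP) | (p >= 1.0 - _CLIP))
        if pinned > 0.10:
            warnings.warn(
                f"{pinned:.0%} of fitted probabilities pinned at the clipping "
                "bounds; possible separation",
                RuntimeWarning,
                stacklevel=2,
            )
        if use_smooth:
            # prediction must reuse the exact (residual, weights) pair of the
            # final smoothing step so predict-at-a-training-point reproduces
            # the training fitted value bit-for-bit
            resid_target = resid_fit
            w = w_fit
            edf_smooth = float(ws.smoother_diag(w_fit).sum()) - 1.0 if compute_edf else np.nan
        else:
            w = p * (1.0 - p)
            resid_target = None
            edf_smooth = 0.0
        edf_total = X.shape[1] + edf_smooth
        aic = dev + 2.0 * edf_total
        return GAMResults(
            model=self,
            params=beta,
            smooth=f.copy() if use_smooth else None,
            linpred=eta,
            fittedvalues=expit(eta),
            deviance=dev,
            edf_smooth=edf_smooth,
            edf_total=edf_total,
            aic=aic,
            converged=converged,
            iterations=it,
            _weights=w,
            _resid_target=resid_target,
            _center=center,
            _workspace=ws,
        )


@dataclass
class GAMResults:
    """Fitted logistic GAM: coefficients, smooth, deviance, edf and AIC."""

    model: SpatialLogitGAM
    params: np.ndarray            # [intercept, covariate coefficients...]
    smooth: np.ndarray | None     # centered Z(s_i) at the data points
    linpred: np.ndarray
    fittedvalues: np.ndarray
    deviance: float
    edf_smooth: float
    edf_total: float
    aic: float
    converged: bool
    iterations: int
    _weights: np.ndarray = field(repr=False, default=None)
    _resid_target: np.ndarray | None = field(repr=False, default=None)
    _center: float = field(repr=False, default=0.0)
    _workspace: LoessWorkspace | None = field(repr=False, default=None)

    @property
    def param_names(self) -> list[str]:
        return ["intercept"] + self.model.exog_names

    @property
    def pbar(self) -> float:
        return float(self.model.endog.mean())

    # ------------------------------------------------------------------

    def smooth_at(self, points, workspace: LoessWorkspace | None = None) -> np.ndarray:
        """Evaluate the centered spatial smooth at new planar locations.

        The converged partial residuals and working weights define the smooth
        as a linear operator; prediction applies the identical local-fit
        recipe with neighbourhoods drawn from the training points.
        """
        if self.smooth is None:
            return np.zeros(len(np.atleast_2d(points)))
        if workspace is None:
            smoother = Loess2D(self.model.span, self.model.degree)
            workspace = smoother.workspace(self.model.coords, np.asarray(points, float))
        raw = workspace.smooth(self._resid_target, self._weights)
        return raw - self._center

    def predict_logodds(self, points, covariate_profile=None,
                        workspace: LoessWorkspace | None = None) -> np.ndarray:
        """Model log odds at new locations for a fixed covariate profile.

        ``covariate_profile`` supplies one value per covariate column
        (defaults: the profile recorded by ``from_dataframe`` — continuous
        covariates at the analysis-population mean, categoricals at the
        reference level — or zeros).
        """
        alpha = self.params[0]
        contrib = 0.0
        if self.model.exog is not None:
            if covariate_profile is None:
                covariate_profile = self.model.exog_profile_default
            if covariate_profile is None:
                covariate_profile = np.zeros(len(self.model.exog_names))
            profile = np.asarray(covariate_profile, dtype=float)
            if profile.shape != (len(self.model.exog_names),):
                raise ValueError("covariate_profile must supply one value per covariate")
            contrib = float(profile @ self.params[1:])
        return alpha + contrib + self.smooth_at(points, workspace=workspace)

    # ------------------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Spatial logistic GAM" if self.smooth is not None else "Logistic regression",
            "=" * 58,
            f"n subjects       {self.model.endog.size:>10d}    cases {int(self.model.endog.sum())}",
            f"span             {self.model.span!s:>10}    degree {self.model.degree}",
            f"deviance         {self.deviance:>12.4f}",
            f"edf (smooth)     {self.edf_smooth:>12.4f}",
            f"edf (total)      {self.edf_total:>12.4f}",
            f"AIC              {self.aic:>12.4f}",
            f"converged        {str(self.converged):>10}    iterations {self.iterations}",
            "-" * 58,
            f"{'term':<28}{'coef':>12}",
        ]
        for name, b in zip(self.param_names, self.params):
            lines.append(f"{name:<28}{b:>12.5f}")
        if self.smooth is not None:
            lines.append("-" * 58)
            lines.append("smooth: bivariate loess of planar location, centered to mean 0")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": dict(zip(self.param_names, map(float, self.params))),
            "deviance": float(self.deviance),
            "edf_smooth": float(self.edf_smooth),
            "edf_total": float(self.edf_total),
            "aic": float(self.aic),
            "span": self.model.span,
            "degree": self.model.degree,
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "n": int(self.model.endog.size),
            "n_cases": int(self.model.endog.sum()),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
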