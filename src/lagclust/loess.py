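"""Bivariate locally weighted regression (loess) with nearest-neighbour spans.

This is the engine behind the spatial smooth of the case-control GAM: at every
evaluation point a weighted polynomial (degree 1 by default) is fitted to the
``k = ceil(span * n)`` nearest observations, weighted by the tri-cube kernel in
Euclidean distance, and the fitted value is the local polynomial evaluated at
that point.  The operator is linear in the response, so a smoother matrix (and
its trace, the effective degrees of freedom of the smooth) is available.

The implementation deliberately performs an exact local solve at every
evaluation point -- no interpolation shortcuts -- so it can be validated
against a brute-force weighted-least-squares oracle.  Neighbourhoods and
tri-cube weights depend only on locations and span; :class:`LoessWorkspace`
precomputes them once so the smoother can be re-applied cheaply to many
response/weight vectors over fixed locations (e.g. permutation refits).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Loess2D",
    "Loess2DFit",
    "LoessWorkspace",
    "neighborhood_size",
    "tricube_weight",
    "pairwise_distances",
]

#: minimum neighbourhood size per local polynomial degree (number of terms
#: of the bivariate polynomial: 1 + s1 + s2 for degree 1, + quadratics for 2)
_Q_MIN = {1: 3, 2: 6}
# guard against binary round-off in span * n (e.g. 0.275 * 1000)
_CEIL_EPS = 1e-9


def neighborhood_size(span: float, n: int, degree: int = 1) -> int:
    """Number of nearest observations used in each local fit.

    ``k = max(q_min, ceil(span * n))`` capped at ``n``; a span of 0.5 with
    n = 100 uses the 50 nearest points.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    if n < 1:
        raise ValueError("n must be >= 1")
    q_min = _Q_MIN[degree]
    k = max(q_min, math.ceil(span * n - _CEIL_EPS))
    return min(k, n)


def tricube_weight(d, d_k):
    """Tri-cube kernel ``(1 - (d/d_k)^3)^3`` for ``d < d_k``, else 0.

    ``d_k`` is the distance to the k-th nearest neighbour; the weight decays
    smoothly to exactly zero at the neighbourhood boundary.  The degenerate
    case ``d_k == 0`` (all neighbours coincident with the evaluation point)
    assigns weight 1 to the coincident points.
    """
    d = np.asarray(d, dtype=float)
    if np.ndim(d_k) == 0:
        if d_k == 0:
            return np.where(d == 0, 1.0, 0.0)
        u = d / d_k
        w = np.where(u < 1.0, (1.0 - np.minimum(u, 1.0) ** 3) ** 3, 0.0)
        return w
    d_k = np.asarray(d_k, dtype=float)
    out = np.zeros(np.broadcast(d, d_k).shape)
    zero = d_k == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(zero, np.inf, d / np.where(d_k == 0, 1.0, d_k))
    inside = u < 1.0
    out[inside] = (1.0 - u[inside] ** 3) ** 3
    out[zero & (d == 0)] = 1.0
    return out


def pairwise_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between two planar point sets."""
    return cdist(np.asarray(a, float), np.asarray(b, float))


def _design(points: np.ndarray, degree: int, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Polynomial design matrix on standardized coordinates.

    Standardization only preconditions the local normal equations; the fitted
    values are invariant because the polynomial basis is closed under affine
    coordinate changes.
    """
    z = (points - center) / scale
    cols = [np.ones(len(z)), z[:, 0], z[:, 1]]
    if degree == 2:
        cols += [z[:, 0] ** 2, z[:, 0] * z[:, 1], z[:, 1] ** 2]
    return np.column_stack(cols)


@dataclass
class LoessWorkspace:
    """Precomputed neighbourhoods and tri-cube weights for fixed locations.

    ``smooth`` re-applies the smoother to new responses / prior weights without
    recomputing distances, which is what makes permutation refits cheap.
    """

    train_points: np.ndarray
    eval_points: np.ndarray
    span: float
    degree: int
    tricube: np.ndarray = field(repr=False)  # (m_eval, n_train)
    neighbor_mask: np.ndarray = field(repr=False)  # d <= d_k, incl. zero-weight rim
    X: np.ndarray = field(repr=False)  # (n_train, p)
    Xe: np.ndarray = field(repr=False)  # (m_eval, p)
    cross: np.ndarray = field(repr=False)  # (n_train, p*(p+1)/2) column products
    in_sample: bool = False

    @property
    def n_train(self) -> int:
        return self.train_points.shape[0]

    @property
    def n_eval(self) -> int:
        return self.eval_points.shape[0]

    # -- core linear-operator machinery -------------------------------------

    def _combined_weights(self, prior_weights) -> np.ndarray:
        C = self.tricube
        if prior_weights is not None:
            w = np.asarray(prior_weights, dtype=float)
            if w.shape != (self.n_train,):
                raise ValueError("prior_weights must have one entry per training point")
            if np.any(w < 0):
                raise ValueError("prior_weights must be non-negative")
            C = C * w[np.newaxis, :]
        # rows whose tri-cube x prior weights vanished entirely fall back to
        # uniform weights over the neighbourhood (documented degenerate rule)
        dead = C.sum(axis=1) == 0
        if np.any(dead):
            C = C.copy()
            C[dead] = self.neighbor_mask[dead].astype(float)
        return C

    def _normal_equations(self, C: np.ndarray):
        p = self.X.shape[1]
        iu, ju = np.triu_indices(p)
        A_flat = C @ self.cross  # (m, p*(p+1)/2)
        A = np.empty((self.n_eval, p, p))
        A[:, iu, ju] = A_flat
        A[:, ju, iu] = A_flat
        return A

    def _solve(self, A: np.ndarray, B: np.ndarray, C: np.ndarray, y: np.ndarray):
        """Batched local solves with a weighted-local-mean fallback."""
        try:
            beta = np.linalg.solve(A, B[..., np.newaxis])[..., 0]
            bad = ~np.all(np.isfinite(beta), axis=-1)
        except np.linalg.LinAlgError:
            beta = np.full(B.shape, np.nan)
            bad = np.ones(self.n_eval, dtype=bool)
        if np.any(bad):
            # retry singular rows individually; truly collinear neighbourhoods
            # fall back to the local weighted mean
            fallback_rows = []
            for i in np.flatnonzero(bad):
                try:
                    beta[i] = np.linalg.solve(A[i], B[i])
                    if not np.all(np.isfinite(beta[i])):
                        raise np.linalg.LinAlgError
                    bad[i] = False
                except np.linalg.LinAlgError:
                    sw = C[i].sum()
                    mu = (C[i] @ y) / sw if sw > 0 else np.nan
                    beta[i] = 0.0
                    beta[i, 0] = mu
                    # intercept column of Xe is 1, so fitted value = local mean
                    fallback_rows.append(i)
            if fallback_rows:
                warnings.warn(
                    f"singular local design at {len(fallback_rows)} evaluation "
                    "point(s); fell back to local weighted mean",
                    RuntimeWarning,
                    stacklevel=3,
                )
                # make the fallback exact: Xe rows are (1, z1, z2, ...) so zero
                # slopes + intercept=mean already evaluate to the local mean
        return beta

    def smooth(self, y, prior_weights=None) -> np.ndarray:
        """Fitted values at the evaluation points for response ``y``."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_train,):
            raise ValueError("response must have one entry per training point")
        C = self._combined_weights(prior_weights)
        A = self._normal_equations(C)
        B = C @ (self.X * y[:, np.newaxis])
        beta = self._solve(A, B, C, y)
        return np.einsum("mp,mp->m", beta, self.Xe)

    def smoother_matrix(self, prior_weights=None) -> np.ndarray:
        """Full (m_eval, n_train) linear smoother matrix S with fitted = S y."""
        C = self._combined_weights(prior_weights)
        A = self._normal_equations(C)
        try:
            V = np.linalg.solve(A, self.Xe[..., np.newaxis])[..., 0]
        except np.linalg.LinAlgError:
            V = np.stack([np.linalg.lstsq(A[i], self.Xe[i], rcond=None)[0] for i in range(self.n_eval)])
        S = (V @ self.X.T) * C
        dead = ~np.all(np.isfinite(S), axis=1)
        if np.any(dead):
            S[dead] = C[dead] / C[dead].sum(axis=1, keepdims=True)
        return S

    def smoother_diag(self, prior_weights=None) -> np.ndarray:
        """Diagonal of S (requires eval points == training points)."""
        if not self.in_sample:
            raise ValueError("smoother_diag requires an in-sample workspace")
        C = self._combined_weights(prior_weights)
        A = self._normal_equations(C)
        try:
            V = np.linalg.solve(A, self.Xe[..., np.newaxis])[..., 0]
        except np.linalg.LinAlgError:
            V = np.stack([np.linalg.lstsq(A[i], self.Xe[i], rcond=None)[0] for i in range(self.n_eval)])
        diag = np.einsum("mp,mp->m", V, self.X) * np.diagonal(C)
        bad = ~np.isfinite(diag)
        if np.any(bad):
            rowsum = C[bad].sum(axis=1)
            diag[bad] = np.diagonal(C)[bad] / np.where(rowsum > 0, rowsum, 1.0)
        return diag


class Loess2D:
    """Bivariate loess smoother specification.

    Parameters
    ----------
    span : float in (0, 1]
        Fraction of the data entering each local fit (nearest-neighbour
        bandwidth).  A span of 0.5 uses the nearest 50% of the observations at
        every evaluation point.
    degree : {1, 2}
        Local polynomial degree; degree 1 (intercept + both coordinates) is the
        standard choice for disease mapping.
    """

    def __init__(self, span: float = 0.5, degree: int = 1):
        if not 0.0 < span <= 1.0:
            raise ValueError(f"span must lie in (0, 1], got {span}")
        if degree not in _Q_MIN:
            raise ValueError("degree must be 1 or 2")
        self.span = float(span)
        self.degree = int(degree)

    def workspace(
        self,
        train_points,
        eval_points=None,
        distances: np.ndarray | None = None,
    ) -> LoessWorkspace:
        """Precompute neighbourhoods/weights for fixed train & eval locations.

        ``distances`` may supply the (m_eval, n_train) Euclidean distance
        matrix to avoid recomputation across spans on the same points.
        """
        train = np.ascontiguousarray(np.asarray(train_points, dtype=float))
        if train.ndim != 2 or train.shape[1] != 2:
            raise ValueError("train_points must be (n, 2)")
        if not np.all(np.isfinite(train)):
            raise ValueError("train_points must be finite")
        in_sample = eval_points is None
        ev = train if in_sample else np.ascontiguousarray(np.asarray(eval_points, dtype=float))
        if ev.ndim != 2 or ev.shape[1] != 2:
            raise ValueError("eval_points must be (m, 2)")
        n = train.shape[0]
        k = neighborhood_size(self.span, n, self.degree)
        if n < _Q_MIN[self.degree]:
            raise ValueError(f"need at least {_Q_MIN[self.degree]} points for degree {self.degree}")
        d = pairwise_distances(ev, train) if distances is None else np.asarray(distances, float)
        d_k = np.partition(d, k - 1, axis=1)[:, k - 1]
        T = tricube_weight(d, d_k[:, np.newaxis])
        mask = d <= d_k[:, np.newaxis]
        center = train.mean(axis=0)
        scale = train.std(axis=0)
        scale[scale == 0] = 1.0
        X = _design(train, self.degree, center, scale)
        Xe = X if in_sample else _design(ev, self.degree, center, scale)
        p = X.shape[1]
        iu, ju = np.triu_indices(p)
        cross = X[:, iu] * X[:, ju]
        return LoessWorkspace(
            train_points=train,
            eval_points=ev,
            span=self.span,
            degree=self.degree,
            tricube=T,
            neighbor_mask=mask,
            X=X,
            Xe=Xe,
            cross=cross,
            in_sample=in_sample,
        )

    def fit(self, points, y, prior_weights=None, compute_trace: bool = True) -> "Loess2DFit":
        """Fit the smoother at the data points themselves."""
        ws = self.workspace(points)
        fitted = ws.smooth(y, prior_weights)
        trace = float(ws.smoother_diag(prior_weights).sum()) if compute_trace else np.nan
        return Loess2DFit(
            spec=self,
            points=ws.train_points,
            y=np.asarray(y, dtype=float),
            prior_weights=None if prior_weights is None else np.asarray(prior_weights, float),
            fitted=fitted,
            trace=trace,
            workspace=ws,
        )


@dataclass
class Loess2DFit:
    """Fitted loess smooth: values at the data points plus the linear-operator
    trace (effective degrees of freedom of the smooth)."""

    spec: Loess2D
    points: np.ndarray
    y: np.ndarray
    prior_weights: np.ndarray | None
    fitted: np.ndarray
    trace: float
    workspace: LoessWorkspace

    def predict(self, new_points) -> np.ndarray:
        """Evaluate the smooth at new locations.

        Neighbourhoods are drawn from the training points; evaluation outside
        the training hull is permissible (local extrapolation) but flagged.
        """
        new_points = np.asarray(new_points, dtype=float)
        lo, hi = self.points.min(axis=0), self.points.max(axis=0)
        if np.any(new_points < lo) or np.any(new_points > hi):
            warnings.warn(
                "predicting outside the bounding box of the training points "
                "(local extrapolation)",
                RuntimeWarning,
                stacklevel=2,
            )
        ws = self.spec.workspace(self.points, new_points)
        return ws.smooth(self.y, self.prior_weights)

    def smoother_matrix(self) -> np.ndarray:
        return self.workspace.smoother_matrix(self.prior_weights)
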