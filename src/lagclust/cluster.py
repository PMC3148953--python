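"""Local odds-ratio maps and pointwise permutation cluster inference.

The fitted spatial model's log odds are predicted over a rectangular grid of
cell centers spanning the bounding box of the subject locations (default
50 x 50 = 2,500 cells) and divided by the odds of the intercept-only null
model, so each cell's odds ratio reads as risk relative to the whole study
area (an OR of 1.8 means risk elevated 80%).

Significance is assessed pointwise: case labels are permuted over the fixed
residential locations (covariates stay attached to their subject/location),
the model is refitted at the same span, and the OR grid re-predicted; cells
whose observed OR falls in the upper (lower) 2.5% of the permutation
distribution are classified hot (cold).  Tail probabilities use the add-one
Monte-Carlo rank convention ``(r + 1) / (n_perm + 1)``, ties counting toward
exceedance.  This is pointwise inference only — no family-wise control — and
every report of the classification carries that label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import GAMResults, NullFit, SpatialLogitGAM, fit_null
from .loess import Loess2D

__all__ = [
    "Grid",
    "ORGrid",
    "PermutationResult",
    "ClusterContour",
    "make_grid",
    "predict_or_map",
    "permutation_null",
    "classify_cells",
    "extract_contours",
    "percent_elevation",
    "contours_to_geojson",
    "plot_or_map",
]

DEFAULT_NX = DEFAULT_NY = 50
POINTWISE_NOTE = ("pointwise permutation inference only; no overall/family-wise "
                  "cluster significance is implied")


def percent_elevation(odds_ratio) -> np.ndarray | float:
    """Map-legend convention: OR 1.8 reads as an 80% elevation relative to
    the whole study area."""
    return (np.asarray(odds_ratio, dtype=float) - 1.0) * 100.0


@dataclass(frozen=True)
class Grid:
    """Rectangular grid of cell centers over a bounding box.

    Cell centers follow the half-offset convention: the (i, j) center sits at
    ``(x_min + (j + 0.5) dx, y_min + (i + 0.5) dy)``.  ``mask`` flags cells
    outside an optional boundary polygon (flagged, never dropped).
    """

    nx: int
    ny: int
    bbox: tuple[float, float, float, float]
    mask: np.ndarray | None = None  # (ny, nx) True = outside boundary

    @property
    def dx(self) -> float:
        return (self.bbox[2] - self.bbox[0]) / self.nx

    @property
    def dy(self) -> float:
        return (self.bbox[3] - self.bbox[1]) / self.ny

    @property
    def xc(self) -> np.ndarray:
        return self.bbox[0] + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def yc(self) -> np.ndarray:
        return self.bbox[1] + (np.arange(self.ny) + 0.5) * self.dy

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def centers(self) -> np.ndarray:
        """(nx*ny, 2) cell-center coordinates, row-major over (y, x)."""
        xx, yy = np.meshgrid(self.xc, self.yc)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def reshape(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values).reshape(self.ny, self.nx)


def make_grid(points, nx: int = DEFAULT_NX, ny: int = DEFAULT_NY,
              boundary=None, bbox=None) -> Grid:
    """Grid spanning the min/max coordinates of the subject locations.

    ``bbox`` may override the data-driven bounding box (e.g. to share one grid
    across two populations).  A degenerate bounding box is an error.
    """
    if bbox is None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError("need at least 2 points to define a grid")
        bbox = (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
    x0, y0, x1, y1 = map(float, bbox)
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate bounding box")
    grid = Grid(nx=int(nx), ny=int(ny), bbox=(x0, y0, x1, y1))
    if boundary is not None:
        from shapely import contains_xy

        c = grid.centers()
        inside = contains_xy(boundary, c[:, 0], c[:, 1])
        grid = Grid(nx=grid.nx, ny=grid.ny, bbox=grid.bbox,
                    mask=grid.reshape(~inside))
    return grid


@dataclass
class ORGrid:
    """Gridded local odds ratios relative to the null (whole-study-area) odds."""

    grid: Grid
    log_odds: np.ndarray      # (ny, nx) model log odds
    odds_ratio: np.ndarray    # (ny, nx) model odds / null odds
    null_odds: float
    covariate_profile: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        c = self.grid.centers()
        return pd.DataFrame({
            "x": c[:, 0],
            "y": c[:, 1],
            "log_odds": self.log_odds.ravel(),
            "odds_ratio": self.odds_ratio.ravel(),
            "masked": (self.grid.mask.ravel() if self.grid.mask is not None
                       else np.zeros(self.grid.n_cells, bool)),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def predict_or_map(results: GAMResults, null: NullFit, grid: Grid,
                   covariate_profile=None, workspace=None) -> ORGrid:
    """Predict the local odds-ratio map from a fitted model.

    Per cell: ``log odds = alpha + profile . beta + Z(cell center)``;
    ``OR = exp(log odds) / (pbar / (1 - pbar))``.
    """
    eta = results.predict_logodds(grid.centers(), covariate_profile=covariate_profile,
                                  workspace=workspace)
    log_odds = grid.reshape(eta)
    or_ = np.exp(log_odds) / null.odds
    profile = None
    if results.model.exog is not None:
        profile = (np.asarray(covariate_profile, float) if covariate_profile is not None
                   else (results.model.exog_profile_default
                         if results.model.exog_profile_default is not None
                         else np.zeros(len(results.model.exog_names))))
    return ORGrid(grid=grid, log_odds=log_odds, odds_ratio=or_,
                  null_odds=null.odds, covariate_profile=profile)


@dataclass
class PermutationResult:
    """Per-cell permutation exceedance counts and hot/cold classification.

    ``count_ge[i, j]`` is the number of permuted ORs >= the observed OR at
    cell (i, j) (ties included), ``count_le`` the symmetric count.  A cell is
    hot iff ``(count_ge + 1) / (n_perm + 1) <= alpha`` and cold symmetrically
    (default alpha 0.025 per tail).
    """

    n_perm: int
    seed: int
    alpha: float
    observed: ORGrid
    count_ge: np.ndarray
    count_le: np.ndarray
    n_failed: int = 0
    note: str = POINTWISE_NOTE

    @property
    def upper_p(self) -> np.ndarray:
        return (self.count_ge + 1.0) / (self.n_perm + 1.0)

    @property
    def lower_p(self) -> np.ndarray:
        return (self.count_le + 1.0) / (self.n_perm + 1.0)

    def classification(self) -> np.ndarray:
        return classify_cells(self)


def classify_cells(result: PermutationResult) -> np.ndarray:
    """(ny, nx) int grid: +1 hot, -1 cold, 0 neutral; masked cells neutral."""
    hot = result.upper_p <= result.alpha
    cold = result.lower_p <= result.alpha
    both = hot & cold
    if np.any(both):  # degenerate permutation distribution; stay neutral
        hot = hot & ~both
        cold = cold & ~both
    out = np.zeros(hot.shape, dtype=int)
    out[hot] = 1
    out[cold] = -1
    mask = result.observed.grid.mask
    if mask is not None:
        out[mask] = 0
    return out


def permutation_null(endog, coords, grid: Grid, span: float, exog=None,
                     covariate_profile=None, n_perm: int = 999, seed: int = 0,
                     degree: int = 1, alpha: float = 0.025,
                     max_failure_frac: float = 0.05, exog_names=None,
                     fit_kwargs: dict | None = None) -> PermutationResult:
    """Pointwise permutation distribution of the local odds ratios.

    Conditions on the residential locations (and attached covariates) and
    randomizes the case labels ``n_perm`` times; each permutation refits the
    model at the *fixed* span and re-predicts the OR grid.  Failed permutation
    fits are resampled; more than ``max_failure_frac`` failures aborts.
    Deterministic given ``seed``.
    """
    y = np.asarray(endog, dtype=float)
    coords = np.asarray(coords, dtype=float)
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("compute_edf", False)
    smoother = Loess2D(span, degree)
    ws_train = smoother.workspace(coords)
    ws_grid = smoother.workspace(coords, grid.centers())

    def _fit_or(labels) -> ORGrid:
        model = SpatialLogitGAM(labels, coords, exog=exog, span=span,
                                degree=degree, exog_names=exog_names)
        res = model.fit(workspace=ws_train, **fit_kwargs)
        null = fit_null(labels)
        return predict_or_map(res, null, grid,
                              covariate_profile=covariate_profile, workspace=ws_grid)

    observed = _fit_or(y)
    if not np.all(np.isfinite(observed.odds_ratio)):
        raise RuntimeError("observed OR map contains non-finite values")

    rng = np.random.default_rng(seed)
    count_ge = np.zeros(observed.odds_ratio.shape, dtype=np.int64)
    count_le = np.zeros_like(count_ge)
    done = 0
    failed = 0
    max_failures = max(1, int(np.ceil(max_failure_frac * n_perm)))
    while done < n_perm:
        labels = rng.permutation(y)
        try:
            perm = _fit_or(labels)
            if not np.all(np.isfinite(perm.odds_ratio)):
                raise RuntimeError("non-finite permuted OR map")
        except Exception as exc:  # noqa: BLE001 - resample failed permutations
            failed += 1
            if failed > max_failures:
                raise RuntimeError(
                    f"more than {max_failure_frac:.0%} of permutation fits "
                    f"failed (last error: {exc})"
                ) from exc
            warnings.warn(f"permutation fit failed ({exc}); resampled",
                          RuntimeWarning, stacklevel=2)
            continue
        count_ge += perm.odds_ratio >= observed.odds_ratio
        count_le += perm.odds_ratio <= observed.odds_ratio
        done += 1
    return PermutationResult(n_perm=n_perm, seed=int(seed), alpha=alpha,
                             observed=observed, count_ge=count_ge,
                             count_le=count_le, n_failed=failed)


@dataclass
class ClusterContour:
    """Boundary polyline of a hot ('high') or cold ('low') region, in data
    coordinates."""

    kind: str  # "high" | "low"
    vertices: np.ndarray  # (m, 2) x,y
    closed: bool = True


def extract_contours(classification: np.ndarray, grid: Grid) -> list[ClusterContour]:
    """Marching-squares boundaries of the hot and cold regions.

    One contour per connected boundary component; an all-neutral grid yields
    an empty list.
    """
    from skimage import measure

    out: list[ClusterContour] = []
    for kind, target in (("high", 1), ("low", -1)):
        indicator = (classification == target).astype(float)
        if indicator.sum() == 0:
            continue
        for cont in measure.find_contours(indicator, 0.5):
            # (row, col) index space -> data coordinates at cell centers
            xs = grid.bbox[0] + (cont[:, 1] + 0.5) * grid.dx
            ys = grid.bbox[1] + (cont[:, 0] + 0.5) * grid.dy
            verts = np.column_stack([xs, ys])
            closed = bool(np.allclose(cont[0], cont[-1]))
            out.append(ClusterContour(kind=kind, vertices=verts, closed=closed))
    return out


def contours_to_geojson(contours: list[ClusterContour], path=None) -> dict:
    """Contours as a GeoJSON FeatureCollection (closed rings as Polygons)."""
    features = []
    for c in contours:
        coords = [[float(x), float(y)] for x, y in c.vertices]
        if c.closed and len(coords) >= 4:
            geom = {"type": "Polygon", "coordinates": [coords]}
        else:
            geom = {"type": "LineString", "coordinates": coords}
        features.append({
            "type": "Feature",
            "properties": {"class": c.kind, "inference": POINTWISE_NOTE},
            "geometry": geom,
        })
    gj = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(gj, fh, sort_keys=True)
    return gj


def plot_or_map(or_grid: ORGrid, classification: np.ndarray | None = None,
                ax=None, cmap: str = "RdBu_r", title: str | None = None):
    """Render the OR map with white (hot) / dashed black (cold) contour
    styling.  Returns the matplotlib axes."""
    import matplotlib.colors as mcolors
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    x0, y0, x1, y1 = or_grid.grid.bbox
    vals = np.ma.masked_array(or_grid.odds_ratio,
                              mask=or_grid.grid.mask if or_grid.grid.mask is not None else False)
    vmax = float(np.nanmax(np.abs(np.log(vals))))
    if vmax <= 0:
        vmax = np.log(2.0)
    im = ax.imshow(vals, origin="lower", extent=(x0, x1, y0, y1), cmap=cmap,
                   norm=mcolors.LogNorm(vmin=np.exp(-vmax), vmax=np.exp(vmax)),
                   aspect="auto")
    plt.colorbar(im, ax=ax, label="local odds ratio (vs whole study area)")
    if classification is not None:
        for c in extract_contours(classification, or_grid.grid):
            if c.kind == "high":
                ax.plot(c.vertices[:, 0], c.vertices[:, 1], color="white",
                        linestyle="-", linewidth=1.5)
            else:
                ax.plot(c.vertices[:, 0], c.vertices[:, 1], color="black",
                        linestyle="--", linewidth=1.5)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    if title:
        ax.set_title(title)
    ax.text(0.01, 0.01, "pointwise inference", transform=ax.transAxes,
            fontsize=7, color="gray")
    return ax
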