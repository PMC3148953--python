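import math

import numpy as np
import pandas as pd
import pytest


def brute_force_loess(train_points, y, eval_points, span, prior_weights=None):
    """Independent loess oracle: per evaluation point, an explicit weighted
    least-squares solve on a locally centered degree-1 design.

    Deliberately parameterized differently from the package implementation
    (local centering vs global standardized design) so agreement is a real
    cross-check.
    """
    train_points = np.asarray(train_points, float)
    eval_points = np.asarray(eval_points, float)
    y = np.asarray(y, float)
    n = len(train_points)
    k = max(3, math.ceil(span * n - 1e-9))
    k = min(k, n)
    w0 = np.ones(n) if prior_weights is None else np.asarray(prior_weights, float)
    out = np.empty(len(eval_points))
    for i, pt in enumerate(eval_points):
        d = np.hypot(train_points[:, 0] - pt[0], train_points[:, 1] - pt[1])
        d_k = np.sort(d)[k - 1]
        if d_k == 0:
            tw = np.where(d == 0, 1.0, 0.0)
        else:
            tw = np.where(d < d_k, (1.0 - (d / d_k) ** 3) ** 3, 0.0)
        w = tw * w0
        X = np.column_stack([np.ones(n), train_points[:, 0] - pt[0],
                             train_points[:, 1] - pt[1]])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        out[i] = beta[0]
    return out


@pytest.fixture(scope="session")
def eight_points():
    """Fixed 8-point planar configuration with a seeded response."""
    pts = np.array([
        [0.0, 0.0], [1.0, 0.2], [2.1, 1.0], [0.4, 2.0],
        [1.5, 1.7], [2.8, 0.3], [0.9, 2.9], [2.2, 2.4],
    ])
    rng = np.random.default_rng(42)
    y = rng.normal(size=8)
    return pts, y


@pytest.fixture(scope="session")
def fifty_points():
    rng = np.random.default_rng(7)
    pts = rng.uniform(0.0, 10.0, size=(50, 2))
    y = np.sin(pts[:, 0]) + 0.3 * pts[:, 1] + rng.normal(0, 0.2, size=50)
    return pts, y


@pytest.fixture(scope="session")
def logistic_fixture_50():
    """50-subject binary-outcome fixture with two covariates."""
    rng = np.random.default_rng(19)
    n = 50
    x1 = rng.normal(size=n)
    x2 = rng.integers(0, 2, size=n).astype(float)
    eta = -0.3 + 0.8 * x1 - 0.5 * x2
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return y, np.column_stack([x1, x2])


@pytest.fixture(scope="session")
def tiny_study():
    """Small synthetic study with one bump at lag 20, single center."""
    from lagclust.simulate import CovariateEffects, GaussianBump, ScenarioConfig, generate_study

    cfg = ScenarioConfig(
        n_cases=150, n_controls=150, centers=("c1",),
        bumps=(GaussianBump(30.0, 30.0, 15.0, 1.2),), active_lag_years=20,
        covariate_effects=CovariateEffects.null(),
        matching_strata=("age_group", "sex"),
        match_level_probs={"exact": 1.0, "intersection": 0.0, "zip_centroid": 0.0,
                           "place": 0.0, "county_centroid": 0.0, "state_centroid": 0.0},
        seed=21,
    )
    return cfg, *generate_study(cfg)


@pytest.fixture
def simple_residences():
    """The two-residence subject of the lag-selection examples."""
    return pd.DataFrame({
        "subject_id": ["s1", "s1"],
        "move_in_year": [1975, 1985],
        "move_out_year": [1985, 2000],
        "x": [1.0, 2.0],
        "y": [1.0, 2.0],
        "match_level": ["exact", "exact"],
        "in_area": [True, True],
    })
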