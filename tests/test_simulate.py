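import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from lagclust.histories import apply_inclusion_filters, build_lagged_points
from lagclust.simulate import (
    CovariateEffects,
    GaussianBump,
    MatchingError,
    ScenarioConfig,
    TrueSurface,
    evaluate_true_surface,
    generate_study,
    largest_remainder,
)

ALL_EXACT = {"exact": 1.0, "intersection": 0.0, "zip_centroid": 0.0,
             "place": 0.0, "county_centroid": 0.0, "state_centroid": 0.0}


class TestTrueSurface:
    def test_bump_center_equals_amplitude(self):
        s = TrueSurface((GaussianBump(5.0, 5.0, 2.0, 1.0),))
        assert evaluate_true_surface(s, [[5.0, 5.0]])[0] == pytest.approx(1.0)

    def test_far_field_is_zero(self):
        s = TrueSurface((GaussianBump(5.0, 5.0, 2.0, 1.0),))
        assert evaluate_true_surface(s, [[1e6, 1e6]])[0] == pytest.approx(0.0, abs=1e-12)

    def test_one_radius_decay(self):
        s = TrueSurface((GaussianBump(0.0, 0.0, 2.0, 1.0),))
        val = evaluate_true_surface(s, [[2.0, 0.0]])[0]
        assert val == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_bumps_superpose(self):
        s = TrueSurface((GaussianBump(0, 0, 1, 1.0), GaussianBump(0, 0, 1, 0.5)))
        assert evaluate_true_surface(s, [[0.0, 0.0]])[0] == pytest.approx(1.5)

    def test_invalid_bump_rejected(self):
        with pytest.raises(ValueError):
            GaussianBump(0, 0, -1.0, 1.0)
        with pytest.raises(ValueError):
            GaussianBump(0, 0, 1.0, np.inf)


class TestLargestRemainder:
    def test_exact_apportionment(self):
        quotas = largest_remainder(10, {"a": 1, "b": 1, "c": 1})
        assert sum(quotas.values()) == 10
        assert sorted(quotas.values()) == [3, 3, 4]

    def test_deterministic_tie_break_by_key(self):
        q1 = largest_remainder(1, {"a": 1, "b": 1})
        q2 = largest_remainder(1, {"a": 1, "b": 1})
        assert q1 == q2 == {"a": 1, "b": 0}

    def test_proportionality(self):
        quotas = largest_remainder(100, {"a": 30, "b": 70})
        assert quotas == {"a": 30, "b": 70}


class TestGenerateStudy:
    def test_seeded_determinism(self):
        cfg = ScenarioConfig(n_cases=80, n_controls=80, centers=("c1",), seed=9)
        s1, r1 = generate_study(cfg)
        s2, r2 = generate_study(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_different_seed_differs(self):
        from dataclasses import replace

        cfg = ScenarioConfig(n_cases=80, n_controls=80, centers=("c1",), seed=9)
        s1, _ = generate_study(cfg)
        s2, _ = generate_study(replace(cfg, seed=10))
        assert not s1.equals(s2)

    def test_null_scenario_case_fraction(self):
        cfg = ScenarioConfig(n_cases=500, n_controls=500, centers=("c1",),
                             seed=2).null_variant()
        subjects, _ = generate_study(cfg)
        n_cases = int(subjects["case"].sum())
        # realized cases ~ Binomial(1000, 0.5) by construction of the labels
        assert abs(n_cases - 500) < 4 * np.sqrt(1000 * 0.25)

    def test_histories_tile_window_without_gaps(self):
        cfg = ScenarioConfig(n_cases=60, n_controls=60, centers=("c1",), seed=4,
                             match_level_probs=ALL_EXACT)
        subjects, residences = generate_study(cfg)
        _, _, rep = apply_inclusion_filters(subjects, residences, window_years=20)
        assert rep.n_subjects_removed_incomplete_coverage == 0
        grp = residences.groupby("subject_id")
        assert (grp["move_in_year"].min() == 1980).all()
        assert (grp["move_out_year"].max() == 2000).all()

    def test_mobility_distribution(self):
        cfg = ScenarioConfig(n_cases=2500, n_controls=2500, centers=("c1",),
                             seed=5).null_variant()
        subjects, residences = generate_study(cfg)
        counts = residences.groupby("subject_id").size()
        observed = counts.value_counts().reindex([1, 2, 3], fill_value=0).to_numpy()
        expected = np.array([0.25, 0.50, 0.25]) * len(subjects)
        chi2, p = stats.chisquare(observed, expected)
        assert p > 1e-3
        assert counts.median() == 2

    def test_match_level_proportions(self):
        cfg = ScenarioConfig(n_cases=2500, n_controls=2500, centers=("c1",), seed=6)
        _, residences = generate_study(cfg)
        frac = residences["match_level"].value_counts(normalize=True)
        assert frac["intersection"] == pytest.approx(0.088, abs=0.01)
        assert frac["zip_centroid"] == pytest.approx(0.05, abs=0.01)

    def test_controls_match_realized_case_margins(self):
        cfg = ScenarioConfig(n_cases=300, n_controls=250, centers=("c1", "c2"),
                             matching_strata=("age_group", "sex", "center"), seed=7)
        subjects, _ = generate_study(cfg)
        strata = ["age_group", "sex", "center"]
        cases = subjects[subjects["case"] == 1]
        controls = subjects[subjects["case"] == 0]
        margins = {tuple(map(str, k)) if isinstance(k, tuple) else (str(k),): v
                   for k, v in cases.groupby(strata).size().items()}
        quotas = largest_remainder(250, margins)
        observed = {tuple(map(str, k)): v for k, v in controls.groupby(strata).size().items()}
        for key, q in quotas.items():
            assert observed.get(key, 0) == q
        assert len(controls) == 250

    def test_infeasible_matching_names_stratum(self):
        # a near-certain disease surface leaves almost no disease-free
        # candidates, exhausting the per-stratum sampling budget
        cfg = ScenarioConfig(
            n_cases=20, n_controls=20, centers=("c1",),
            bumps=(GaussianBump(50.0, 50.0, 1e6, 30.0),), active_lag_years=20,
            covariate_effects=CovariateEffects.null(),
            matching_strata=("sex",), seed=8,
        )
        with pytest.raises(MatchingError, match="stratum"):
            generate_study(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_cases=0)
        with pytest.raises(ValueError):
            ScenarioConfig(bbox=(0, 0, 0, 10))
        with pytest.raises(ValueError):
            ScenarioConfig(mobility={1: 0.5, 2: 0.4})


class TestAmplitudeRecovery:
    def test_empirical_logodds_contrast_matches_generating_surface(self):
        """A single bump of amplitude 1.0 at lag 20 must reproduce itself in
        the empirical case/control 2x2 log odds at the lag-20 residence.

        Oracle: the expected in/out log odds ratio is computed by numerical
        integration of the generating logistic model over the two regions
        (independent of the sampling code); the empirical contrast from a
        n = 5,000 study must agree within Monte-Carlo error.
        """
        amp, radius, cx, cy = 1.0, 15.0, 40.0, 40.0
        cfg = ScenarioConfig(
            n_cases=2500, n_controls=2500, centers=("c1",),
            bumps=(GaussianBump(cx, cy, radius, amp),), active_lag_years=20,
            covariate_effects=CovariateEffects.null(),
            match_level_probs=ALL_EXACT, seed=13,
        )
        subjects, residences = generate_study(cfg)
        pts = build_lagged_points(subjects, residences, 20)
        d = np.hypot(pts["x"] - cx, pts["y"] - cy)
        inner = d < 0.5 * radius
        outer = d > 2.5 * radius
        tab = np.array([
            [pts.loc[inner, "case"].sum(), (1 - pts.loc[inner, "case"]).sum()],
            [pts.loc[outer, "case"].sum(), (1 - pts.loc[outer, "case"]).sum()],
        ], float)
        log_or = np.log(tab[0, 0] * tab[1, 1] / (tab[0, 1] * tab[1, 0]))

        # independent oracle: integrate p(s) and 1-p(s) over the two regions
        b0 = cfg.baseline_logodds
        gx, gy = np.meshgrid(np.linspace(0, 100, 601), np.linspace(0, 100, 601))
        z = amp * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * radius**2))
        p = expit(b0 + z)
        dist = np.hypot(gx - cx, gy - cy)
        m_in, m_out = dist < 0.5 * radius, dist > 2.5 * radius
        odds_in = p[m_in].sum() / (1 - p[m_in]).sum()
        odds_out = p[m_out].sum() / (1 - p[m_out]).sum()
        expected = np.log(odds_in / odds_out)
        assert expected == pytest.approx(amp, abs=0.1)  # near-center contrast ~ amplitude
        se = np.sqrt((1.0 / tab).sum())
        assert abs(log_or - expected) < 3.5 * se
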