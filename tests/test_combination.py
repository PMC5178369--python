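"""Combination index, interaction classification, isobolograms."""

import warnings

import numpy as np
import pytest
from scipy.optimize import brentq

from drugcombo import (
    MedianEffectFit,
    build_record,
    classify_interaction,
    combination_index,
    derive_equieffective_doses,
    effect_at_dose,
    place_on_isobologram,
    theoretical_isobologram,
)
from drugcombo.combination import EffectRangeError, round_half_up

# Published preincubation-scheme CI table:
# (D1 CDDP, D2 alpha-M, Dx1, Dx2, control growth %, printed CI)
PUBLISHED_ROWS = [
    (2.0, 5.0, 6.6, 8.4, 89.8, 1.1),
    (2.0, 10.0, 20.7, 13.8, 73.0, 0.8),
    (5.0, 10.0, 25.4, 14.8, 68.0, 1.0),
    (2.0, 15.0, 37.9, 16.5, 56.1, 1.0),
]


class TestCombinationIndex:
    @pytest.mark.parametrize(
        "d1, d2, dx1, dx2, expected_1dp",
        [
            (2.0, 5.0, 6.6, 8.4, 1.1),
            (5.0, 10.0, 25.4, 14.8, 1.0),
            (2.0, 15.0, 37.9, 16.5, 1.0),
        ],
    )
    def test_published_rows_reproduced(self, d1, d2, dx1, dx2, expected_1dp):
        ci = combination_index(d1, d2, dx1, dx2, alpha=1)
        assert round_half_up(ci, 1) == expected_1dp

    def test_published_row_two_is_arithmetically_inconsistent(self):
        """The (2, 10) row evaluates to 0.891 -> 0.9, not the printed 0.8."""
        ci = combination_index(2.0, 10.0, 20.7, 13.8, alpha=1)
        assert ci == pytest.approx(0.8913, abs=5e-4)
        assert round_half_up(ci, 1) == 0.9

    @pytest.mark.parametrize("alpha", [0, 1])
    def test_single_agent_limit(self, alpha):
        assert combination_index(7.3, 0.0, 7.3, 5.0, alpha=alpha) == 1.0

    def test_alpha_term_strictly_positive(self):
        ci0 = combination_index(3.0, 4.0, 10.0, 12.0, alpha=0)
        ci1 = combination_index(3.0, 4.0, 10.0, 12.0, alpha=1)
        assert ci1 == ci0 + (3.0 * 4.0) / (10.0 * 12.0)
        assert ci1 > ci0

    def test_unit_rescaling_invariance(self):
        base = combination_index(2.0, 5.0, 6.6, 8.4)
        assert combination_index(2000.0, 5.0, 6600.0, 8.4) == pytest.approx(base)
        assert combination_index(2.0, 0.005, 6.6, 0.0084) == pytest.approx(base)

    def test_nonpositive_equieffective_dose_rejected(self):
        with pytest.raises(ValueError, match="Dx1"):
            combination_index(1.0, 1.0, 0.0, 2.0)
        with pytest.raises(ValueError, match="Dx2"):
            combination_index(1.0, 1.0, 2.0, -1.0)

    def test_alpha_validated(self):
        with pytest.raises(ValueError, match="alpha"):
            combination_index(1.0, 1.0, 2.0, 2.0, alpha=2)


class TestClassification:
    @pytest.mark.parametrize(
        "ci, call",
        [
            (1.006, "additive"),     # prints as 1.0
            (0.8, "synergistic"),
            (1.0, "additive"),
            (1.078, "antagonistic"), # prints as 1.1
            (0.951, "additive"),
            (1.05, "antagonistic"),  # half-up tie rounds away from 1.0
        ],
    )
    def test_one_decimal_rule(self, ci, call):
        assert classify_interaction(ci) == call

    def test_exact_mode(self):
        assert classify_interaction(1.006, tol=0.0) == "antagonistic"
        assert classify_interaction(1.0, tol=0.0) == "additive"
        assert classify_interaction(0.999, tol=0.0) == "synergistic"

    def test_invalid_ci(self):
        with pytest.raises(ValueError):
            classify_interaction(0.0)


class TestEquieffectiveDoses:
    def test_half_effect_returns_dm(self, cddp_fit, am_fit):
        dx1, dx2 = derive_equieffective_doses(2.0, 5.0, 50.0, cddp_fit, am_fit)
        assert dx1 == pytest.approx(cddp_fit.dm)
        assert dx2 == pytest.approx(am_fit.dm)

    def test_matches_bisection_of_forward_model(self, cddp_fit, am_fit):
        """Inverting the fit agrees with root-finding effect_at_dose."""
        for growth in (89.8, 73.0, 68.0, 56.1, 20.0):
            fa = 1.0 - growth / 100.0
            dx1, dx2 = derive_equieffective_doses(
                1.0, 1.0, growth, cddp_fit, am_fit
            )
            for fit, dx in ((cddp_fit, dx1), (am_fit, dx2)):
                root = brentq(
                    lambda d: effect_at_dose(fit, d) - fa, 1e-9, 1e6,
                    xtol=1e-12,
                )
                assert dx == pytest.approx(root, abs=1e-8)

    @pytest.mark.parametrize("growth", [0.0, 100.0, 120.0])
    def test_extreme_effect_flagged(self, growth, cddp_fit, am_fit):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # growth > 100 also warns
            with pytest.raises(EffectRangeError):
                derive_equieffective_doses(2.0, 5.0, growth, cddp_fit, am_fit)


class TestIsobologram:
    def test_theoretical_line_endpoints_and_midpoint(self):
        pairs = theoretical_isobologram(29.7, 19.1, n_points=3)
        np.testing.assert_allclose(pairs[0], [0.0, 19.1])
        np.testing.assert_allclose(pairs[1], [14.85, 9.55])
        np.testing.assert_allclose(pairs[2], [29.7, 0.0])

    def test_every_pair_sits_on_the_additivity_line(self):
        pairs = theoretical_isobologram(29.7, 19.1, n_points=17)
        s = pairs[:, 0] / 29.7 + pairs[:, 1] / 19.1
        np.testing.assert_allclose(s, 1.0)

    def test_placement_basic(self):
        assert place_on_isobologram(14.85, 9.55, 29.7, 19.1).position == "on_line"
        assert place_on_isobologram(0.0, 0.0, 29.7, 19.1).position == "below_line"
        assert place_on_isobologram(29.7, 19.1, 29.7, 19.1).position == "above_line"

    def test_placement_matches_alpha0_ci_classification(self):
        """For IC50-equieffective points the coordinate sum equals the
        alpha=0 CI, so placement and classification must agree."""
        rng = np.random.default_rng(7)
        side_of = {
            "synergistic": "below_line",
            "additive": "on_line",
            "antagonistic": "above_line",
        }
        for _ in range(200):
            d1 = rng.uniform(0.5, 40.0)
            d2 = rng.uniform(0.5, 30.0)
            ci = combination_index(d1, d2, 29.7, 19.1, alpha=0)
            s = d1 / 29.7 + d2 / 19.1
            assert ci == pytest.approx(s, abs=1e-12)
            call = classify_interaction(ci, tol=0.05)
            assert place_on_isobologram(
                d1, d2, 29.7, 19.1, tol=0.05
            ).position == side_of[call]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            theoretical_isobologram(-1.0, 19.1)
        with pytest.raises(ValueError):
            theoretical_isobologram(29.7, 19.1, n_points=1)
        with pytest.raises(ValueError):
            place_on_isobologram(1.0, 1.0, 0.0, 19.1)


class TestBuildRecord:
    def test_replication_mode(self):
        rec = build_record(2.0, 5.0, dx1=6.6, dx2=8.4, control_growth_pct=89.8)
        assert round_half_up(rec.ci, 1) == 1.1
        assert rec.call == "antagonistic"

    def test_pipeline_mode_additive_point(self, cddp_fit, am_fit):
        rec = build_record(
            14.85, 9.55, control_growth_pct=50.0,
            fit1=cddp_fit, fit2=am_fit, alpha=0,
        )
        assert rec.ci == pytest.approx(1.0)
        assert rec.call == "additive"

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError, match="required"):
            build_record(2.0, 5.0)
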