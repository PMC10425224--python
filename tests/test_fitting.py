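"""Least-squares fitting, model selection and batch WSRI fitting."""

import numpy as np
import pytest

from cottonwl import (
    DurationResponseModel,
    ResponseFamily,
    compute_wsri,
    evaluate_trajectory,
    fit_family,
    fit_wsri_table,
    generate_wsri_points,
    r_squared,
    select_model,
)
from cottonwl.errors import (
    InitializationError,
    RankError,
    UndefinedRSquaredError,
)

DESIGN = np.arange(0.0, 15.0, 2.0)


class TestFitFamily:
    def test_exact_line(self):
        pts = [(0, 1.0), (2, 0.9), (4, 0.8), (6, 0.7)]
        res = fit_family(pts, "linear")
        np.testing.assert_allclose(res.params, [-0.05, 1.0], atol=1e-12)
        np.testing.assert_allclose(res.resid, 0.0, atol=1e-12)

    @pytest.mark.parametrize("code", [
        "PH", "SD", "LN", "LA", "DWL", "DWS", "DWSh", "DWT", "RL", "RSA", "RV",
        "RWD", "RT", "RC", "CHL", "FL", "AN", "NBI", "P", "E", "Ci/Ca", "Gs",
        "ETR", "phiPS2", "NPQ", "Fv'/Fm'",
    ])
    def test_noiseless_recovery_every_registry_entry(self, registry, code):
        curve = registry[code]
        pts = generate_wsri_points(code, DESIGN, registry=registry)
        res = fit_family([tuple(p) for p in pts], curve.family)
        tol = 1e-4 if curve.family is ResponseFamily.EXP_DECAY else 1e-6
        np.testing.assert_allclose(res.params, curve.coefficients, atol=tol)
        assert res.converged

    def test_matches_polyfit_oracle_on_noisy_data(self):
        rng = np.random.default_rng(5)
        y = 1.0 - 0.04 * DESIGN + 0.002 * DESIGN**2 + rng.normal(0, 0.02, DESIGN.size)
        res = fit_family(list(zip(DESIGN, y)), "quadratic")
        np.testing.assert_allclose(res.params, np.polyfit(DESIGN, y, 2), atol=1e-10)

    def test_matches_grid_search_oracle(self):
        # brute-force SSE minimisation over a coefficient grid around truth
        pts = np.array([(0, 1.02), (4, 0.80), (8, 0.63), (12, 0.41)])
        res = fit_family([tuple(p) for p in pts], "linear")
        slopes = np.linspace(res.params[0] - 0.01, res.params[0] + 0.01, 81)
        intercepts = np.linspace(res.params[1] - 0.01, res.params[1] + 0.01, 81)
        sse = lambda m, b: np.sum((pts[:, 1] - (m * pts[:, 0] + b)) ** 2)
        best = min(
            ((m, b) for m in slopes for b in intercepts), key=lambda p: sse(*p)
        )
        np.testing.assert_allclose(res.params, best, atol=2.6e-4)  # grid resolution

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        y = 0.95 * np.exp(-0.12 * DESIGN) + rng.normal(0, 0.01, DESIGN.size)
        pts = list(zip(DESIGN, y))
        res1 = fit_family(pts, "exp_decay")
        perm = rng.permutation(len(pts))
        res2 = fit_family([pts[i] for i in perm], "exp_decay")
        np.testing.assert_allclose(res1.params, res2.params, rtol=1e-8)

    def test_rank_error_on_too_few_distinct_durations(self):
        with pytest.raises(RankError):
            fit_family([(0, 1.0), (0, 1.1), (0, 0.9)], "quadratic")

    def test_exp_decay_needs_a_positive_index(self):
        with pytest.raises(InitializationError):
            fit_family([(0, -1.0), (2, -0.5), (4, 0.0)], "exp_decay")

    def test_inverse_variance_weights_accepted(self):
        pts = [(0, 1.0), (2, 0.9), (4, 0.85), (6, 0.7)]
        res = fit_family(pts, "linear", weights=[4.0, 1.0, 1.0, 4.0])
        assert res.params[0] < 0  # sane weighted fit

    def test_standard_errors_scale_with_noise(self):
        rng = np.random.default_rng(2)
        lo = fit_family(list(zip(DESIGN, 1 - 0.05 * DESIGN + rng.normal(0, 0.01, 8))), "linear")
        hi = fit_family(list(zip(DESIGN, 1 - 0.05 * DESIGN + rng.normal(0, 0.1, 8))), "linear")
        assert np.all(hi.bse > lo.bse)


class TestRSquared:
    def test_perfect_fit_is_one(self, registry):
        pts = generate_wsri_points("LA", DESIGN, registry=registry)
        assert r_squared([tuple(p) for p in pts], registry["LA"]) == pytest.approx(1.0, abs=1e-8)

    def test_constant_indices_undefined(self, registry):
        with pytest.raises(UndefinedRSquaredError):
            r_squared([(0, 1.0), (2, 1.0), (4, 1.0)], registry["PH"])

    def test_bad_curve_can_go_negative(self, registry):
        pts = [(0, 1.0), (7, 0.5), (14, 0.0)]
        assert r_squared(pts, registry["NPQ"]) < 0


class TestSelectModel:
    def test_strong_curvature_selects_quadratic(self, registry):
        pts = generate_wsri_points("PH", DESIGN, registry=registry)
        res = select_model([tuple(p) for p in pts])
        assert res.family is ResponseFamily.QUADRATIC

    def test_exact_line_selects_linear_by_parsimony(self):
        pts = [(d, 1.0 - 0.05 * d) for d in DESIGN]
        res = select_model(pts)
        assert res.family is ResponseFamily.LINEAR
        assert res.selection["quadratic"] <= 1.0 + 1e-12

    def test_three_points_rejected(self):
        with pytest.raises(RankError):
            select_model([(0, 1.0), (2, 0.9), (4, 0.8)])


class TestFitWsriTable:
    def test_noiseless_round_trip_recovers_rescaled_curves(self, registry, noiseless_table):
        """cv=0 generation -> WSRI -> refit returns each generating curve up
        to the 1/curve(0) renormalisation that the index definition applies
        (clamping perturbs only RC, checked separately)."""
        wsri = compute_wsri(noiseless_table)
        fits = fit_wsri_table(wsri, mode="registry_families", registry=registry)
        assert set(fits) == set(registry.codes)
        for code, res in fits.items():
            if code == "RC":
                continue  # its curve goes negative at 14 d and is clamped
            curve = registry[code]
            y0 = curve(0.0)
            if curve.family is ResponseFamily.EXP_DECAY:
                expected = (curve.coefficients[0] / y0, curve.coefficients[1])
            else:
                expected = tuple(c / y0 for c in curve.coefficients)
            np.testing.assert_allclose(res.params, expected, atol=1e-4)

    def test_clamped_rc_fit_matches_polyfit_oracle(self, registry, noiseless_table):
        wsri = compute_wsri(noiseless_table)
        x, y = wsri.points("RC")
        res = fit_wsri_table(wsri, registry=registry)["RC"]
        np.testing.assert_allclose(res.params, np.polyfit(x, y, 2), atol=1e-10)

    def test_auto_select_picks_exp_decay_for_leaf_area(self, registry):
        from cottonwl.wsri import WsriTable
        import pandas as pd

        frames = []
        for code in ("LA", "PH", "RL"):
            pts = generate_wsri_points(code, DESIGN, registry=registry)
            frames.append(pd.DataFrame({"parameter": code, "duration": pts[:, 0], "index": pts[:, 1]}))
        wsri = WsriTable(entries=pd.concat(frames, ignore_index=True))
        fits = fit_wsri_table(wsri, mode="auto_select")
        assert fits["LA"].family is ResponseFamily.EXP_DECAY
        assert fits["RL"].family is ResponseFamily.LINEAR

    def test_too_few_durations_rejected(self, registry):
        from cottonwl.wsri import WsriTable
        import pandas as pd

        wsri = WsriTable(entries=pd.DataFrame(
            {"parameter": "PH", "duration": [0, 2, 4], "index": [1.0, 0.9, 0.8]}
        ))
        with pytest.raises(RankError):
            fit_wsri_table(wsri, registry=registry)

    def test_unknown_parameter_rejected_in_registry_mode(self, registry):
        from cottonwl.wsri import WsriTable
        import pandas as pd

        wsri = WsriTable(entries=pd.DataFrame(
            {"parameter": "NOPE", "duration": DESIGN, "index": 1 - 0.01 * DESIGN}
        ))
        with pytest.raises(KeyError):
            fit_wsri_table(wsri, registry=registry)


class TestNoisyRecovery:
    def test_slope_within_three_standard_errors(self, registry):
        """With sd-0.03 Gaussian noise on replicate indices at the 8 design
        durations (5 replicate means), the recovered linear slope lies within
        3 SE of truth in at least 95% of 200 Monte-Carlo repetitions."""
        curve = registry["RL"]
        truth = curve.coefficients[0]
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            reps = evaluate_trajectory(curve, DESIGN)[:, None] + rng.normal(
                0, 0.03, size=(DESIGN.size, 5)
            )
            y = reps.mean(axis=1)
            res = fit_family(list(zip(DESIGN, y)), "linear")
            if abs(res.params[0] - truth) <= 3 * res.bse[0]:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_exp_rate_within_three_standard_errors(self, registry):
        curve = registry["LA"]
        truth = curve.coefficients[1]
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            reps = evaluate_trajectory(curve, DESIGN)[:, None] + rng.normal(
                0, 0.03, size=(DESIGN.size, 5)
            )
            res = fit_family(list(zip(DESIGN, reps.mean(axis=1))), "exp_decay")
            if abs(res.params[1] - truth) <= 3 * res.bse[1]:
                hits += 1
        assert hits / n_rep >= 0.95


class TestModelObjects:
    def test_from_dataframe_constructor(self, registry):
        import pandas as pd

        pts = generate_wsri_points("PH", DESIGN, registry=registry)
        df = pd.DataFrame({"duration": pts[:, 0], "index": pts[:, 1]})
        res = DurationResponseModel.from_dataframe(df, "quadratic").fit()
        np.testing.assert_allclose(res.params, registry["PH"].coefficients, atol=1e-8)

    def test_summary_contains_estimates_and_uncertainty(self, registry):
        pts = generate_wsri_points("PH", DESIGN, noise_sd=0.02, seed=3, registry=registry)
        res = fit_family([tuple(p) for p in pts], "quadratic", parameter_code="PH")
        text = res.summary()
        assert "PH" in text and "R-squared" in text and "std err" in text

    def test_results_curve_round_trips_through_evaluation(self, registry):
        pts = generate_wsri_points("LA", DESIGN, registry=registry)
        res = fit_family([tuple(p) for p in pts], "exp_decay")
        np.testing.assert_allclose(res.curve(DESIGN), res.predict(DESIGN), rtol=1e-12)
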