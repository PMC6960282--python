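"""Quartic/sigmoid fits, second-derivative roots, bootstrap estimator."""

import numpy as np
import pytest

from misig import (
    ANCHOR,
    InflectionConfig,
    MisigError,
    QuarticFit,
    ScatterParams,
    estimate_genus_inflection,
    fit_quartic,
    fit_sigmoid,
    make_genus_scatter,
    second_derivative_roots,
)


def _gompertz(x, y0, a, b, c):
    return y0 + a * np.exp(-b * np.exp(-c * np.asarray(x)))


class TestFitQuartic:
    def test_exact_polynomial_recovery(self):
        af = np.arange(0.1, 0.95, 0.1)
        ani = af**4 - 2 * af**3 + 80
        fit = fit_quartic(list(zip(af, ani)), include_anchor=False)
        assert fit.coefficients == pytest.approx((80, 0, 0, -2, 1), abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_perturbed_point_lowers_r2(self):
        af = np.arange(0.1, 0.95, 0.1)
        ani = af**4 - 2 * af**3 + 80
        ani[3] += 0.5
        fit = fit_quartic(list(zip(af, ani)), include_anchor=False)
        assert fit.r2 < 1.0

    def test_underdetermined(self):
        pts = [(0.1 * i, 70 + i) for i in range(5)]
        with pytest.raises(MisigError, match="underdetermined"):
            fit_quartic(pts, include_anchor=False)

    def test_degenerate_af(self):
        pts = [(0.2, 70 + i) for i in range(8)]
        with pytest.raises(MisigError, match="degenerate AF"):
            fit_quartic(pts, include_anchor=False)

    def test_anchor_appended_once(self):
        pts = [(0.1 * i, 70.0 + 3 * i) for i in range(1, 8)]
        fit = fit_quartic(pts, include_anchor=True)
        assert fit.n_points == len(pts) + 1
        fit2 = fit_quartic(pts + [ANCHOR], include_anchor=True)
        assert fit2.n_points == len(pts) + 1


class TestSecondDerivativeRoots:
    def test_analytic_quartic_roots(self):
        fit = QuarticFit((3, 0, 0, -2, 1), 1.0, 9, False)
        pair = second_derivative_roots(fit, (-0.5, 1.5))
        assert pair.first == (pytest.approx(0.0), pytest.approx(3.0))
        assert pair.second == (pytest.approx(1.0), pytest.approx(2.0))

    def test_cubic_single_root(self):
        fit = QuarticFit((0, 0, -3, 1, 0), 1.0, 9, False)  # f'' = 6x - 6
        pair = second_derivative_roots(fit, (0, 2))
        assert pair.first[0] == pytest.approx(1.0)
        assert pair.second is None

    def test_quadratic_has_no_inflection(self):
        fit = QuarticFit((1, 1, 1, 0, 0), 1.0, 9, False)
        with pytest.raises(MisigError, match="no inflection detected"):
            second_derivative_roots(fit, (0, 1))

    def test_roots_outside_range_rejected(self):
        fit = QuarticFit((3, 0, 0, -2, 1), 1.0, 9, False)  # roots at 0 and 1
        with pytest.raises(MisigError, match="no inflection detected"):
            second_derivative_roots(fit, (0.2, 0.8))


class TestFitSigmoid:
    def test_gompertz_noiseless_recovery(self):
        x = np.linspace(0.02, 1.0, 40)
        y = _gompertz(x, 70, 30, np.e, 4)
        fit = fit_sigmoid(list(zip(x, y)), "gompertz", include_anchor=False)
        af, ani = fit.analytic_inflection
        assert af == pytest.approx(0.25, abs=1e-6)
        assert ani == pytest.approx(70 + 30 / np.e, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_logistic_noiseless_recovery(self):
        x = np.linspace(0.02, 1.0, 40)
        y = 70 + 30 / (1 + np.exp(-15 * (x - 0.33)))
        fit = fit_sigmoid(list(zip(x, y)), "logistic", include_anchor=False)
        af, ani = fit.analytic_inflection
        assert af == pytest.approx(0.33, abs=1e-6)
        assert ani == pytest.approx(85.0, abs=1e-6)

    def test_zero_variance_fails(self):
        pts = [(0.1 * i, 80.0) for i in range(1, 9)]
        with pytest.raises(MisigError, match="fit failed"):
            fit_sigmoid(pts, "gompertz", include_anchor=False)

    @pytest.mark.parametrize("family", ["gompertz", "logistic"])
    def test_analytic_inflection_identity_numerically(self, family):
        """The closed-form inflection is where the fitted curve's second
        derivative changes sign."""
        res = make_genus_scatter(ScatterParams(seed=3))
        pts = [(a, v) for a, v, _ in res.points]
        fit = fit_sigmoid(pts, family, include_anchor=False)
        af_star, ani_star = fit.analytic_inflection
        h = 1e-5
        d2 = lambda x: (fit(x + h) - 2 * fit(x) + fit(x - h)) / h**2
        assert d2(af_star - 1e-3) * d2(af_star + 1e-3) < 0
        assert fit(af_star) == pytest.approx(ani_star, abs=1e-9)


class TestEstimateGenusInflection:
    def test_recovery_on_default_scatter(self):
        res = make_genus_scatter(ScatterParams(seed=7))
        pts = [(a, v) for a, v, _ in res.points]
        est = estimate_genus_inflection(pts, InflectionConfig(n_boot=200, seed=1))
        assert abs(est.af_star - res.truth["inflection_af"]) <= 0.05
        assert abs(est.ani_star - res.truth["inflection_ani"]) <= 1.0
        assert est.r2_quartic >= 0.90

    def test_high_noise_rejected(self):
        res = make_genus_scatter(ScatterParams(noise_sd_ani=15.0, seed=7))
        pts = [(a, v) for a, v, _ in res.points]
        est = estimate_genus_inflection(pts, InflectionConfig(n_boot=50, seed=1))
        assert est.r2_quartic < 0.90
        assert not est.accepted

    def test_accepted_flag_matches_definition(self):
        cfg = InflectionConfig(n_boot=50, seed=1)
        res = make_genus_scatter(ScatterParams(seed=7))
        est = estimate_genus_inflection([(a, v) for a, v, _ in res.points], cfg)
        agree = all(
            inf is not None
            and abs(inf[0] - est.af_star) <= cfg.agreement_tol_af
            and abs(inf[1] - est.ani_star) <= cfg.agreement_tol_ani
            for inf in est.sigmoid_inflections.values()
        )
        assert est.accepted == (est.r2_quartic >= cfg.r2_min and agree)

    def test_ci_nesting_and_determinism(self):
        res = make_genus_scatter(ScatterParams(seed=5))
        pts = [(a, v) for a, v, _ in res.points]
        cfg = InflectionConfig(n_boot=200, seed=42)
        est1 = estimate_genus_inflection(pts, cfg)
        est2 = estimate_genus_inflection(pts, cfg)
        assert est1 == est2
        lo95, hi95 = est1.ci95_af
        lo99, hi99 = est1.ci99_af
        assert lo99 <= lo95 <= hi95 <= hi99
        assert lo95 <= est1.af_star <= hi95
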