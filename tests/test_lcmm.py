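"""Tests for the latent-class mixed model: basis, likelihood oracles,
EM behaviour, classification, and model search."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from swimtraj.lcmm import (
    LCMMParams,
    LCMMSpec,
    TrajectoryData,
    assign_and_summarize,
    fit,
    marginal_loglik,
    model_search,
    posterior_probs,
    spline_basis,
    weighted_class_means,
    NaturalSplineBasis,
)


def make_data(series, knots=2, random_effects="intercept"):
    return TrajectoryData(series, knots, random_effects)


def quadrature_loglik(params: LCMMParams, series) -> float:
    """Independent oracle: per subject, integrate the random intercept
    out of the conditional Gaussian likelihood with adaptive quadrature
    and mix over classes."""
    total = 0.0
    sd_b_base = math.sqrt(params.B[0, 0])
    pis = params.pi
    for t, y in series:
        X = _oracle_basis(t)
        like = 0.0
        for g in range(params.n_classes):
            mean = X @ params.beta[g]
            sd_b = params.w[g] * sd_b_base

            def integrand(b):
                return norm.pdf(b, 0, sd_b) * np.prod(
                    norm.pdf(y, mean + b, params.sigma)
                )

            if sd_b > 0:
                val, _ = quad(integrand, -8 * sd_b, 8 * sd_b, limit=200)
            else:
                val = float(np.prod(norm.pdf(y, mean, params.sigma)))
            like += pis[g] * val
        total += math.log(like)
    return total


_ORACLE_BASIS = {}


def _oracle_basis(t):
    key = tuple(t)
    if key not in _ORACLE_BASIS:
        raise KeyError("oracle basis not registered")
    return _ORACLE_BASIS[key]


class TestSplineBasis:
    def test_zero_interior_knots_is_linear(self):
        t = np.arange(1.0, 26.0)
        X = spline_basis(t, 0)
        assert X.shape == (25, 2)
        assert np.allclose(X[:, 0], 1.0)
        assert np.allclose(X[:, 1], t)

    def test_column_count(self):
        t = np.arange(1.0, 26.0)
        for m in (1, 3, 5, 8):
            assert spline_basis(t, m).shape[1] == m + 2

    def test_reproduces_line_exactly(self):
        t = np.arange(1.0, 26.0)
        X = spline_basis(t, 4)
        y = 3.0 + 2.0 * t
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(X @ coef, y, atol=1e-9)

    def test_smoothness_at_knots(self):
        # value, first and second derivative continuous across each knot
        basis = NaturalSplineBasis(np.arange(1.0, 26.0), 3)
        h = 1e-4
        for knot in basis.knots[1:-1]:
            for deriv in range(3):
                left = _fd(basis, knot - 20 * h, h, deriv)
                right = _fd(basis, knot + 20 * h, h, deriv)
                assert np.allclose(left, right, rtol=1e-2, atol=0.05)

    def test_linear_extrapolation_beyond_boundary(self):
        basis = NaturalSplineBasis(np.arange(1.0, 26.0), 3)
        # second derivative vanishes outside the boundary knots
        for t0 in (-5.0, 0.0, 30.0, 40.0):
            assert np.allclose(_fd(basis, t0, 1e-4, 2), 0.0, atol=1e-4)

    def test_too_few_times_rejected(self):
        with pytest.raises(ValueError):
            spline_basis(np.array([1.0, 2.0, 3.0]), 5)


def _fd(basis, t0, h, deriv):
    if deriv == 0:
        return basis(np.array([t0]))[0]
    if deriv == 1:
        return (basis(np.array([t0 + h]))[0] - basis(np.array([t0 - h]))[0]) / (2 * h)
    return (
        basis(np.array([t0 + h]))[0]
        - 2 * basis(np.array([t0]))[0]
        + basis(np.array([t0 - h]))[0]
    ) / h**2


class TestMarginalLoglik:
    def test_k1_no_random_effect_is_iid_gaussian(self, rng):
        t = np.arange(1.0, 11.0)
        series = [(t, rng.normal(50, 5, 10)) for _ in range(4)]
        data = make_data(series, knots=2)
        beta = rng.normal(0, 1, (1, data.p))
        params = LCMMParams(
            logits=np.zeros(0), beta=beta, B=np.zeros((1, 1)),
            w=np.ones(1), sigma=3.0,
        )
        ll = marginal_loglik(params, data)
        expected = sum(
            norm.logpdf(y, data.blocks[0].X @ beta[0], 3.0).sum()
            for _, y in series
        )
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_matches_quadrature_oracle_on_tiny_instances(self, rng):
        # tiny instances (2 subjects, 3 timepoints, K=2, random intercept)
        # generated from the model itself so densities stay in range
        for rep in range(5):
            t = np.arange(1.0, 4.0)
            beta = np.array([[50.0 + rng.normal(0, 3), rng.normal(0, 1)],
                             [40.0 + rng.normal(0, 3), rng.normal(0, 1)]])
            params = LCMMParams(
                logits=np.array([rng.normal()]),
                beta=beta,
                B=np.array([[rng.uniform(1, 9)]]),
                w=np.ones(2),
                sigma=rng.uniform(1, 4),
            )
            series = []
            for _ in range(2):
                g = int(rng.integers(2))
                X = np.column_stack([np.ones(3), t])
                y = X @ beta[g] + rng.normal(0, 3) + rng.normal(0, 2, 3)
                series.append((t, y))
            data = make_data(series, knots=0)
            _ORACLE_BASIS[tuple(t)] = data.blocks[0].X
            assert marginal_loglik(params, data) == pytest.approx(
                quadrature_loglik(params, series), abs=1e-6
            )

    def test_label_switching_symmetry(self, rng):
        t = np.arange(1.0, 8.0)
        series = [(t, rng.normal(55, 6, 7)) for _ in range(5)]
        data = make_data(series, knots=1)
        beta = rng.normal(0, 2, (2, data.p))
        pi = np.array([0.3, 0.7])
        params = LCMMParams(
            logits=np.log(pi[:1] / pi[1]), beta=beta,
            B=np.array([[4.0]]), w=np.ones(2), sigma=2.0,
        )
        swapped = LCMMParams(
            logits=np.log(pi[1:] / pi[0]), beta=beta[::-1].copy(),
            B=np.array([[4.0]]), w=np.ones(2), sigma=2.0,
        )
        assert marginal_loglik(params, data) == pytest.approx(
            marginal_loglik(swapped, data), abs=1e-9
        )


class TestPosterior:
    def test_k1_posteriors_are_one(self, rng):
        t = np.arange(1.0, 6.0)
        series = [(t, rng.normal(50, 5, 5)) for _ in range(3)]
        data = make_data(series, knots=0)
        params = LCMMParams(
            logits=np.zeros(0), beta=np.zeros((1, data.p)),
            B=np.array([[1.0]]), w=np.ones(1), sigma=2.0,
        )
        assert np.allclose(posterior_probs(params, data), 1.0)

    def test_equidistant_subject_gets_half_half(self):
        t = np.arange(1.0, 5.0)
        series = [(t, np.full(4, 50.0))]
        data = make_data(series, knots=0)
        # two classes symmetric around the observed trajectory
        beta = np.array([[52.0, 0.0], [48.0, 0.0]])
        params = LCMMParams(
            logits=np.zeros(1), beta=beta, B=np.array([[1.0]]),
            w=np.ones(2), sigma=2.0,
        )
        post = posterior_probs(params, data)
        assert post[0] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_density_ratio_oracle(self, rng):
        t = np.arange(1.0, 7.0)
        series = [(t, rng.normal(55, 8, 6)) for _ in range(4)]
        data = make_data(series, knots=1)
        _ORACLE_BASIS[tuple(t)] = data.blocks[0].X
        # class means near the data so neither class density underflows
        beta = np.linalg.lstsq(
            data.blocks[0].X, np.vstack([y for _, y in series]).mean(axis=0),
            rcond=None,
        )[0]
        params = LCMMParams(
            logits=np.array([0.4]),
            beta=np.vstack([beta * 1.05, beta * 0.95]),
            B=np.array([[3.0]]), w=np.ones(2), sigma=2.5,
        )
        post = posterior_probs(params, data)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)
        # oracle: per-subject mixture weights from quadrature likelihoods
        pis = params.pi
        for i, (tt, y) in enumerate(series):
            comps = []
            for g in range(2):
                single = LCMMParams(
                    logits=np.zeros(0), beta=params.beta[g : g + 1],
                    B=params.B, w=np.ones(1), sigma=params.sigma,
                )
                comps.append(
                    pis[g]
                    * math.exp(quadrature_loglik(single, [(tt, y)]))
                )
            expected = np.array(comps) / sum(comps)
            assert np.allclose(post[i], expected, atol=1e-6)


class TestAssignAndSummarize:
    def test_uniform_rows_class_one(self):
        post = np.tile([0.9, 0.1], (6, 1))
        modal, mean_post, shares = assign_and_summarize(post)
        assert np.all(modal == 1)
        assert mean_post[0] == pytest.approx(0.9)
        assert np.isnan(mean_post[1])
        assert shares == pytest.approx([1.0, 0.0])

    def test_tie_breaks_to_lowest_class(self):
        modal, _, _ = assign_and_summarize(np.array([[0.5, 0.5]]))
        assert modal[0] == 1

    def test_matches_bruteforce_oracle(self, rng):
        post = rng.dirichlet(np.ones(3), size=40)
        modal, mean_post, shares = assign_and_summarize(post)
        for g in range(3):
            members = [i for i in range(40) if np.argmax(post[i]) == g]
            assert shares[g] == pytest.approx(len(members) / 40)
            if members:
                assert mean_post[g] == pytest.approx(
                    np.mean([post[i, g] for i in members])
                )


class TestWeightedClassMeans:
    def test_hard_posteriors_are_group_means(self, rng):
        t = np.arange(1.0, 6.0)
        series = [(t, rng.normal(50, 5, 5)) for _ in range(6)]
        data = make_data(series, knots=0)
        post = np.zeros((6, 2))
        post[:3, 0] = 1.0
        post[3:, 1] = 1.0
        df = weighted_class_means(data, post)
        y = np.vstack([s[1] for s in series])
        for g, sl in ((1, slice(0, 3)), (2, slice(3, 6))):
            got = df[df["class"] == g].sort_values(
                "week_before_bp", ascending=True
            )["mean"].values
            assert np.allclose(got, y[sl].mean(axis=0), atol=1e-12)

    def test_uniform_posteriors_give_grand_mean(self, rng):
        t = np.arange(1.0, 6.0)
        series = [(t, rng.normal(50, 5, 5)) for _ in range(6)]
        data = make_data(series, knots=0)
        post = np.full((6, 2), 0.5)
        df = weighted_class_means(data, post)
        grand = np.vstack([s[1] for s in series]).mean(axis=0)
        for g in (1, 2):
            got = df[df["class"] == g].sort_values(
                "week_before_bp", ascending=True
            )["mean"].values
            assert np.allclose(got, grand, atol=1e-12)

    def test_weighted_average_oracle(self, rng):
        t = np.arange(1.0, 6.0)
        series = [(t, rng.normal(50, 5, 5)) for _ in range(7)]
        data = make_data(series, knots=0)
        post = rng.dirichlet(np.ones(3), size=7)
        df = weighted_class_means(data, post)
        y = np.vstack([s[1] for s in series])
        for g in range(3):
            expected = (post[:, g] @ y) / post[:, g].sum()
            got = df[df["class"] == g + 1].sort_values(
                "week_before_bp", ascending=True
            )["mean"].values
            assert np.allclose(got, expected, atol=1e-12)


def _two_class_series(rng, n=40, sep=20.0, re_sd=0.0, res_sd=0.0):
    t = np.arange(25.0, 0.0, -1.0)
    series, labels = [], []
    for i in range(n):
        g = i % 2
        mu = 50.0 + g * sep + 0.5 * t * (1 if g == 0 else -1)
        y = mu + rng.normal(0, re_sd) + rng.normal(0, res_sd, len(t))
        series.append((t, y))
        labels.append(g)
    return series, np.array(labels)


class TestFit:
    def test_k1_matches_gls_oracle(self, rng):
        # single-class fits against a closed-form-GLS profile-likelihood
        # oracle for the balanced random-intercept mixed model
        from oracles import gls_random_intercept_ml

        t = np.arange(25.0, 0.0, -1.0)
        spec = LCMMSpec(n_classes=1, n_interior_knots=2)
        for rep in range(3):
            series = []
            for i in range(30):
                b = rng.normal(0, 4)
                y = 60 + 0.8 * t - 0.02 * t**2 + b + rng.normal(0, 3, len(t))
                series.append((t, y))
            data = make_data(series, knots=2)
            f = fit(data, spec, n_starts=2, seed=rep, max_polish_iter=200)
            X = data.blocks[0].X
            Y = np.vstack([y for _, y in series])
            beta_o, sigma_o, tau_o, ll_o = gls_random_intercept_ml(X, Y)
            assert np.allclose(f.params.beta[0], beta_o, atol=1e-4)
            assert f.params.sigma == pytest.approx(sigma_o, rel=1e-4)
            assert math.sqrt(f.params.B[0, 0]) == pytest.approx(tau_o, rel=1e-3)
            assert f.loglik == pytest.approx(ll_o, abs=1e-4)

    def test_separable_noise_free_recovery(self, rng):
        series, labels = _two_class_series(rng, n=30, sep=25.0)
        data = make_data(series, knots=2)
        f = fit(data, LCMMSpec(n_classes=2, n_interior_knots=2), n_starts=2, seed=0)
        # classes are label-ordered by mean level: class 1 = higher curve
        pred = np.where(f.modal_class == 1, 1, 0)
        truth_high = (labels == 1).astype(int)  # group 1 has the higher mean
        assert np.array_equal(pred, truth_high)
        assert f.params.pi == pytest.approx([0.5, 0.5], abs=1e-6)
        assert np.allclose(f.posterior.sum(axis=1), 1.0, atol=1e-10)

    def test_em_monotone_loglik(self, rng):
        series, _ = _two_class_series(rng, n=20, sep=10.0, re_sd=4.0, res_sd=3.0)
        data = make_data(series, knots=2)
        f = fit(data, LCMMSpec(n_classes=2, n_interior_knots=2), n_starts=1, seed=3)
        hist = np.asarray(f.loglik_history)
        assert np.all(np.diff(hist) >= -1e-10 * np.abs(hist[:-1]))

    def test_canonical_class_order(self, rng):
        series, _ = _two_class_series(rng, n=30, sep=20.0, res_sd=2.0)
        data = make_data(series, knots=2)
        f = fit(data, LCMMSpec(n_classes=2, n_interior_knots=2), n_starts=2, seed=1)
        X = data.blocks[0].X
        levels = (X @ f.params.beta.T).mean(axis=0)
        assert levels[0] >= levels[1]

    def test_nesting_loglik_nondecreasing_in_k(self, rng):
        series, _ = _two_class_series(rng, n=24, sep=12.0, re_sd=3.0, res_sd=3.0)
        data = make_data(series, knots=2)
        lls = []
        for k in (1, 2, 3):
            f = fit(data, LCMMSpec(n_classes=k, n_interior_knots=2),
                    n_starts=3, seed=5)
            lls.append(f.loglik)
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[1] - 1e-6

    def test_information_criteria_formulas(self, rng):
        series, _ = _two_class_series(rng, n=16, sep=15.0, res_sd=3.0)
        data = make_data(series, knots=2)
        f = fit(data, LCMMSpec(n_classes=2, n_interior_knots=2), n_starts=1, seed=0)
        assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.n_params)
        assert f.bic == pytest.approx(-2 * f.loglik + f.n_params * math.log(16))

    def test_parameter_count(self):
        # K=3, p=5, intercept-only diagonal common: 2 + 15 + 1 + 1 = 19
        spec = LCMMSpec(n_classes=3, n_interior_knots=3)
        assert spec.n_parameters(5) == 19
        prop = LCMMSpec(n_classes=3, n_interior_knots=3,
                        re_class_structure="proportional")
        assert prop.n_parameters(5) == 21
        slope = LCMMSpec(n_classes=2, n_interior_knots=2,
                         random_effects="intercept_slope",
                         re_covariance="unstructured")
        assert slope.n_parameters(4) == 1 + 8 + 3 + 1

    def test_proportional_structure_fits(self, rng):
        # classes with different random-intercept spread
        t = np.arange(25.0, 0.0, -1.0)
        series = []
        for i in range(40):
            g = i % 2
            sd_b = 2.0 if g == 0 else 8.0
            y = 50 + g * 20 + rng.normal(0, sd_b) + rng.normal(0, 3, len(t))
            series.append((t, y))
        data = make_data(series, knots=1)
        spec = LCMMSpec(n_classes=2, n_interior_knots=1,
                        re_class_structure="proportional")
        f = fit(data, spec, n_starts=2, seed=0)
        assert f.params.w[-1] == pytest.approx(1.0)
        # class 1 (higher level, generated with sd 8) should get a larger scale
        assert f.params.w[0] * math.sqrt(f.params.B[0, 0]) > math.sqrt(f.params.B[0, 0])

    def test_intercept_slope_design_fits(self, rng):
        t = np.arange(25.0, 0.0, -1.0)
        series = []
        for i in range(30):
            b0, b1 = rng.normal(0, 5), rng.normal(0, 0.4)
            y = 55 + b0 + b1 * (t - t.mean()) + rng.normal(0, 2, len(t))
            series.append((t, y))
        data = make_data(series, knots=1, random_effects="intercept_slope")
        spec = LCMMSpec(n_classes=1, n_interior_knots=1,
                        random_effects="intercept_slope",
                        re_covariance="unstructured")
        f = fit(data, spec, n_starts=1, seed=0)
        assert f.params.B.shape == (2, 2)
        assert f.params.B[0, 0] > 1.0  # intercept variance recovered as sizeable
        assert f.params.B[1, 1] > 0.01


class TestModelSearch:
    def test_single_cell_grid(self, rng):
        series, _ = _two_class_series(rng, n=16, sep=15.0, res_sd=3.0)
        data_series = series

        best, table = model_search(
            lambda spec: make_data(data_series, spec.n_interior_knots),
            k_range=(2,), knot_range=(2,),
            re_covariances=("diagonal",), re_class_structures=("common",),
            n_starts=1, seed=0,
        )
        assert len(table) == 1
        assert best.spec.n_classes == 2

    def test_criteria_recomputable_from_table(self, rng):
        series, _ = _two_class_series(rng, n=16, sep=15.0, res_sd=3.0)
        _, table = model_search(
            lambda spec: make_data(series, spec.n_interior_knots),
            k_range=(1, 2), knot_range=(1, 2),
            re_covariances=("diagonal",), re_class_structures=("common",),
            n_starts=1, seed=0,
        )
        ok = table[table["converged"]]
        assert np.allclose(ok["AIC"], -2 * ok["loglik"] + 2 * ok["n_params"])
        assert np.allclose(
            ok["BIC"], -2 * ok["loglik"] + ok["n_params"] * math.log(16)
        )

    def test_redundant_cells_skipped_for_scalar_random_effect(self, rng):
        series, _ = _two_class_series(rng, n=12, sep=15.0, res_sd=3.0)
        _, table = model_search(
            lambda spec: make_data(series, spec.n_interior_knots),
            k_range=(1,), knot_range=(2,),
            re_covariances=("diagonal", "unstructured"),
            re_class_structures=("common", "proportional"),
            n_starts=1, seed=0,
        )
        # q=1 makes diagonal/unstructured identical; K=1 makes the
        # proportional structure vacuous: one unique cell remains
        assert len(table) == 1
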