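"""Measurement model: oracle equivalence, identification, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from integra_index.cfa import (
    ModelSpec,
    Priors,
    SamplerConfig,
    augmented_loglikelihood,
    fit,
    resolve_sign,
    standardize_loadings,
)
from integra_index.ordinalize import IndicatorMatrix
from integra_index.synthetic import GeneratorConfig, generate_study


def grid_posterior_means(matrix, prior_variance=2.0, n_grid=81, span=8.0):
    """Brute-force grid posterior for a 2-binary-indicator 1-factor model.

    Independent of the Gibbs implementation: pattern probabilities by
    Gauss-Hermite quadrature over the factor, posterior means by direct
    summation on a (lambda1, tau1, lambda2, tau2) lattice restricted to
    the lambda1 + lambda2 > 0 orientation.
    """
    y = matrix.values_array()
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    weights = weights / weights.sum()
    grid = np.linspace(-span, span, n_grid)
    v = prior_variance
    a = ndtr(grid[:, None, None] * nodes[None, None, :] - grid[None, :, None])  # (L,T,Q)
    counts = np.zeros((2, 2))
    np.add.at(counts, (y[:, 0].astype(int), y[:, 1].astype(int)), 1.0)
    prior = -(grid**2) / (2 * v)
    marg = [np.zeros(n_grid) for _ in range(4)]
    for i1 in range(n_grid):
        ll = np.zeros((n_grid, n_grid, n_grid))
        for c1, a1 in ((1, a[i1]), (0, 1 - a[i1])):
            for c2, a2 in ((1, a), (0, 1 - a)):
                p = np.einsum("q,jq,klq->jkl", weights, a1, a2)
                ll += counts[c1, c2] * np.log(np.clip(p, 1e-300, None))
        lp = ll + prior[i1] + prior[:, None, None] + prior[None, :, None] + prior[None, None, :]
        w = np.exp(lp)
        w *= (grid[i1] + grid[None, :, None]) > 0  # sign orientation
        marg[0][i1] = w.sum()
        marg[1] += w.sum(axis=(1, 2))
        marg[2] += w.sum(axis=(0, 2))
        marg[3] += w.sum(axis=(0, 1))
    z = marg[0].sum()
    return np.array([(m / z * grid).sum() for m in marg])


class TestOracleEquivalence:
    def test_gibbs_matches_grid_posterior(self, small_binary_matrix):
        """Posterior means of loadings and thresholds from the Gibbs sampler
        agree with a brute-force grid posterior within 0.05."""
        oracle = grid_posterior_means(small_binary_matrix)
        spec = ModelSpec(n_factors=1, loading_pattern={"a": 0, "b": 0})
        post = resolve_sign(
            fit(
                small_binary_matrix,
                spec,
                Priors(2.0, 2.0),
                SamplerConfig(n_chains=4, n_iterations=30_000, seed=9),
            )
        )
        lam = post.stacked(post.lam)
        taus = [post.stacked(t) for t in post.tau]
        gibbs = np.array(
            [lam[:, 0].mean(), taus[0][:, 0].mean(), lam[:, 1].mean(), taus[1][:, 0].mean()]
        )
        np.testing.assert_allclose(gibbs, oracle, atol=0.05)


class TestStandardization:
    @pytest.mark.parametrize(
        "lam, expected",
        [(1.0, 1 / np.sqrt(2)), (0.0, 0.0), (1e6, 1.0), (-1.0, -1 / np.sqrt(2))],
    )
    def test_closed_form(self, lam, expected):
        post = _toy_posterior(lam_value=lam)
        out = standardize_loadings(post)
        assert out.loc["a", "mean"] == pytest.approx(expected, abs=1e-6)

    def test_values_strictly_inside_unit_interval(self):
        post = _toy_posterior(lam_value=50.0)
        out = standardize_loadings(post)
        assert (out["mean"].abs() < 1.0).all()


class TestSignResolution:
    def test_all_negative_draw_flipped_and_eta_negated(self):
        post = _toy_posterior(lam_value=-2.0)
        resolved = resolve_sign(post)
        assert (resolved.lam > 0).all()
        np.testing.assert_array_equal(resolved.eta, -post.eta)

    def test_positive_draw_unchanged_and_idempotent(self):
        post = _toy_posterior(lam_value=2.0)
        resolved = resolve_sign(post)
        np.testing.assert_array_equal(resolved.lam, post.lam)
        again = resolve_sign(resolved)
        np.testing.assert_array_equal(again.lam, resolved.lam)

    def test_reflected_chains_align_after_resolution(self):
        post = _toy_posterior(lam_value=2.0, n_chains=2)
        post.lam[1] *= -1
        post.eta[1] *= -1
        resolved = resolve_sign(post)
        np.testing.assert_allclose(resolved.lam[0], resolved.lam[1])


def test_reflection_leaves_augmented_likelihood_invariant():
    rng = np.random.default_rng(1)
    n, p, q = 10, 4, 2
    eta = rng.standard_normal((n, q))
    lam_full = rng.standard_normal((p, q))
    z = eta @ lam_full.T + rng.standard_normal((n, p))
    base = augmented_loglikelihood(z, eta, lam_full)
    flipped_lam = lam_full.copy()
    flipped_lam[:, 0] *= -1
    flipped_eta = eta.copy()
    flipped_eta[:, 0] *= -1
    assert augmented_loglikelihood(z, flipped_eta, flipped_lam) == pytest.approx(base)


class TestFitContracts:
    def test_seed_reproducibility(self):
        mat = generate_study(GeneratorConfig(n_facilities=20, seed=5)).indicators["baseline"]
        cfg = SamplerConfig(n_chains=2, n_iterations=400, seed=3)
        spec = ModelSpec.two_factor()
        a = fit(mat, spec, None, cfg)
        b = fit(mat, spec, None, cfg)
        np.testing.assert_array_equal(a.lam, b.lam)
        np.testing.assert_array_equal(a.eta, b.eta)

    def test_thresholds_increasing_in_every_retained_draw(self):
        mat = generate_study(GeneratorConfig(n_facilities=30, seed=6)).indicators["baseline"]
        post = fit(mat, ModelSpec.two_factor(), None, SamplerConfig(2, 600, seed=2))
        for t in post.tau:
            if t.shape[2] > 1:
                assert (np.diff(t, axis=2) > 0).all()

    def test_missing_cells_are_integrated_out(self):
        mat = generate_study(GeneratorConfig(n_facilities=30, seed=7)).indicators["baseline"]
        data = mat.data.copy()
        data.iloc[0, 0] = np.nan
        data.iloc[5, 3] = np.nan
        holed = IndicatorMatrix(data=data, n_categories=dict(mat.n_categories))
        post = fit(holed, ModelSpec.two_factor(), None, SamplerConfig(2, 600, seed=2))
        assert np.isfinite(post.lam).all()

    def test_single_category_indicator_rejected_at_entry(self):
        df = pd.DataFrame(
            {"a": [1.0] * 12, "b": [0.0, 1.0] * 6},
            index=pd.Index([f"F{i}" for i in range(12)], name="facility_id"),
        )
        mat = IndicatorMatrix(data=df, n_categories={"a": 2, "b": 2})
        with pytest.raises(ValueError, match="'a'"):
            fit(mat, ModelSpec(n_factors=1, loading_pattern={"a": 0, "b": 0}), None, SamplerConfig(2, 200, seed=0))

    def test_more_loadings_than_facilities_rejected(self):
        mat = generate_study(GeneratorConfig(n_facilities=40, seed=8)).indicators["baseline"]
        small = IndicatorMatrix(
            data=mat.data.iloc[:5], n_categories=dict(mat.n_categories)
        )
        with pytest.raises(ValueError, match="identify"):
            fit(small, ModelSpec.two_factor(), None, SamplerConfig(2, 400, seed=1))


def test_independent_indicators_reproduce_marginal_frequencies():
    """Null-model limit: with zero generating loadings the fit collapses to
    independent ordinal probits, so the model-implied marginal category
    probabilities (averaged over draws) match the observed frequencies.
    The raw loading itself is only weakly identified in this limit; the
    identified quantity tau / sqrt(lambda^2 + 1) is what the check uses."""
    cfg = GeneratorConfig(
        n_facilities=200,
        loadings={k: 0.0 for k in GeneratorConfig().loadings},
        seed=11,
    )
    mat = generate_study(cfg).indicators["baseline"]
    post = resolve_sign(fit(mat, ModelSpec.two_factor(), None, SamplerConfig(2, 1500, seed=4)))
    lam = post.stacked(post.lam)  # (S, p)
    for j, name in enumerate(post.indicators):
        tau = post.stacked(post.tau[j])  # (S, K-1)
        s = np.sqrt(lam[:, [j]] ** 2 + 1)
        cdf = ndtr(tau / s)
        implied = np.diff(
            np.concatenate([np.zeros((len(cdf), 1)), cdf, np.ones((len(cdf), 1))], axis=1), axis=1
        ).mean(axis=0)
        observed = np.bincount(
            mat.data[name].astype(int), minlength=post.n_categories[name]
        ) / len(mat.data)
        np.testing.assert_allclose(implied, observed, atol=0.05)


def _toy_posterior(lam_value: float, n_chains: int = 2):
    """Hand-built posterior with constant draws, for algebraic checks."""
    from integra_index.cfa import Posterior

    n_draws, n_fac = 5, 6
    spec = ModelSpec(n_factors=1, loading_pattern={"a": 0})
    lam = np.full((n_chains, n_draws, 1), float(lam_value))
    tau = [np.zeros((n_chains, n_draws, 1))]
    rng = np.random.default_rng(0)
    eta = rng.standard_normal((n_chains, n_draws, n_fac, 1))
    return Posterior(
        spec=spec,
        config=SamplerConfig(n_chains=n_chains, n_iterations=10, seed=0),
        indicators=["a"],
        n_categories={"a": 2},
        facility_index=pd.Index([f"F{i}" for i in range(n_fac)], name="facility_id"),
        lam=lam,
        tau=tau,
        eta=eta,
    )
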