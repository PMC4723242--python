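"""Repeated-simulation evaluation of the whole pipeline.

Four study-condition experiments, each run over independent seeds under
the default generator (40 facilities, two orthogonal factors, published
baseline loadings):

* :func:`loading_recovery` — does the 95% credible interval of each
  standardized loading cover its generating value?
* :func:`dimensionality_check` — does the posterior predictive check
  reject the one-factor model and retain the two-factor model?
* :func:`orthogonality_check` — how correlated are the two factors'
  plausible-value scores on orthogonally generated data?
* :func:`oracle_comparison` — do Gibbs posterior means match a
  brute-force grid posterior on a tiny two-indicator model?

Sampler sizes are scaled for repeated simulation (thousands, not the
production default of 50,000 iterations); each function documents its own.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from .cfa import ModelSpec, Priors, SamplerConfig, fit, resolve_sign, standardize_loadings
from .diagnostics import ppc
from .ordinalize import IndicatorMatrix
from .scoring import plausible_values
from .synthetic import DEFAULT_LOADINGS, GeneratorConfig, generate_study


def _two_factor_fit(seed: int, n_iterations: int = 3000, n_chains: int = 4):
    study = generate_study(GeneratorConfig(seed=seed))
    mat = study.indicators["baseline"]
    post = resolve_sign(
        fit(mat, ModelSpec.two_factor(), None, SamplerConfig(n_chains, n_iterations, seed=seed + 10_000))
    )
    return study, mat, post


def loading_recovery(seeds: list[int], n_iterations: int = 3000) -> dict:
    """Per-seed CI coverage of the generating standardized loadings.

    Fits the two-factor model (4 chains x ``n_iterations``, 50% burn-in)
    to a fresh 40-facility study per seed.
    """
    covered = 0
    total = 0
    per_seed = []
    posteriors = {}
    for seed in seeds:
        _, mat, post = _two_factor_fit(seed, n_iterations)
        posteriors[seed] = (mat, post)
        sl = standardize_loadings(post)
        inside = {
            k: bool(sl.loc[k, "ci_low"] <= DEFAULT_LOADINGS[k] <= sl.loc[k, "ci_high"])
            for k in DEFAULT_LOADINGS
        }
        covered += sum(inside.values())
        total += len(inside)
        per_seed.append(inside)
    return {
        "coverage": covered / total,
        "covered": covered,
        "total": total,
        "per_seed": per_seed,
        "posteriors": posteriors,
    }


def dimensionality_check(
    seeds: list[int],
    two_factor_posteriors: dict | None = None,
    n_iterations: int = 3000,
    n_reps: int = 300,
) -> dict:
    """One- vs two-factor posterior predictive verdicts per seed."""
    rows = []
    for seed in seeds:
        if two_factor_posteriors and seed in two_factor_posteriors:
            mat, post2 = two_factor_posteriors[seed]
        else:
            _, mat, post2 = _two_factor_fit(seed, n_iterations)
        post1 = resolve_sign(
            fit(
                mat,
                ModelSpec.one_factor(mat.indicators),
                None,
                SamplerConfig(4, n_iterations, seed=seed + 20_000),
            )
        )
        r2 = ppc(post2, mat, n_reps=n_reps, seed=seed + 30_000)
        r1 = ppc(post1, mat, n_reps=n_reps, seed=seed + 40_000)
        rows.append(
            {
                "seed": seed,
                "p_one": r1.p_value,
                "ci_one": r1.diff_interval,
                "p_two": r2.p_value,
                "ci_two": r2.diff_interval,
            }
        )
    n = len(rows)
    return {
        "rows": rows,
        "one_factor_p_le_05": sum(r["p_one"] <= 0.05 for r in rows),
        "one_factor_ci_excludes_zero": sum(r["ci_one"][0] > 0 for r in rows),
        "two_factor_p_gt_05": sum(r["p_two"] > 0.05 for r in rows),
        "two_factor_ci_includes_zero": sum(r["ci_two"][0] <= 0 <= r["ci_two"][1] for r in rows),
        "median_p_one": float(np.median([r["p_one"] for r in rows])),
        "median_p_two": float(np.median([r["p_two"] for r in rows])),
        "n_seeds": n,
    }


def orthogonality_check(
    seeds: list[int],
    two_factor_posteriors: dict | None = None,
    n_iterations: int = 2000,
    n_chains: int = 2,
) -> dict:
    """Cross-factor correlation of plausible-value scores per seed."""
    rs = []
    for seed in seeds:
        if two_factor_posteriors and seed in two_factor_posteriors:
            _, post = two_factor_posteriors[seed]
        else:
            _, _, post = _two_factor_fit(seed, n_iterations, n_chains)
        wide = plausible_values(post).wide()
        rs.append(float(np.corrcoef(wide[0], wide[1])[0, 1]))
    ar = np.abs(rs)
    return {
        "r": rs,
        "max_abs_r": float(ar.max()),
        "mean_abs_r": float(ar.mean()),
        "n_exceeding_0_2": int((ar >= 0.2).sum()),
        "n_seeds": len(rs),
    }


# ---------------------------------------------------------------------------
# grid oracle for the tiny binary model


def small_binary_study(seed: int = 42, n: int = 12) -> IndicatorMatrix:
    """Two binary indicators from a one-factor probit model."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    lam_true = np.array([1.0, 0.8])
    tau_true = np.array([-0.3, 0.4])
    eta = rng.standard_normal(n)
    z = lam_true * eta[:, None] + rng.standard_normal((n, 2))
    y = (z > tau_true).astype(float)
    return IndicatorMatrix(
        data=pd.DataFrame(
            {"a": y[:, 0], "b": y[:, 1]},
            index=pd.Index([f"F{i}" for i in range(n)], name="facility_id"),
        ),
        n_categories={"a": 2, "b": 2},
    )


def grid_posterior_means(
    matrix: IndicatorMatrix, prior_variance: float = 2.0, n_grid: int = 81, span: float = 8.0
) -> np.ndarray:
    """Brute-force posterior means (lam1, tau1, lam2, tau2) on a lattice.

    Pattern probabilities by Gauss-Hermite quadrature over the factor;
    posterior restricted to the lam1 + lam2 > 0 orientation, matching the
    sampler's sign resolution.
    """
    y = matrix.values_array()
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    weights = weights / weights.sum()
    grid = np.linspace(-span, span, n_grid)
    a = ndtr(grid[:, None, None] * nodes[None, None, :] - grid[None, :, None])
    counts = np.zeros((2, 2))
    np.add.at(counts, (y[:, 0].astype(int), y[:, 1].astype(int)), 1.0)
    prior = -(grid**2) / (2 * prior_variance)
    marg = [np.zeros(n_grid) for _ in range(4)]
    for i1 in range(n_grid):
        ll = np.zeros((n_grid, n_grid, n_grid))
        for c1, a1 in ((1, a[i1]), (0, 1 - a[i1])):
            for c2, a2 in ((1, a), (0, 1 - a)):
                p = np.einsum("q,jq,klq->jkl", weights, a1, a2)
                ll += counts[c1, c2] * np.log(np.clip(p, 1e-300, None))
        lp = ll + prior[i1] + prior[:, None, None] + prior[None, :, None] + prior[None, None, :]
        w = np.exp(lp)
        w *= (grid[i1] + grid[None, :, None]) > 0
        marg[0][i1] = w.sum()
        marg[1] += w.sum(axis=(1, 2))
        marg[2] += w.sum(axis=(0, 2))
        marg[3] += w.sum(axis=(0, 1))
    z = marg[0].sum()
    return np.array([(m / z * grid).sum() for m in marg])


def oracle_comparison(seed: int = 42, sampler_seed: int = 9, n_iterations: int = 30_000) -> dict:
    """Gibbs vs grid posterior means on the tiny binary model.

    Both routes use the same N(0, 2) priors; comparison on the raw
    loading/threshold scale after sign resolution.
    """
    matrix = small_binary_study(seed)
    oracle = grid_posterior_means(matrix)
    spec = ModelSpec(n_factors=1, loading_pattern={"a": 0, "b": 0})
    post = resolve_sign(
        fit(matrix, spec, Priors(2.0, 2.0), SamplerConfig(4, n_iterations, seed=sampler_seed))
    )
    lam = post.stacked(post.lam)
    taus = [post.stacked(t) for t in post.tau]
    gibbs = np.array(
        [lam[:, 0].mean(), taus[0][:, 0].mean(), lam[:, 1].mean(), taus[1][:, 0].mean()]
    )
    return {
        "gibbs": gibbs.tolist(),
        "grid": oracle.tolist(),
        "max_abs_diff": float(np.abs(gibbs - oracle).max()),
    }
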