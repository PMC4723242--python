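"""Convergence and model-fit diagnostics.

Convergence: the potential scale reduction (PSR) criterion, computed per
scalar parameter after sign resolution as

    PSR = sqrt((W + B) / W),

where W is the mean within-chain variance and B the between-chain variance
of chain means.  Identical chains give PSR = 1 exactly; values close to 1
indicate convergence.

Fit: posterior predictive checking with an observed-vs-replicated
chi-square discrepancy.  The default statistic is the full-information
likelihood-ratio chi-square against the saturated multinomial,

    f(y; lambda, tau) = 2 * [loglik_saturated(y) - loglik_model(y)],

with the model likelihood marginalized over the factors by dense
quadrature.  A limited-information alternative ("pairwise_g2") sums
likelihood-ratio G^2 over every univariate and pairwise two-way indicator
table, with bivariate cell probabilities from normal rectangle
probabilities via Gauss-Hermite quadrature over the shared factor; it is
cheaper but, at ~40 facilities, spreads the dependence signal over many
sparse tables and has visibly lower power against misspecified factor
structure.  Reported are the central 95% interval of (f_obs - f_rep) over
posterior draws and the posterior predictive p-value Pr(f_rep >= f_obs):
an interval containing zero and a non-small p indicate good fit.  Both
statistics are of the same family as the observed-vs-replicated chi-square
used by mainstream SEM software, but not identical to any one program's
internal version.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .cfa import Posterior, resolve_sign
from .ordinalize import IndicatorMatrix

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()  # weights for eta ~ N(0,1)

# dense grid for the full-information likelihood: resolves the narrow
# eta-windows that large raw loadings produce
_FG_NODES = np.linspace(-6.0, 6.0, 241)
_FG_WEIGHTS = np.exp(-0.5 * _FG_NODES**2)
_FG_WEIGHTS = _FG_WEIGHTS / _FG_WEIGHTS.sum()

_PCLIP = 1e-12


@dataclass
class FitReport:
    """PSR per parameter plus posterior-predictive fit summaries."""

    psr: dict[str, float]
    max_psr: float
    f_obs: np.ndarray
    f_rep: np.ndarray
    diff_interval: tuple[float, float]
    p_value: float
    converged: bool = field(init=False)
    good_fit: bool = field(init=False)
    psr_threshold: float = 1.1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.converged = self.max_psr < self.psr_threshold
        lo, hi = self.diff_interval
        self.good_fit = (lo <= 0.0 <= hi) and (self.p_value > self.alpha)

    def summary(self) -> str:
        lo, hi = self.diff_interval
        return (
            f"chi2 diff 95% CI [{lo:.3f}, {hi:.3f}]  p={self.p_value:.3f}  "
            f"max PSR={self.max_psr:.3f}  "
            f"fit={'good' if self.good_fit else 'poor'}, "
            f"{'converged' if self.converged else 'NOT converged'}"
        )


def psr(post: Posterior) -> dict[str, float]:
    """Potential scale reduction per scalar model parameter.

    Requires >= 2 chains of equal retained length; computed on the
    sign-resolved posterior (reflection ambiguity would otherwise inflate
    between-chain variance spuriously).
    """
    if post.lam.shape[0] < 2:
        raise ValueError("PSR needs at least 2 chains")
    if not post.sign_resolved:
        post = resolve_sign(post)
    out: dict[str, float] = {}
    for name, draws in post.parameter_draws().items():
        out[name] = _psr_scalar(draws)
    return out


def _psr_scalar(draws: np.ndarray) -> float:
    """draws: (chains, iterations)."""
    lengths = {d.shape[0] for d in draws}
    if len(lengths) != 1:
        raise ValueError("chains have unequal retained lengths")
    w = draws.var(axis=1, ddof=1).mean()
    b = draws.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else float("inf")
    return float(np.sqrt((w + b) / w))


def max_psr(post: Posterior) -> float:
    return max(psr(post).values())


def _category_probs_at_nodes(lam_j: float, tau_j: np.ndarray) -> np.ndarray:
    """(nodes, K) category probabilities conditional on eta at GH nodes."""
    edges = np.concatenate(([-np.inf], tau_j, [np.inf]))
    cdf = ndtr(edges[None, :] - lam_j * _GH_NODES[:, None])  # (nodes, K+1)
    return np.diff(cdf, axis=1)


def _marginal_probs(lam_j: float, tau_j: np.ndarray) -> np.ndarray:
    s = np.sqrt(lam_j**2 + 1.0)
    edges = np.concatenate(([-np.inf], tau_j / s, [np.inf]))
    return np.diff(ndtr(edges))


def _g2(counts: np.ndarray, probs: np.ndarray, n: int) -> float:
    """Likelihood-ratio statistic 2 * sum n_c log(n_c / (N p_c))."""
    mask = counts > 0
    expected = n * np.clip(probs, _PCLIP, None)
    return float(2.0 * (counts[mask] * np.log(counts[mask] / expected[mask])).sum())


def _model_loglik(
    y: np.ndarray,
    obs_mask: np.ndarray,
    lam: np.ndarray,
    taus: list[np.ndarray],
    factor_of: np.ndarray,
) -> float:
    """Marginal log-likelihood of the ordinal table under one draw.

    Factors are orthogonal, so the likelihood factorizes over factor
    blocks; each block is integrated over its factor on a dense grid.
    Missing cells contribute a factor of 1.
    """
    n = y.shape[0]
    total = np.zeros(n)
    for f in np.unique(factor_of):
        cols = np.flatnonzero(factor_of == f)
        prod = np.ones((len(_FG_NODES), n))
        for j in cols:
            edges = np.concatenate(([-np.inf], taus[j], [np.inf]))
            cdf = ndtr(edges[None, :] - lam[j] * _FG_NODES[:, None])
            probs = np.diff(cdf, axis=1)  # (nodes, K)
            pj = probs[:, np.where(obs_mask[:, j], y[:, j], 0).astype(int)]
            prod *= np.where(obs_mask[:, j], pj, 1.0)
        total += np.log(_FG_WEIGHTS @ prod + 1e-300)
    return float(total.sum())


def _saturated_loglik(y: np.ndarray) -> float:
    """Multinomial log-likelihood of the observed response patterns."""
    _, counts = np.unique(np.nan_to_num(y, nan=-1).astype(int), axis=0, return_counts=True)
    n = y.shape[0]
    return float((counts * np.log(counts / n)).sum())


def _lrt_discrepancy(
    y: np.ndarray,
    obs_mask: np.ndarray,
    lam: np.ndarray,
    taus: list[np.ndarray],
    factor_of: np.ndarray,
) -> float:
    return 2.0 * (_saturated_loglik(y) - _model_loglik(y, obs_mask, lam, taus, factor_of))


def _discrepancy(
    y: np.ndarray,
    obs_mask: np.ndarray,
    ks: np.ndarray,
    lam: np.ndarray,
    taus: list[np.ndarray],
    factor_of: np.ndarray,
) -> float:
    """G^2 over all univariate and pairwise tables for one parameter draw."""
    p = y.shape[1]
    total = 0.0
    node_probs = [_category_probs_at_nodes(lam[j], taus[j]) for j in range(p)]
    marg = [_marginal_probs(lam[j], taus[j]) for j in range(p)]
    for j in range(p):
        yj = y[obs_mask[:, j], j].astype(int)
        counts = np.bincount(yj, minlength=ks[j]).astype(float)
        total += _g2(counts, marg[j], len(yj))
    for j in range(p):
        for k in range(j + 1, p):
            both = obs_mask[:, j] & obs_mask[:, k]
            yj = y[both, j].astype(int)
            yk = y[both, k].astype(int)
            counts = np.zeros((ks[j], ks[k]))
            np.add.at(counts, (yj, yk), 1.0)
            if factor_of[j] == factor_of[k]:
                probs = np.einsum("n,na,nb->ab", _GH_WEIGHTS, node_probs[j], node_probs[k])
            else:  # orthogonal factors: latent responses independent
                probs = np.outer(marg[j], marg[k])
            total += _g2(counts, probs, len(yj))
    return total


def _simulate_from_draw(
    rng: np.random.Generator,
    n: int,
    ks: np.ndarray,
    lam: np.ndarray,
    taus: list[np.ndarray],
    factor_of: np.ndarray,
) -> np.ndarray:
    q = int(factor_of.max()) + 1
    eta = rng.standard_normal((n, q))
    z = eta[:, factor_of] * lam + rng.standard_normal((n, len(lam)))
    y = np.zeros_like(z)
    for j in range(len(lam)):
        y[:, j] = np.searchsorted(taus[j], z[:, j])
    return y


def ppc(
    post: Posterior,
    indicators: IndicatorMatrix,
    n_reps: int = 1000,
    seed: int | None = None,
    statistic: str = "lrt",
) -> FitReport:
    """Posterior predictive check of the fitted measurement model.

    For each of ``n_reps`` posterior draws (evenly thinned across chains),
    computes the discrepancy on the observed table (f_obs) and on a fresh
    replicate simulated from the same draw (f_rep).  Facility order does
    not affect the result.  ``statistic`` selects the discrepancy: "lrt"
    (full-information chi-square vs the saturated multinomial, default) or
    "pairwise_g2" (limited-information G^2 over one- and two-way tables).
    """
    if statistic not in ("lrt", "pairwise_g2"):
        raise ValueError(f"unknown discrepancy statistic {statistic!r}")
    if n_reps < 100:
        warnings.warn(f"n_reps={n_reps} < 100: the 95% interval will be unstable", stacklevel=2)
    if not post.sign_resolved:
        post = resolve_sign(post)
    rng = np.random.default_rng(seed)
    y = indicators.values_array()
    obs_mask = ~np.isnan(y)
    ks = np.array([post.n_categories[k] for k in post.indicators])
    factor_of = post.factor_of
    n = y.shape[0]

    n_chains, n_draws = post.lam.shape[:2]
    total = n_chains * n_draws
    idx = np.linspace(0, total - 1, min(n_reps, total)).astype(int)

    lam_flat = post.stacked(post.lam)
    tau_flat = [post.stacked(t) for t in post.tau]
    f_obs = np.empty(len(idx))
    f_rep = np.empty(len(idx))
    for r, i in enumerate(idx):
        lam = lam_flat[i]
        taus = [tau_flat[j][i] for j in range(len(ks))]
        y_rep = _simulate_from_draw(rng, n, ks, lam, taus, factor_of)
        rep_mask = np.ones_like(y_rep, dtype=bool)
        if statistic == "lrt":
            f_obs[r] = _lrt_discrepancy(y, obs_mask, lam, taus, factor_of)
            f_rep[r] = _lrt_discrepancy(y_rep, rep_mask, lam, taus, factor_of)
        else:
            f_obs[r] = _discrepancy(y, obs_mask, ks, lam, taus, factor_of)
            f_rep[r] = _discrepancy(y_rep, rep_mask, ks, lam, taus, factor_of)

    diff = f_obs - f_rep
    interval = (float(np.quantile(diff, 0.025)), float(np.quantile(diff, 0.975)))
    p_value = float((f_rep >= f_obs).mean())
    psr_values = psr(post)
    return FitReport(
        psr=psr_values,
        max_psr=max(psr_values.values()),
        f_obs=f_obs,
        f_rep=f_rep,
        diff_interval=interval,
        p_value=p_value,
    )
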