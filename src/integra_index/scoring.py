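"""Facility scores, rankings, rescaling, and cross-wave change metrics.

Each facility's index value is a Bayesian plausible value of its latent
factor score: by default the posterior mean of eta with the posterior SD
as standard error; optionally a seeded random posterior draw (classical
plausible-value semantics).  Scores are ranked 1 = highest (ties
averaged) and mapped to a 1-7 graphing scale by adding 4, sending the
practical -3..3 range to 1..7 (values outside pass through with a
warning).

For fair baseline-vs-endline comparison, endline facilities are scored
against the *baseline* measurement model: loadings and thresholds fixed at
their baseline posterior means, with a small per-facility Gibbs run over
(z, eta) only.  Change between waves is summarized by the per-factor sum
of absolute score differences (SAD) and the Pearson correlation between
waves, plus the within-wave correlation between the two factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from .cfa import Posterior, _truncnorm_draw, resolve_sign
from .ordinalize import IndicatorMatrix


@dataclass
class FactorScores:
    """Long-form scores: one row per facility x factor.

    Columns: facility_id, wave (optional), factor, score, se, and after
    :func:`rank_and_rescale` also rank and rescaled.
    """

    data: pd.DataFrame
    draws: np.ndarray | None = None  # (draws, facilities, factors)

    @property
    def n_factors(self) -> int:
        return int(self.data["factor"].nunique())

    def wide(self, field: str = "score") -> pd.DataFrame:
        return self.data.pivot_table(index="facility_id", columns="factor", values=field)


def _index_frame(post: Posterior) -> pd.DataFrame:
    idx = post.facility_index
    if isinstance(idx, pd.MultiIndex):
        frame = idx.to_frame(index=False)
    else:
        frame = pd.DataFrame({"facility_id": list(idx)})
    if "facility_id" not in frame.columns:
        frame = frame.rename(columns={frame.columns[0]: "facility_id"})
    return frame


def _scores_frame(
    base: pd.DataFrame, mean: np.ndarray, sd: np.ndarray, n_factors: int
) -> pd.DataFrame:
    rows = []
    for f in range(n_factors):
        block = base.copy()
        block["factor"] = f
        block["score"] = mean[:, f]
        block["se"] = sd[:, f]
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def plausible_values(
    post: Posterior, summary: str = "mean", seed: int | None = None
) -> FactorScores:
    """Facility scores from a fitted posterior.

    ``summary="mean"``: posterior mean of eta (SE = posterior SD).
    ``summary="random_draw"``: one seeded draw per facility (independent
    draw indices across facilities), SE still the posterior SD.
    """
    if summary not in ("mean", "random_draw"):
        raise ValueError("summary must be 'mean' or 'random_draw'")
    if not post.sign_resolved:
        post = resolve_sign(post)
    eta = post.stacked(post.eta)  # (S, n, q)
    sd = eta.std(axis=0, ddof=1)
    if summary == "mean":
        val = eta.mean(axis=0)
    else:
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, eta.shape[0], size=eta.shape[1])
        val = eta[picks, np.arange(eta.shape[1]), :]
    frame = _scores_frame(_index_frame(post), val, sd, post.spec.n_factors)
    return FactorScores(data=frame, draws=eta)


def score_with_fixed_params(
    baseline_post: Posterior,
    new_indicators: IndicatorMatrix,
    n_iterations: int = 4000,
    burn_in: int = 1000,
    seed: int | None = None,
) -> FactorScores:
    """Score facilities against a frozen (baseline) measurement model.

    Loadings and thresholds are fixed at the baseline posterior means
    (sign-resolved); only (z, eta) are sampled, so facilities are scored
    conditionally independently — a facility's score does not depend on
    which other facilities are in the batch.
    """
    if not baseline_post.sign_resolved:
        baseline_post = resolve_sign(baseline_post)
    names = baseline_post.indicators
    if list(new_indicators.indicators) != names:
        raise ValueError(
            f"indicator mismatch: baseline {names} vs new {list(new_indicators.indicators)}"
        )
    for k in names:
        base_k = baseline_post.n_categories[k]
        new_k = new_indicators.n_categories[k]
        observed_max = new_indicators.data[k].dropna().max()
        if new_k > base_k or (len(new_indicators.data[k].dropna()) and observed_max >= base_k):
            raise ValueError(
                f"indicator {k!r}: new data uses category >= {base_k}, outside baseline coding"
            )

    lam = baseline_post.stacked(baseline_post.lam).mean(axis=0)  # (p,)
    taus = [baseline_post.stacked(t).mean(axis=0) for t in baseline_post.tau]
    factor_of = baseline_post.factor_of
    q = baseline_post.spec.n_factors

    y = new_indicators.values_array()
    obs_mask = ~np.isnan(y)
    y_int = np.where(obs_mask, y, 0).astype(int)
    n, p = y.shape
    rng = np.random.default_rng(seed)

    lam_mat = np.zeros((p, q))
    lam_mat[np.arange(p), factor_of] = lam
    cov = np.linalg.inv(np.eye(q) + lam_mat.T @ lam_mat)
    chol = np.linalg.cholesky(cov)

    lo = np.full((n, p), -np.inf)
    hi = np.full((n, p), np.inf)
    for j in range(p):
        edges = np.concatenate(([-np.inf], taus[j], [np.inf]))
        lo[:, j] = edges[y_int[:, j]]
        hi[:, j] = edges[y_int[:, j] + 1]

    eta = np.zeros((n, q))
    keep = np.empty((n_iterations - burn_in, n, q))
    for it in range(n_iterations):
        mean = eta[:, factor_of] * lam
        z = _truncnorm_draw(rng, mean, lo, hi)
        if not obs_mask.all():
            z = np.where(obs_mask, z, mean + rng.standard_normal((n, p)))
        mean_eta = z @ lam_mat @ cov.T
        eta = mean_eta + rng.standard_normal((n, q)) @ chol.T
        if it >= burn_in:
            keep[it - burn_in] = eta

    base = new_indicators.data.index
    if isinstance(base, pd.MultiIndex):
        frame0 = base.to_frame(index=False)
    else:
        frame0 = pd.DataFrame({"facility_id": list(base)})
    frame = _scores_frame(frame0, keep.mean(axis=0), keep.std(axis=0, ddof=1), q)
    return FactorScores(data=frame, draws=keep)


def rank_and_rescale(scores: FactorScores) -> FactorScores:
    """Add descending ranks (1 = highest, ties averaged) and the 1-7
    graphing rescale (score + 4), within each wave x factor group."""
    df = scores.data.copy()
    group_cols = ["factor"] + (["wave"] if "wave" in df.columns else [])
    df["rank"] = df.groupby(group_cols)["score"].rank(ascending=False, method="average")
    df["rescaled"] = df["score"] + 4.0
    out_of_range = df[(df["rescaled"] < 1.0) | (df["rescaled"] > 7.0)]
    if len(out_of_range):
        warnings.warn(
            f"{len(out_of_range)} rescaled score(s) outside the 1-7 graphing range "
            "(not clipped)",
            stacklevel=2,
        )
    return FactorScores(data=df, draws=scores.draws)


@dataclass
class ChangeReport:
    """Per-factor baseline-vs-endline change summaries."""

    sad: dict[int, float]  # sum of |endline - baseline| per factor
    between_wave_r: dict[int, float]
    cross_factor_r: dict[str, float]  # wave label -> r(factor0, factor1)
    n_facilities: int

    def summary(self) -> str:
        lines = [f"n facilities matched: {self.n_facilities}"]
        for f in sorted(self.sad):
            r = self.between_wave_r[f]
            r_s = "NA" if np.isnan(r) else f"{r:.2f}"
            lines.append(f"factor {f}: SAD={self.sad[f]:.1f}, baseline-endline r={r_s}")
        for w, r in self.cross_factor_r.items():
            r_s = "NA" if np.isnan(r) else f"{r:.2f}"
            lines.append(f"wave {w}: cross-factor r={r_s}")
        return "\n".join(lines)


def _safe_pearson(a: np.ndarray, b: np.ndarray, label: str) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn(f"degenerate variance in {label}; correlation undefined", stacklevel=3)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def change_metrics(baseline: FactorScores, endline: FactorScores) -> ChangeReport:
    """Sum of absolute differences and correlations between two waves."""
    b = baseline.data
    e = endline.data
    fac_b = set(b["facility_id"])
    fac_e = set(e["facility_id"])
    if fac_b != fac_e:
        raise ValueError(
            f"unmatched facilities: only-baseline {sorted(fac_b - fac_e)}, "
            f"only-endline {sorted(fac_e - fac_b)}"
        )
    sad: dict[int, float] = {}
    between: dict[int, float] = {}
    factors = sorted(int(f) for f in b["factor"].unique())
    for f in factors:
        bv = b[b["factor"] == f].set_index("facility_id")["score"].sort_index()
        ev = e[e["factor"] == f].set_index("facility_id")["score"].sort_index()
        sad[f] = float(np.abs(ev.to_numpy() - bv.to_numpy()).sum())
        between[f] = _safe_pearson(bv.to_numpy(), ev.to_numpy(), f"factor {f} between-wave")
    cross: dict[str, float] = {}
    if len(factors) == 2:
        for label, df in (("baseline", b), ("endline", e)):
            w0 = df[df["factor"] == factors[0]].set_index("facility_id")["score"].sort_index()
            w1 = df[df["factor"] == factors[1]].set_index("facility_id")["score"].sort_index()
            cross[label] = _safe_pearson(w0.to_numpy(), w1.to_numpy(), f"{label} cross-factor")
    return ChangeReport(
        sad=sad, between_wave_r=between, cross_factor_r=cross, n_facilities=len(fac_b)
    )


def plot_scores(
    baseline: FactorScores,
    endline: FactorScores | None = None,
    factor_names: dict[int, str] | None = None,
    path: str | None = None,
):
    """Simple per-facility before/after dot plot of rescaled scores."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    factor_names = factor_names or {0: "functional", 1: "structural"}
    factors = sorted(baseline.data["factor"].unique())
    fig, axes = plt.subplots(len(factors), 1, figsize=(10, 3.2 * len(factors)), squeeze=False)
    order = None
    for ax_row, f in zip(axes, factors):
        ax = ax_row[0]
        bf = baseline.data[baseline.data["factor"] == f].set_index("facility_id")
        if order is None:
            order = bf["score"].sort_values(ascending=False).index
        vals = bf.loc[order, "score"] + 4.0
        ax.plot(range(len(order)), vals, "o", label="baseline")
        if endline is not None:
            ef = endline.data[endline.data["factor"] == f].set_index("facility_id")
            ax.plot(range(len(order)), ef.loc[order, "score"] + 4.0, "s", label="endline")
        ax.set_ylabel(f"{factor_names.get(f, f)} (1-7)")
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels(order, rotation=90, fontsize=6)
        ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
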