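"""End-to-end pipeline: raw CSVs -> attributes -> indicators -> posterior
-> diagnostics -> scores -> change report, with a provenance manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .attributes import build_attribute_table
from .cfa import ModelSpec, Priors, SamplerConfig, fit, resolve_sign, standardize_loadings
from .diagnostics import ppc
from .ordinalize import default_scheme, ordinalize
from .scoring import change_metrics, plausible_values, rank_and_rescale, score_with_fixed_params


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class WaveInputs:
    flow_csv: str
    inventory_dir: str


@dataclass
class RunConfig:
    """Everything needed to re-run the pipeline byte-for-byte.

    ``waves`` maps wave label -> input paths; the first label (sorted
    baseline-first) is the reference wave whose fitted measurement model
    scores all waves.
    """

    waves: dict[str, WaveInputs]
    out_dir: str
    n_factors: int = 2
    n_days: int = 5
    seed: int | None = None
    n_chains: int = 4
    n_iterations: int = 50_000
    ppc_reps: int = 1000
    allow_missing: bool = False
    loading_prior_variance: float = 100.0
    threshold_prior_variance: float = 100.0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["waves"] = {k: WaveInputs(**v) for k, v in d["waves"].items()}
        return cls(**d)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run every stage, writing artifacts under ``config.out_dir``.

    Returns the in-memory artifacts keyed by name.  Deterministic given
    the seed: reruns produce identical posterior summaries.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wave_order = sorted(config.waves, key=lambda w: (w != "baseline", w))
    artifacts: dict[str, object] = {}

    tables = []
    for wave in wave_order:
        inputs = config.waves[wave]
        visits = _stage(f"read_flow:{wave}")(io.read_client_flow)(inputs.flow_csv)
        inventories = _stage(f"read_inventory:{wave}")(io.read_inventories)(inputs.inventory_dir)
        table = _stage(f"attributes:{wave}")(build_attribute_table)(
            visits, inventories, wave=wave, n_days=config.n_days
        )
        if not config.allow_missing and table[list(io.ATTRIBUTE_NAMES)].isna().any().any():
            bad = table[list(io.ATTRIBUTE_NAMES)].isna().any()
            raise PipelineError(
                f"attributes:{wave}",
                f"missing attribute values in {list(bad[bad].index)}; "
                "rerun with allow_missing=True to fit anyway",
            )
        io.write_attribute_table(table, out / f"attributes_{wave}.csv")
        tables.append(table)
    pooled = pd.concat(tables, ignore_index=True)
    artifacts["attributes"] = pooled

    # attributes with no data at all (e.g. a missing staff-log register)
    # are dropped when allow_missing is set; the model runs on the rest
    attribute_columns = list(io.ATTRIBUTE_NAMES)
    if config.allow_missing:
        dead = [c for c in attribute_columns if pooled[c].isna().all()]
        if dead:
            warnings.warn(f"dropping all-missing attributes: {dead}", stacklevel=2)
            attribute_columns = [c for c in attribute_columns if c not in dead]

    matrix = _stage("ordinalize")(ordinalize)(
        pooled, default_scheme(), attribute_columns=attribute_columns
    )
    io.write_indicator_matrix(matrix, out / "indicators.csv")
    artifacts["indicators"] = matrix

    # fit on the reference (baseline) wave only; its parameters score all waves
    ref_wave = wave_order[0]
    ref_mask = matrix.data.index.get_level_values("wave") == ref_wave
    ref_matrix = _stage("ordinalize")(_subset)(matrix, ref_mask)

    if config.n_factors == 2:
        full = ModelSpec.two_factor()
        spec = ModelSpec(
            n_factors=2,
            loading_pattern={k: full.loading_pattern[k] for k in matrix.indicators},
        )
    else:
        spec = ModelSpec.one_factor(matrix.indicators)
    priors = Priors(config.loading_prior_variance, config.threshold_prior_variance)
    sampler = SamplerConfig(
        n_chains=config.n_chains, n_iterations=config.n_iterations, seed=config.seed
    )
    post = _stage("fit")(fit)(ref_matrix, spec, priors, sampler)
    post = resolve_sign(post)
    io.save_posterior(post, out / "posterior.npz")
    artifacts["posterior"] = post

    loadings = standardize_loadings(post)
    loadings.to_csv(out / "loadings.csv")
    artifacts["loadings"] = loadings

    report = _stage("diagnose")(ppc)(
        post, ref_matrix, n_reps=config.ppc_reps, seed=_derive_seed(config.seed, "ppc")
    )
    (out / "fit_report.json").write_text(
        json.dumps(
            {
                "max_psr": report.max_psr,
                "psr": report.psr,
                "diff_interval": list(report.diff_interval),
                "p_value": report.p_value,
                "converged": report.converged,
                "good_fit": report.good_fit,
            },
            indent=2,
        )
    )
    artifacts["fit_report"] = report

    scores = {}
    for wave in wave_order:
        mask = matrix.data.index.get_level_values("wave") == wave
        wave_matrix = _subset(matrix, mask)
        if wave == ref_wave:
            sc = _stage(f"score:{wave}")(plausible_values)(post)
        else:
            sc = _stage(f"score:{wave}")(score_with_fixed_params)(
                post, wave_matrix, seed=_derive_seed(config.seed, f"score:{wave}")
            )
        sc = rank_and_rescale(sc)
        if "wave" not in sc.data.columns:
            sc.data["wave"] = wave
        io.write_scores(sc, out / f"scores_{wave}.csv")
        scores[wave] = sc
    artifacts["scores"] = scores

    if len(wave_order) == 2:
        change = _stage("compare_waves")(change_metrics)(scores[wave_order[0]], scores[wave_order[1]])
        (out / "change_report.json").write_text(
            json.dumps(
                {
                    "sad": change.sad,
                    "between_wave_r": change.between_wave_r,
                    "cross_factor_r": change.cross_factor_r,
                    "n_facilities": change.n_facilities,
                },
                indent=2,
            )
        )
        artifacts["change_report"] = change

    manifest = {
        "config": json.loads(config.to_json()),
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest
    return artifacts


def _subset(matrix, mask):
    from .ordinalize import IndicatorMatrix

    return IndicatorMatrix(
        data=matrix.data[mask], n_categories=dict(matrix.n_categories), scheme=matrix.scheme
    )


def _derive_seed(seed: int | None, label: str) -> int | None:
    if seed is None:
        return None
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
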