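"""Coding of continuous attributes into ordinal indicators.

The measurement model consumes ordered categories, not raw proportions.
Each attribute gets a per-attribute rule:

* ``as_is_ordinal`` — values are already small non-negative integers
  (used for the 0-3 ART score),
* ``cutpoints`` — an ascending list of thresholds; value v maps to the
  number of cutpoints strictly below it... precisely, category
  ``sum(v > c for c in cutpoints)``, so ties at a cutpoint fall in the
  lower category,
* ``quantile`` — K categories with cutpoints at the empirical quantiles
  of the (by default pooled-across-waves) values, which guarantees
  occupied categories at small n and identical coding for both waves.

The mapping is monotone by construction: larger values never map to a
smaller category.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attributes import ATTRIBUTE_NAMES


@dataclass(frozen=True)
class AttributeRule:
    """Coding rule for one attribute: exactly one mode is active."""

    kind: str  # "as_is_ordinal" | "cutpoints" | "quantile"
    cutpoints: tuple[float, ...] = ()
    n_categories: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("as_is_ordinal", "cutpoints", "quantile"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "cutpoints":
            if not self.cutpoints:
                raise ValueError("cutpoints rule needs at least one cutpoint")
            if any(b <= a for a, b in zip(self.cutpoints, self.cutpoints[1:])):
                raise ValueError(f"cutpoints must be strictly ascending: {self.cutpoints}")
        if self.kind == "quantile" and self.n_categories < 2:
            raise ValueError("quantile rule needs K >= 2")


def default_scheme() -> "OrdinalizationScheme":
    """Quantile terciles for the seven proportion attributes; the 0-3 ART
    score kept as-is."""
    rules = {name: AttributeRule("quantile", n_categories=3) for name in ATTRIBUTE_NAMES}
    rules["art_location_score"] = AttributeRule("as_is_ordinal")
    return OrdinalizationScheme(rules=rules)


@dataclass
class OrdinalizationScheme:
    """Per-attribute coding rules plus the cutpoints actually used.

    ``fitted_cutpoints`` is populated by :func:`ordinalize` for quantile
    rules so that a scheme fitted on pooled baseline+endline data can be
    re-applied wave by wave (or to new data) with identical coding.
    """

    rules: Mapping[str, AttributeRule]
    fitted_cutpoints: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rules": {
                    k: {"kind": r.kind, "cutpoints": list(r.cutpoints), "n_categories": r.n_categories}
                    for k, r in self.rules.items()
                },
                "fitted_cutpoints": {k: list(v) for k, v in self.fitted_cutpoints.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "OrdinalizationScheme":
        d = json.loads(text)
        rules = {
            k: AttributeRule(r["kind"], tuple(r["cutpoints"]), r["n_categories"])
            for k, r in d["rules"].items()
        }
        return cls(rules=rules, fitted_cutpoints={k: tuple(v) for k, v in d["fitted_cutpoints"].items()})


@dataclass
class IndicatorMatrix:
    """Facilities × indicators of ordinal categories.

    ``data`` is a float DataFrame (NaN = missing) whose non-missing entries
    are the integers 0..K-1 for that column; ``n_categories`` maps each
    indicator to its K; ``scheme`` records the coding provenance.
    """

    data: pd.DataFrame
    n_categories: dict[str, int]
    scheme: OrdinalizationScheme | None = None

    def __post_init__(self) -> None:
        for col in self.data.columns:
            k = self.n_categories[col]
            vals = self.data[col].dropna()
            if len(vals) and (vals.max() >= k or vals.min() < 0):
                raise ValueError(f"indicator {col!r} has values outside 0..{k - 1}")

    def require_fittable(self) -> None:
        """Model fitting needs >= 2 observed categories per indicator."""
        for col in self.data.columns:
            if self.data[col].dropna().nunique() < 2:
                raise ValueError(
                    f"indicator {col!r} collapses to a single observed category; "
                    "it cannot enter the measurement model"
                )

    @property
    def indicators(self) -> list[str]:
        return list(self.data.columns)

    def values_array(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def category_frequencies(self) -> dict[str, list[int]]:
        out = {}
        for col in self.data.columns:
            k = self.n_categories[col]
            counts = self.data[col].value_counts()
            out[col] = [int(counts.get(float(c), 0)) for c in range(k)]
        return out


def _apply_cutpoints(values: np.ndarray, cutpoints: Sequence[float]) -> np.ndarray:
    out = np.zeros_like(values)
    for c in cutpoints:
        out += (values > c).astype(float)
    out[np.isnan(values)] = np.nan
    return out


def _quantile_cutpoints(values: np.ndarray, k: int) -> tuple[float, ...]:
    clean = values[~np.isnan(values)]
    if clean.size == 0:
        raise ValueError("cannot derive quantile cutpoints from all-missing values")
    qs = np.quantile(clean, np.arange(1, k) / k)
    # collapse duplicate quantiles (heavily tied data); categories stay contiguous
    cuts = sorted(set(float(q) for q in qs))
    return tuple(cuts)


def ordinalize(
    table: pd.DataFrame,
    scheme: OrdinalizationScheme | None = None,
    attribute_columns: Sequence[str] = ATTRIBUTE_NAMES,
    index_columns: Sequence[str] = ("facility_id", "wave"),
) -> IndicatorMatrix:
    """Code an attribute table (possibly both waves pooled) into categories.

    Quantile cutpoints are derived from all rows passed in — pass the pooled
    two-wave table to obtain wave-comparable coding — and recorded on the
    returned matrix's scheme.  A previously fitted scheme (with
    ``fitted_cutpoints``) is re-applied verbatim.
    """
    if scheme is None:
        scheme = default_scheme()
    missing_rules = [c for c in attribute_columns if c not in scheme.rules]
    if missing_rules:
        raise ValueError(f"scheme lacks rules for attributes: {missing_rules}")

    fitted = dict(scheme.fitted_cutpoints)
    coded: dict[str, np.ndarray] = {}
    n_categories: dict[str, int] = {}
    for col in attribute_columns:
        rule = scheme.rules[col]
        values = table[col].to_numpy(dtype=float)
        if rule.kind == "as_is_ordinal":
            clean = values[~np.isnan(values)]
            if clean.size and not np.allclose(clean, np.round(clean)):
                # facility means of the 0-3 client scale are continuous;
                # fall back to quartile coding rather than refusing
                warnings.warn(
                    f"attribute {col!r} is not integer-coded; "
                    "as_is_ordinal falling back to quantile (K=4)",
                    stacklevel=2,
                )
                cuts = fitted.get(col)
                if cuts is None:
                    cuts = _quantile_cutpoints(values, 4)
                    fitted[col] = cuts
                out = _apply_cutpoints(values, cuts)
                k = len(cuts) + 1
            else:
                lo = 0.0 if clean.size == 0 else min(0.0, clean.min())
                out = values - lo
                k = int(np.nanmax(out)) + 1 if clean.size else 2
        elif rule.kind == "cutpoints":
            cuts = rule.cutpoints
            fitted[col] = cuts
            out = _apply_cutpoints(values, cuts)
            k = len(cuts) + 1
        else:  # quantile
            cuts = fitted.get(col)
            if cuts is None:
                cuts = _quantile_cutpoints(values, rule.n_categories)
                fitted[col] = cuts
            out = _apply_cutpoints(values, cuts)
            k = len(cuts) + 1
        coded[col] = out
        n_categories[col] = k

    frame = pd.DataFrame(coded, index=pd.MultiIndex.from_frame(table[list(index_columns)]))
    used_scheme = OrdinalizationScheme(rules=dict(scheme.rules), fitted_cutpoints=fitted)
    matrix = IndicatorMatrix(data=frame, n_categories=n_categories, scheme=used_scheme)
    matrix.require_fittable()
    return matrix
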