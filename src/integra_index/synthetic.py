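"""Synthetic two-wave facility studies with known truth.

The generator emulates the study design the index method targets: ~40
clinics observed at baseline and endline, with two orthogonal latent
dimensions — functional integration (actual integrated service receipt)
and structural integration (co-located capacity) — driving four ordinal
indicators each through a probit measurement model.  Default standardized
loadings are the fitted baseline values of the published two-factor model
(functional: 0.489, 0.774, 0.979, 0.984; structural: 0.952, 0.617, 0.836,
0.795), so recovery tests run under realistic signal strength.

Three layers, each reproducible from the master seed:

1. :func:`generate_latent` — per-facility factor scores, standard normal
   and independent across factors; wave 2 follows a mean-reverting change
   model ``eta2 = (1-kappa)*eta1 + sigma*eps`` with ``sigma`` chosen to
   keep unit marginal variance (so the wave correlation is ``1-kappa``).
2. :func:`generate_indicators` — ordinal indicators from the probit model:
   latent response ``lambda*eta + N(0,1)`` cut at thresholds, with raw
   ``lambda = s/sqrt(1-s^2)`` from the standardized loading ``s``.
3. :func:`generate_flow` — client-flow contact records and facility
   inventories whose *computed* attributes have expectation equal to
   per-facility targets; a fixture for the attribute pipeline, not a
   behavioural simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .attributes import ATTRIBUTE_NAMES, FUNCTIONAL_ATTRIBUTES, STRUCTURAL_ATTRIBUTES, FacilityInventory
from .ordinalize import IndicatorMatrix, OrdinalizationScheme, AttributeRule
from .services import HIV_SERVICES, RH_SERVICES

#: Fitted baseline standardized loadings of the two-factor model, used as
#: generator defaults.
DEFAULT_LOADINGS: dict[str, float] = {
    "art_location_score": 0.489,
    "temporal_range": 0.774,
    "consult_integration": 0.979,
    "visit_integration": 0.984,
    "unit_availability": 0.952,
    "facility_availability": 0.617,
    "provider_range": 0.836,
    "room_range": 0.795,
}

_TERCILE_CUTS = tuple(float(ndtri(q)) for q in (1 / 3, 2 / 3))
_QUARTILE_CUTS = tuple(float(ndtri(q)) for q in (0.25, 0.5, 0.75))

#: Standardized-scale thresholds giving equal-probability categories.
DEFAULT_THRESHOLDS: dict[str, tuple[float, ...]] = {
    name: (_QUARTILE_CUTS if name == "art_location_score" else _TERCILE_CUTS)
    for name in ATTRIBUTE_NAMES
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_facilities: int = 40
    n_waves: int = 2
    loadings: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    thresholds: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    #: mean-reversion per factor: eta2 = (1-kappa)*eta1 + sqrt(1-(1-kappa)^2)*eps
    kappa: tuple[float, float] = (0.5, 0.1)
    #: client-flow layer
    n_days: int = 5
    clients_per_day: int = 20
    n_rooms: int = 2
    n_staff: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_facilities < 1 or self.n_waves not in (1, 2):
            raise ValueError("need n_facilities >= 1 and 1 or 2 waves")
        for k, s in self.loadings.items():
            if not -1 < s < 1:
                raise ValueError(f"standardized loading for {k} must be in (-1,1), got {s}")
        for k, t in self.thresholds.items():
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ValueError(f"thresholds for {k} must be strictly ascending")

    @property
    def factor_of(self) -> dict[str, int]:
        out = {k: 0 for k in FUNCTIONAL_ATTRIBUTES}
        out.update({k: 1 for k in STRUCTURAL_ATTRIBUTES})
        return out

    def raw_loading(self, name: str) -> float:
        s = self.loadings[name]
        return s / math.sqrt(1.0 - s * s)

    def raw_thresholds(self, name: str) -> np.ndarray:
        lam = self.raw_loading(name)
        scale = math.sqrt(lam * lam + 1.0)
        return np.asarray(self.thresholds[name]) * scale


WAVES = ("baseline", "endline")


def _facility_ids(n: int) -> list[str]:
    return [f"F{i + 1:03d}" for i in range(n)]


def generate_latent(config: GeneratorConfig, rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """True factor scores per wave: arrays (n_facilities, 2)."""
    rng = rng or np.random.default_rng(config.seed)
    eta1 = rng.standard_normal((config.n_facilities, 2))
    out = {"baseline": eta1}
    if config.n_waves == 2:
        eta2 = np.empty_like(eta1)
        for f in range(2):
            rho = 1.0 - config.kappa[f]
            sigma = math.sqrt(max(0.0, 1.0 - rho * rho))
            eta2[:, f] = rho * eta1[:, f] + sigma * rng.standard_normal(config.n_facilities)
        out["endline"] = eta2
    return out


def generate_indicators(
    true_scores: Mapping[str, np.ndarray],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, IndicatorMatrix]:
    """Ordinal indicators per wave from the probit measurement model."""
    rng = rng or np.random.default_rng(config.seed)
    fac = _facility_ids(config.n_facilities)
    factor_of = config.factor_of
    out: dict[str, IndicatorMatrix] = {}
    for wave, eta in true_scores.items():
        cols: dict[str, np.ndarray] = {}
        n_cats: dict[str, int] = {}
        for name in ATTRIBUTE_NAMES:
            lam = config.raw_loading(name)
            tau = config.raw_thresholds(name)
            z = lam * eta[:, factor_of[name]] + rng.standard_normal(config.n_facilities)
            cols[name] = np.searchsorted(tau, z).astype(float)
            n_cats[name] = len(tau) + 1
        idx = pd.MultiIndex.from_arrays([fac, [wave] * len(fac)], names=["facility_id", "wave"])
        scheme = OrdinalizationScheme(
            rules={k: AttributeRule("as_is_ordinal") for k in ATTRIBUTE_NAMES}
        )
        out[wave] = IndicatorMatrix(
            data=pd.DataFrame(cols, index=idx), n_categories=n_cats, scheme=scheme
        )
    return out


def attribute_targets_from_latent(
    true_scores: Mapping[str, np.ndarray],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Continuous per-facility attribute targets consistent with the latent
    structure: target = Phi(latent response), times 3 for the ART score."""
    rng = rng or np.random.default_rng(config.seed)
    fac = _facility_ids(config.n_facilities)
    factor_of = config.factor_of
    out = {}
    for wave, eta in true_scores.items():
        cols = {}
        for name in ATTRIBUTE_NAMES:
            s = config.loadings[name]
            x = s * eta[:, factor_of[name]] + math.sqrt(1 - s * s) * rng.standard_normal(
                config.n_facilities
            )
            t = ndtr(x)
            cols[name] = 3.0 * t if name == "art_location_score" else t
        frame = pd.DataFrame(cols, index=pd.Index(fac, name="facility_id"))
        # Feasibility of the flow layer requires consult <= visit <= temporal
        # (a client integrated in one contact is integrated in the visit; a
        # visit-integrated client implies an integration-active day).  Enforce
        # the ordering per facility; the distortion of the nominal loadings is
        # confined to the flow fixture.
        frame["consult_integration"] = np.minimum(
            frame["consult_integration"], frame["visit_integration"]
        )
        frame["temporal_range"] = np.maximum(
            frame["temporal_range"], frame["visit_integration"]
        )
        # ART level 3 requires same-contact co-delivery, so the mean ART
        # score cannot exceed 3x the consult-integration share.
        frame["art_location_score"] = np.minimum(
            frame["art_location_score"], 3.0 * frame["consult_integration"]
        )
        out[wave] = frame
    return out


class InfeasibleTargets(ValueError):
    """Raised when requested attribute targets cannot coexist."""


def _art_allocation(m: float, p_consult: float, p_visit_extra: float) -> tuple[float, ...]:
    """Split per-active-day client mass among behaviour classes.

    Returns (pA, pB, pC, pD, pE): ART+SRH same provider; consult-integrated
    without ART; visit-only integrated; ART alone; ART referral only.
    ``m`` is the required conditional mean ART score, ``p_consult`` the
    conditional consult-integration probability, ``p_visit_extra`` the
    extra visit-only probability.
    """
    if m > 3.0 + 1e-9:
        raise InfeasibleTargets(f"ART target needs conditional mean {m:.3f} > 3")
    if p_consult + p_visit_extra > 1.0 + 1e-9:
        raise InfeasibleTargets("visit-integration target exceeds 1 conditional on active days")
    pA = min(p_consult, m / 3.0)
    rest = m - 3.0 * pA
    free = 1.0 - p_consult - p_visit_extra
    pD = min(rest / 2.0, free)
    rest -= 2.0 * pD
    pE = min(rest, free - pD)
    rest -= pE
    if rest > 1e-9:
        raise InfeasibleTargets(
            "ART score target cannot be met alongside the integration targets"
        )
    pB = p_consult - pA
    return pA, pB, p_visit_extra, pD, pE


def generate_flow(
    targets: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    wave: str = "baseline",
) -> tuple[pd.DataFrame, dict[str, FacilityInventory]]:
    """Client-flow contacts and inventories matching attribute targets.

    ``targets``: one row per facility (index facility_id) with the eight
    attribute columns as expectations for the *computed* attributes.
    Returns a contact-level DataFrame (the client-flow CSV schema) and a
    facility -> inventory mapping.  Infeasible combinations (consult >
    visit, integration targets with a zero temporal target, ART mean
    unreachable) raise :class:`InfeasibleTargets`.
    """
    rng = rng or np.random.default_rng(config.seed)
    hiv = sorted(HIV_SERVICES)
    everything = sorted(RH_SERVICES | HIV_SERVICES)
    rows: list[dict] = []
    inventories: dict[str, FacilityInventory] = {}

    for fac, t in targets.iterrows():
        p_c, p_v = float(t["consult_integration"]), float(t["visit_integration"])
        t_act = float(t["temporal_range"])
        art = float(t["art_location_score"])
        if p_c > p_v + 1e-9:
            raise InfeasibleTargets(
                f"{fac}: consult_integration {p_c:.3f} > visit_integration {p_v:.3f}"
            )
        needs_activity = max(p_c, p_v, art) > 1e-12
        if needs_activity and t_act <= 0:
            raise InfeasibleTargets(f"{fac}: integration targets require temporal_range > 0")
        if needs_activity:
            pA, pB, pC, pD, pE = _art_allocation(
                art / t_act, p_c / t_act, (p_v - p_c) / t_act
            )
            if p_v / t_act > 1.0 + 1e-9:
                raise InfeasibleTargets(f"{fac}: visit target {p_v:.3f} > temporal target {t_act:.3f}")
        else:
            pA = pB = pC = pD = pE = 0.0

        inventories[fac] = FacilityInventory(
            facility_id=fac,
            unit_services=frozenset(s for s in hiv if rng.uniform() < t["unit_availability"]),
            facility_services=frozenset(
                s for s in everything if rng.uniform() < t["facility_availability"]
            ),
            room_logs={
                f"{fac}-R{r + 1}": frozenset(s for s in hiv if rng.uniform() < t["room_range"])
                for r in range(config.n_rooms)
            },
            staff_logs={
                f"{fac}-S{r + 1}": frozenset(s for s in hiv if rng.uniform() < t["provider_range"])
                for r in range(config.n_staff)
            },
        )

        probs = np.clip(np.array([pA, pB, pC, pD, pE, 0.0]), 0.0, None)
        probs[-1] = max(0.0, 1.0 - probs[:5].sum())
        probs /= probs.sum()
        client_no = 0
        for day in range(1, config.n_days + 1):
            active = rng.uniform() < t_act
            for _ in range(config.clients_per_day):
                client_no += 1
                cid = f"{fac}-{wave}-C{client_no:05d}"
                kind = rng.choice(6, p=probs) if active else 5
                base = dict(facility_id=fac, day=day, client_id=cid)
                if kind == 0:  # ART + SRH, same provider
                    rows.append({**base, "provider_id": "P1", "services": "ART;FP", "referrals": ""})
                elif kind == 1:  # RH + HIV in one contact, no ART
                    rows.append(
                        {**base, "provider_id": "P1", "services": "FP;HIV_TEST", "referrals": ""}
                    )
                elif kind == 2:  # both classes, separate providers
                    rows.append({**base, "provider_id": "P1", "services": "PNC", "referrals": ""})
                    rows.append(
                        {**base, "provider_id": "P2", "services": "HIV_TEST", "referrals": ""}
                    )
                elif kind == 3:  # ART alone
                    rows.append({**base, "provider_id": "P1", "services": "ART", "referrals": ""})
                elif kind == 4:  # referred for ART
                    rows.append({**base, "provider_id": "P1", "services": "FP", "referrals": "ART"})
                else:  # plain RH visit
                    rows.append({**base, "provider_id": "P1", "services": "ANC", "referrals": ""})

    return pd.DataFrame(rows), inventories


@dataclass
class SyntheticStudy:
    """A complete generated study: truth, indicators, optional flow layer."""

    config: GeneratorConfig
    true_scores: dict[str, np.ndarray]
    indicators: dict[str, IndicatorMatrix]
    targets: dict[str, pd.DataFrame] | None = None
    flow: dict[str, tuple[pd.DataFrame, dict[str, FacilityInventory]]] | None = None

    @property
    def facility_ids(self) -> list[str]:
        return _facility_ids(self.config.n_facilities)


def generate_study(config: GeneratorConfig, with_flow: bool = False) -> SyntheticStudy:
    """Deterministic full study from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_ind, rng_tgt, rng_flow = (
        np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(4)
    )
    scores = generate_latent(config, rng_latent)
    indicators = generate_indicators(scores, config, rng_ind)
    targets = None
    flow = None
    if with_flow:
        targets = attribute_targets_from_latent(scores, config, rng_tgt)
        flow = {
            wave: generate_flow(targets[wave], config, rng_flow, wave=wave)
            for wave in scores
        }
    return SyntheticStudy(
        config=config, true_scores=scores, indicators=indicators, targets=targets, flow=flow
    )
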