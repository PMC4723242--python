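"""Eight facility-level integration attributes.

Four "structural" attributes describe co-located capacity, from inventory
and register data:

* ``unit_availability`` — share of the 5 HIV-related services available in
  the MCH/FP unit,
* ``facility_availability`` — share of all 8 services available anywhere in
  the facility,
* ``room_range`` — mean over MCH/FP consultation rooms of the share of HIV
  services provided in the room,
* ``provider_range`` — mean over MCH/FP clinical staff of the share of HIV
  services they provide in a day.

Four "functional" attributes describe actual integrated receipt, from
client-flow records over a (default five-day) observation window:

* ``temporal_range`` — share of window days on which both an RH and an HIV
  service were received by someone,
* ``consult_integration`` — share of clients receiving an RH and an HIV
  service within a single provider contact,
* ``visit_integration`` — share of clients receiving both classes at any
  point during their one-day visit,
* ``art_location_score`` — mean over clients of a 0-3 ART co-delivery
  score (0 no ART and no referral; 1 referred only; 2 ART received alone or
  from a separate provider; 3 ART together with an SRH service from the
  same provider).

Missing inputs yield explicit missing values (NaN), never silent zeros.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .services import (
    HIV_SERVICES,
    RH_SERVICES,
    SRH_FOR_ART_SCORE,
    validate_codes,
)

ATTRIBUTE_NAMES: tuple[str, ...] = (
    "unit_availability",
    "facility_availability",
    "room_range",
    "art_location_score",
    "temporal_range",
    "provider_range",
    "consult_integration",
    "visit_integration",
)

FUNCTIONAL_ATTRIBUTES: tuple[str, ...] = (
    "art_location_score",
    "temporal_range",
    "consult_integration",
    "visit_integration",
)

STRUCTURAL_ATTRIBUTES: tuple[str, ...] = (
    "unit_availability",
    "facility_availability",
    "provider_range",
    "room_range",
)

MISSING = float("nan")


@dataclass(frozen=True)
class ClientContact:
    """One provider contact: services received and referrals issued."""

    facility_id: str
    day: int
    client_id: str
    provider_id: str
    services_received: frozenset[str] = frozenset()
    referrals: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "services_received", validate_codes(self.services_received))
        object.__setattr__(self, "referrals", validate_codes(self.referrals))


@dataclass(frozen=True)
class ClientVisit:
    """All of one client's contacts at one facility on one day."""

    facility_id: str
    day: int
    client_id: str
    contacts: tuple[ClientContact, ...]

    def __post_init__(self) -> None:
        if not self.contacts:
            raise ValueError("a visit needs at least one contact")
        for c in self.contacts:
            if (c.facility_id, c.day, c.client_id) != (self.facility_id, self.day, self.client_id):
                raise ValueError(
                    f"contact {(c.facility_id, c.day, c.client_id)} does not belong to "
                    f"visit {(self.facility_id, self.day, self.client_id)}"
                )

    @property
    def all_services(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for c in self.contacts:
            out |= c.services_received
        return out

    @property
    def all_referrals(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for c in self.contacts:
            out |= c.referrals
        return out


@dataclass
class FacilityInventory:
    """Service availability and room/staff provision logs for one facility.

    ``unit_services`` ⊄ ``facility_services`` is tolerated with a warning:
    real registers can disagree.  Non-HIV codes in room/staff logs are
    dropped (those attributes are defined over HIV services only).
    """

    facility_id: str
    unit_services: frozenset[str] | None = None
    facility_services: frozenset[str] | None = None
    room_logs: Mapping[str, frozenset[str]] = field(default_factory=dict)
    staff_logs: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit_services is not None:
            self.unit_services = validate_codes(self.unit_services)
        if self.facility_services is not None:
            self.facility_services = validate_codes(self.facility_services)
        if (
            self.unit_services is not None
            and self.facility_services is not None
            and not self.unit_services <= self.facility_services
        ):
            warnings.warn(
                f"facility {self.facility_id}: unit services "
                f"{sorted(self.unit_services - self.facility_services)} not in the "
                "facility-wide register",
                stacklevel=2,
            )
        self.room_logs = {
            room: validate_codes(codes) & HIV_SERVICES for room, codes in self.room_logs.items()
        }
        self.staff_logs = {
            staff: validate_codes(codes) & HIV_SERVICES for staff, codes in self.staff_logs.items()
        }


@dataclass
class AttributeVector:
    """One facility's eight attribute values for one wave, with denominators."""

    facility_id: str
    wave: str
    values: dict[str, float]
    denominators: dict[str, int]

    def __post_init__(self) -> None:
        for name in ATTRIBUTE_NAMES:
            v = self.values.get(name, MISSING)
            if math.isnan(v):
                continue
            hi = 3.0 if name == "art_location_score" else 1.0
            if not 0.0 <= v <= hi:
                raise ValueError(f"{name}={v} outside [0, {hi}] for facility {self.facility_id}")


# ---------------------------------------------------------------------------
# structural attributes


def compute_unit_availability(inv: FacilityInventory) -> float:
    """Share of the 5 HIV services available in the MCH/FP unit."""
    if inv.unit_services is None:
        warnings.warn(f"facility {inv.facility_id}: no MCH/FP unit record", stacklevel=2)
        return MISSING
    return len(inv.unit_services & HIV_SERVICES) / len(HIV_SERVICES)


def compute_facility_availability(inv: FacilityInventory) -> float:
    """Share of all 8 RH+HIV services available anywhere in the facility."""
    if inv.facility_services is None:
        warnings.warn(f"facility {inv.facility_id}: no facility-wide record", stacklevel=2)
        return MISSING
    return len(inv.facility_services & (RH_SERVICES | HIV_SERVICES)) / 8


def compute_room_range(inv: FacilityInventory) -> float:
    """Unweighted mean over consultation rooms of HIV services provided / 5."""
    if not inv.room_logs:
        return MISSING
    shares = [len(s) / len(HIV_SERVICES) for s in inv.room_logs.values()]
    return sum(shares) / len(shares)


def compute_provider_range(inv: FacilityInventory) -> float:
    """Unweighted mean over clinical staff of HIV services provided / 5."""
    if not inv.staff_logs:
        return MISSING
    shares = [len(s) / len(HIV_SERVICES) for s in inv.staff_logs.values()]
    return sum(shares) / len(shares)


# ---------------------------------------------------------------------------
# functional attributes (client-flow based)


def compute_temporal_range(visits: Sequence[ClientVisit], n_days: int = 5) -> float:
    """Share of window days on which both service classes were received."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    days = {v.day for v in visits}
    if len(days) > n_days:
        raise ValueError(
            f"{len(days)} distinct observed days exceed the declared {n_days}-day window"
        )
    both = 0
    for day in days:
        received: set[str] = set()
        for v in visits:
            if v.day == day:
                received |= v.all_services
        if received & RH_SERVICES and received & HIV_SERVICES:
            both += 1
    return both / n_days


def _eligible(visits: Sequence[ClientVisit], restrict_to_served: bool) -> list[ClientVisit]:
    if not restrict_to_served:
        return list(visits)
    return [v for v in visits if v.all_services]


def compute_consult_integration(
    visits: Sequence[ClientVisit], restrict_to_served: bool = False
) -> float:
    """Share of clients with both classes within one provider contact."""
    pool = _eligible(visits, restrict_to_served)
    if not pool:
        return MISSING
    hits = sum(
        1
        for v in pool
        if any(
            c.services_received & RH_SERVICES and c.services_received & HIV_SERVICES
            for c in v.contacts
        )
    )
    return hits / len(pool)


def compute_visit_integration(
    visits: Sequence[ClientVisit], restrict_to_served: bool = False
) -> float:
    """Share of clients with both classes at any point in the day's visit."""
    pool = _eligible(visits, restrict_to_served)
    if not pool:
        return MISSING
    hits = sum(
        1 for v in pool if v.all_services & RH_SERVICES and v.all_services & HIV_SERVICES
    )
    return hits / len(pool)


def client_art_score(visit: ClientVisit) -> int:
    """0-3 ART co-delivery score for one client visit.

    3: ART received together with an SRH service from the same provider;
    2: ART received (alone, or with other services from a different
    provider); 1: referred for ART but none received; 0: neither.
    """
    got_art = any("ART" in c.services_received for c in visit.contacts)
    if got_art:
        same_provider_srh = any(
            "ART" in c.services_received and c.services_received & SRH_FOR_ART_SCORE
            for c in visit.contacts
        )
        return 3 if same_provider_srh else 2
    if "ART" in visit.all_referrals:
        return 1
    return 0


def compute_art_score(
    visits: Sequence[ClientVisit], restrict_to_served: bool = False
) -> float:
    """Facility ART score: mean of the client-level 0-3 scores."""
    pool = _eligible(visits, restrict_to_served)
    if not pool:
        return MISSING
    return sum(client_art_score(v) for v in pool) / len(pool)


# ---------------------------------------------------------------------------
# assembly


def group_contacts(contacts: Iterable[ClientContact]) -> list[ClientVisit]:
    """Group raw contacts into per-client per-day visits (order-stable)."""
    by_key: dict[tuple[str, int, str], list[ClientContact]] = {}
    for c in contacts:
        by_key.setdefault((c.facility_id, c.day, c.client_id), []).append(c)
    return [
        ClientVisit(facility_id=k[0], day=k[1], client_id=k[2], contacts=tuple(v))
        for k, v in by_key.items()
    ]


def compute_attribute_vector(
    visits: Sequence[ClientVisit],
    inv: FacilityInventory | None,
    facility_id: str,
    wave: str,
    n_days: int = 5,
    restrict_to_served: bool = False,
) -> AttributeVector:
    """All eight attributes for one facility-wave, with denominators."""
    n_clients = len(_eligible(visits, restrict_to_served)) if visits else 0
    values: dict[str, float] = {}
    denoms: dict[str, int] = {}

    if inv is not None:
        values["unit_availability"] = compute_unit_availability(inv)
        values["facility_availability"] = compute_facility_availability(inv)
        values["room_range"] = compute_room_range(inv)
        values["provider_range"] = compute_provider_range(inv)
        denoms["unit_availability"] = len(HIV_SERVICES)
        denoms["facility_availability"] = 8
        denoms["room_range"] = len(inv.room_logs)
        denoms["provider_range"] = len(inv.staff_logs)
    else:
        warnings.warn(f"facility {facility_id}: no inventory record", stacklevel=2)
        for name in STRUCTURAL_ATTRIBUTES:
            values[name] = MISSING
            denoms[name] = 0

    if visits:
        values["temporal_range"] = compute_temporal_range(visits, n_days=n_days)
        values["consult_integration"] = compute_consult_integration(visits, restrict_to_served)
        values["visit_integration"] = compute_visit_integration(visits, restrict_to_served)
        values["art_location_score"] = compute_art_score(visits, restrict_to_served)
        denoms["temporal_range"] = n_days
        for name in ("consult_integration", "visit_integration", "art_location_score"):
            denoms[name] = n_clients
    else:
        warnings.warn(f"facility {facility_id}: no client-flow records", stacklevel=2)
        for name in FUNCTIONAL_ATTRIBUTES:
            values[name] = MISSING
            denoms[name] = 0

    return AttributeVector(facility_id=facility_id, wave=wave, values=values, denominators=denoms)


def build_attribute_table(
    visits: Sequence[ClientVisit],
    inventories: Mapping[str, FacilityInventory],
    wave: str,
    n_days: int = 5,
    restrict_to_served: bool = False,
) -> pd.DataFrame:
    """Facility × attribute table for one wave.

    One row per facility seen in either source; attributes whose source is
    absent for a facility come out missing (NaN) with a warning, never 0.
    Denominators are carried in companion ``n_<attribute>`` columns.
    """
    by_fac: dict[str, list[ClientVisit]] = {}
    for v in visits:
        by_fac.setdefault(v.facility_id, []).append(v)
    facilities = sorted(set(by_fac) | set(inventories))
    rows = []
    for fac in facilities:
        vec = compute_attribute_vector(
            by_fac.get(fac, []),
            inventories.get(fac),
            facility_id=fac,
            wave=wave,
            n_days=n_days,
            restrict_to_served=restrict_to_served,
        )
        row: dict[str, object] = {"facility_id": fac, "wave": wave}
        row.update({name: vec.values[name] for name in ATTRIBUTE_NAMES})
        row.update({f"n_{name}": vec.denominators[name] for name in ATTRIBUTE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
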