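"""Fixed service-code vocabulary.

Two disjoint service classes are tracked at every facility: reproductive
health (RH: family planning, antenatal and postnatal care) and HIV-related
care (ART, cervical cancer screening, CD4 count, HIV testing, STI
treatment).  All attribute definitions are phrased in terms of these eight
codes; anything else in an input file is a hard error.
"""

from __future__ import annotations

import enum


class ServiceClass(enum.Enum):
    RH = "RH"
    HIV = "HIV"


RH_SERVICES: frozenset[str] = frozenset({"FP", "ANC", "PNC"})
HIV_SERVICES: frozenset[str] = frozenset(
    {"ART", "CACX_SCREEN", "CD4", "HIV_TEST", "STI_TREAT"}
)
ALL_SERVICES: frozenset[str] = RH_SERVICES | HIV_SERVICES

#: Services counted as "SRH" for the ART co-delivery score: an ART client
#: also receiving any of these from the same provider scores 3.
SRH_FOR_ART_SCORE: frozenset[str] = frozenset({"FP", "ANC", "PNC", "STI_TREAT"})


def service_class(code: str) -> ServiceClass:
    """Classify a service code as RH or HIV; raise on unknown codes."""
    if code in RH_SERVICES:
        return ServiceClass.RH
    if code in HIV_SERVICES:
        return ServiceClass.HIV
    raise ValueError(f"unknown service code {code!r}; known codes: {sorted(ALL_SERVICES)}")


def validate_codes(codes) -> frozenset[str]:
    """Validate an iterable of codes, returning them as a frozenset."""
    out = frozenset(codes)
    unknown = out - ALL_SERVICES
    if unknown:
        raise ValueError(
            f"unknown service code(s) {sorted(unknown)}; known codes: {sorted(ALL_SERVICES)}"
        )
    return out
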