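import numpy as np
import pandas as pd
import pytest

from integra_index.attributes import ClientContact, ClientVisit, FacilityInventory


def contact(fac="F1", day=1, client="c1", provider="p1", services=(), referrals=()):
    return ClientContact(
        facility_id=fac,
        day=day,
        client_id=client,
        provider_id=provider,
        services_received=frozenset(services),
        referrals=frozenset(referrals),
    )


def visit(contacts):
    c0 = contacts[0]
    return ClientVisit(
        facility_id=c0.facility_id, day=c0.day, client_id=c0.client_id, contacts=tuple(contacts)
    )


@pytest.fixture
def full_inventory():
    return FacilityInventory(
        facility_id="F1",
        unit_services=frozenset({"ART", "CACX_SCREEN", "CD4", "HIV_TEST", "STI_TREAT"}),
        facility_services=frozenset(
            {"ART", "CACX_SCREEN", "CD4", "HIV_TEST", "STI_TREAT", "FP", "ANC", "PNC"}
        ),
        room_logs={"r1": frozenset({"ART", "CD4", "HIV_TEST", "STI_TREAT", "CACX_SCREEN"})},
        staff_logs={"s1": frozenset({"ART", "CD4", "HIV_TEST", "STI_TREAT", "CACX_SCREEN"})},
    )


@pytest.fixture(scope="session")
def small_binary_matrix():
    """12 facilities x 2 binary indicators generated from a 1-factor probit
    model; shared fixture for sampler-vs-oracle comparisons."""
    from integra_index.ordinalize import IndicatorMatrix

    rng = np.random.default_rng(42)
    n = 12
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
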