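"""Attribute definitions: hand-computable cases and structural invariants."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from integra_index.attributes import (
    FacilityInventory,
    build_attribute_table,
    client_art_score,
    compute_art_score,
    compute_consult_integration,
    compute_facility_availability,
    compute_provider_range,
    compute_room_range,
    compute_temporal_range,
    compute_unit_availability,
    compute_visit_integration,
)
from integra_index.services import ALL_SERVICES, HIV_SERVICES, RH_SERVICES

from .conftest import contact, visit

HIV = sorted(HIV_SERVICES)
RH = sorted(RH_SERVICES)


class TestAvailability:
    @pytest.mark.parametrize(
        "unit, expected",
        [(HIV, 1.0), (["HIV_TEST", "STI_TREAT"], 0.4), ([], 0.0)],
    )
    def test_unit_availability(self, unit, expected):
        inv = FacilityInventory("F1", unit_services=frozenset(unit), facility_services=frozenset(ALL_SERVICES))
        assert compute_unit_availability(inv) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "services, expected",
        [(sorted(ALL_SERVICES), 1.0), (["FP", "ANC", "PNC", "HIV_TEST"], 0.5), ([], 0.0)],
    )
    def test_facility_availability(self, services, expected):
        inv = FacilityInventory("F1", facility_services=frozenset(services))
        assert compute_facility_availability(inv) == pytest.approx(expected)

    def test_missing_unit_record_is_missing_not_zero(self):
        inv = FacilityInventory("F1", facility_services=frozenset(ALL_SERVICES))
        with pytest.warns(UserWarning, match="unit"):
            assert math.isnan(compute_unit_availability(inv))

    def test_unit_exceeding_facility_register_warns_not_raises(self):
        with pytest.warns(UserWarning, match="register"):
            FacilityInventory(
                "F1", unit_services=frozenset({"ART"}), facility_services=frozenset({"FP"})
            )


class TestRoomAndProviderRange:
    @pytest.mark.parametrize(
        "rooms, expected",
        [
            ({"r1": HIV}, 1.0),
            ({"r1": ["ART", "CD4"], "r2": []}, 0.2),
            ({"r1": ["ART"], "r2": ["CD4"], "r3": ["HIV_TEST"]}, 0.2),
        ],
    )
    def test_room_range(self, rooms, expected):
        inv = FacilityInventory("F1", room_logs={k: frozenset(v) for k, v in rooms.items()})
        assert compute_room_range(inv) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "staff, expected",
        [
            ({"s1": HIV}, 1.0),
            ({"s1": ["HIV_TEST"], "s2": ["HIV_TEST", "STI_TREAT"]}, 0.3),
            ({"s1": [], "s2": []}, 0.0),
        ],
    )
    def test_provider_range(self, staff, expected):
        inv = FacilityInventory("F1", staff_logs={k: frozenset(v) for k, v in staff.items()})
        assert compute_provider_range(inv) == pytest.approx(expected)

    def test_no_logs_is_missing(self):
        inv = FacilityInventory("F1")
        assert math.isnan(compute_room_range(inv))
        assert math.isnan(compute_provider_range(inv))

    def test_rh_codes_in_logs_are_ignored(self):
        inv = FacilityInventory("F1", room_logs={"r1": frozenset({"FP", "ART"})})
        assert compute_room_range(inv) == pytest.approx(0.2)


class TestTemporalRange:
    def test_both_classes_every_day(self):
        visits = [visit([contact(day=d, client=f"c{d}", services={"FP", "HIV_TEST"})]) for d in range(1, 6)]
        assert compute_temporal_range(visits, 5) == 1.0

    def test_hiv_on_two_of_five_days(self):
        visits = []
        for d in range(1, 6):
            services = {"FP", "HIV_TEST"} if d in (1, 3) else {"FP"}
            visits.append(visit([contact(day=d, client=f"c{d}", services=services)]))
        assert compute_temporal_range(visits, 5) == pytest.approx(0.4)

    def test_no_hiv_at_all(self):
        visits = [visit([contact(day=d, client=f"c{d}", services={"ANC"})]) for d in range(1, 6)]
        assert compute_temporal_range(visits, 5) == 0.0

    def test_window_shorter_than_observed_days_rejected(self):
        visits = [visit([contact(day=d, client=f"c{d}", services={"FP"})]) for d in range(1, 7)]
        with pytest.raises(ValueError, match="window"):
            compute_temporal_range(visits, 5)


class TestClientIntegration:
    def test_half_of_clients_integrated_in_one_contact(self):
        visits = [
            visit([contact(client="c1", services={"FP", "HIV_TEST"})]),
            visit([contact(client="c2", services={"ANC", "CD4"})]),
            visit([contact(client="c3", services={"FP"})]),
            visit([contact(client="c4", services={"HIV_TEST"})]),
        ]
        assert compute_consult_integration(visits) == pytest.approx(0.5)

    def test_split_providers_count_for_visit_not_consult(self):
        v = visit(
            [
                contact(client="c1", provider="p1", services={"FP"}),
                contact(client="c1", provider="p2", services={"HIV_TEST"}),
            ]
        )
        assert compute_consult_integration([v]) == 0.0
        assert compute_visit_integration([v]) == 1.0

    def test_consult_numerator_is_subset_of_visit_numerator(self):
        rng = random.Random(0)
        visits = []
        for i in range(200):
            contacts = [
                contact(
                    client=f"c{i}",
                    provider=f"p{j}",
                    services=set(rng.sample(sorted(ALL_SERVICES), rng.randint(0, 4))),
                )
                for j in range(rng.randint(1, 3))
            ]
            visits.append(visit(contacts))
        assert compute_consult_integration(visits) <= compute_visit_integration(visits)

    def test_client_with_no_services_dilutes_denominator_only(self):
        visits = [visit([contact(client="c1", services={"FP", "HIV_TEST"})])]
        assert compute_visit_integration(visits) == 1.0
        visits.append(visit([contact(client="c2", services=set())]))
        assert compute_visit_integration(visits) == pytest.approx(0.5)
        assert compute_visit_integration(visits, restrict_to_served=True) == 1.0


class TestArtScore:
    @pytest.mark.parametrize(
        "contacts, expected",
        [
            ([contact(services={"ART", "FP"})], 3),
            ([contact(services={"ART", "STI_TREAT"})], 3),
            ([contact(services={"ART"})], 2),
            ([contact(services={"ANC"}, provider="p1"), contact(services={"ART"}, provider="p2")], 2),
            ([contact(services={"FP"}, referrals={"ART"})], 1),
            ([contact(services={"FP"})], 0),
            ([contact(services=set())], 0),
        ],
    )
    def test_client_level_scale(self, contacts, expected):
        assert client_art_score(visit(contacts)) == expected

    def test_facility_mean_aggregation(self):
        visits = [
            visit([contact(client="c1", services={"ART", "FP"})]),
            visit([contact(client="c2", services={"FP"}, referrals={"ART"})]),
        ]
        assert compute_art_score(visits) == pytest.approx(2.0)


class TestBuildTable:
    def _mini_study(self):
        visits = [
            visit([contact(fac="A", client="c1", services={"FP", "HIV_TEST"})]),
            visit([contact(fac="B", client="c2", services={"ANC"})]),
        ]
        inventories = {
            "A": FacilityInventory(
                "A",
                unit_services=frozenset({"ART"}),
                facility_services=frozenset(ALL_SERVICES),
                room_logs={"r": frozenset({"ART"})},
                staff_logs={"s": frozenset({"ART", "CD4"})},
            )
        }
        return visits, inventories

    def test_shape_and_missing_propagation(self):
        visits, inventories = self._mini_study()
        with pytest.warns(UserWarning, match="inventory"):
            table = build_attribute_table(visits, inventories, wave="baseline")
        assert len(table) == 2
        row_b = table.set_index("facility_id").loc["B"]
        assert math.isnan(row_b["unit_availability"])
        assert row_b["consult_integration"] == 0.0
        row_a = table.set_index("facility_id").loc["A"]
        assert row_a["provider_range"] == pytest.approx(0.4)
        assert row_a["n_consult_integration"] == 1

    def test_order_and_relabel_invariance(self):
        visits, inventories = self._mini_study()
        with pytest.warns(UserWarning):
            t1 = build_attribute_table(visits, inventories, wave="baseline")
        relabeled = [
            visit(
                [
                    contact(
                        fac=c.facility_id,
                        day=c.day,
                        client="x" + c.client_id,
                        provider="y" + c.provider_id,
                        services=c.services_received,
                        referrals=c.referrals,
                    )
                    for c in v.contacts
                ]
            )
            for v in reversed(visits)
        ]
        with pytest.warns(UserWarning):
            t2 = build_attribute_table(relabeled, inventories, wave="baseline")
        assert t1.equals(t2)


@settings(max_examples=25, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(1, 5),  # day
            st.integers(0, 30),  # client number
            st.sets(st.sampled_from(sorted(ALL_SERVICES)), max_size=4),
        ),
        min_size=1,
        max_size=60,
    )
)
def test_fractional_attributes_always_in_unit_interval(rows):
    """Whatever the flow records, every proportion attribute is in [0,1],
    the ART mean is in [0,3], and consult <= visit."""
    by_client = {}
    for day, cnum, services in rows:
        by_client.setdefault((day, cnum), []).append(
            contact(day=day, client=f"c{cnum}", services=services)
        )
    visits = [visit(cs) for cs in by_client.values()]
    ci = compute_consult_integration(visits)
    vi = compute_visit_integration(visits)
    tr = compute_temporal_range(visits, 5)
    art = compute_art_score(visits)
    assert 0.0 <= ci <= vi <= 1.0
    assert 0.0 <= tr <= 1.0
    assert 0.0 <= art <= 3.0
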