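"""Referral-list generation and delivery semantics."""

import numpy as np
import pytest

import crxsim as cx
from crxsim.intervention import (
    DELIVERY_SOURCES,
    DeliveryConfig,
    default_condition_catalog,
    indicated_services,
)


@pytest.fixture(scope="module")
def catalog():
    return default_condition_catalog()


def test_condition_assignment_prevalence(catalog, rng):
    w = cx.generate_world(cx.DemographicConfig(n_agents=10_000), seed=2)
    agents = cx.assign_conditions(w.agents, catalog, rng)
    # binomial 3-sigma band on an age-graded condition within one stratum
    band_mask = (agents["age"] >= 46) & (agents["age"] <= 65)
    sub = agents[band_mask]
    p = catalog.table.set_index(["condition_code", "age_band", "sex"]).loc[
        ("hypertension", "46-65", "female"), "prevalence"]
    fem = sub[sub["sex"] == "female"]
    hits = fem["conditions"].str.contains("hypertension").sum()
    n = len(fem)
    assert abs(hits - n * p) <= 3 * np.sqrt(n * p * (1 - p))
    # pregnancy never assigned to males
    males = agents[agents["sex"] == "male"]
    assert not males["conditions"].str.contains("pregnancy").any()
    assert set(agents["preferred_language"]) <= set(catalog.language_weights)


def test_zero_and_one_prevalence(catalog, rng):
    w = cx.generate_world(cx.DemographicConfig(n_agents=500), seed=3)
    t = catalog.table.copy()
    t["prevalence"] = 0.0
    zero = cx.ConditionCatalog(table=t, services=catalog.services)
    agents = cx.assign_conditions(w.agents, zero, rng)
    assert (agents["conditions"] == "").all()
    t2 = catalog.table.copy()
    t2.loc[t2["condition_code"] == "obesity", "prevalence"] = 1.0
    one = cx.ConditionCatalog(table=t2, services=catalog.services)
    agents = cx.assign_conditions(w.agents, one, rng)
    assert agents["conditions"].str.contains("obesity").all()


def test_indicated_services_union(catalog):
    agent = {"agent_id": 0, "age": 70, "sex": "female",
             "conditions": "diabetes;smoking", "household_id": 0}
    got = indicated_services(agent, catalog)
    base = set(catalog.base_services["66-94"])
    expect = base | set(catalog.services["diabetes"]) | set(catalog.services["smoking"])
    assert got == sorted(expect)


@pytest.fixture(scope="module")
def dense_world():
    """Enough resource sites that any indication set matches >= 40 resources."""
    cfg = cx.DemographicConfig(
        n_agents=50, n_households=20, n_workplaces=5, n_schools=1, n_clinics=2,
        n_resource_sites=400, services_per_site=(2, 4),
    )
    return cx.generate_world(cfg, seed=9)


def test_healtherx_caps_at_40_and_deterministic(dense_world, catalog):
    w = dense_world
    clinic = w.places[w.places["kind"] == "clinic"].iloc[0]
    agent = w.agents.iloc[0].copy()
    agent["conditions"] = "hypertension;diabetes;obesity;depression"
    rx1 = cx.generate_healtherx(agent, clinic, w, catalog)
    rx2 = cx.generate_healtherx(agent, clinic, w, catalog)
    assert len(rx1.items) == 40
    assert len(set(rx1.items)) == 40
    assert rx1.items == rx2.items


def test_healtherx_truncation_floor(catalog):
    cfg = cx.DemographicConfig(
        n_agents=5, n_households=2, n_workplaces=1, n_schools=1, n_clinics=1,
        n_resource_sites=4, services_per_site=(1, 2),
    )
    w = cx.generate_world(cfg, seed=1)
    clinic = w.places[w.places["kind"] == "clinic"].iloc[0]
    agent = w.agents.iloc[0].copy()
    agent["conditions"] = ";".join(catalog.services)  # indicate everything
    rx = cx.generate_healtherx(agent, clinic, w, catalog)
    # fewer than 40 eligible resources -> all of them, no padding
    eligible = set()
    for s in indicated_services(agent, catalog):
        eligible |= set(w.resources.loc[w.resources["service_type"] == s, "resource_id"])
    assert len(rx.items) == len(eligible) <= 40
    assert set(rx.items) == eligible


def test_healtherx_requires_clinic(dense_world, catalog):
    home = dense_world.places[dense_world.places["kind"] == "household"].iloc[0]
    with pytest.raises(ValueError):
        cx.generate_healtherx(dense_world.agents.iloc[0], home, dense_world, catalog)


def test_round_robin_covers_services(dense_world, catalog):
    """Each indicated service contributes its nearest resource before any
    service contributes its second."""
    w = dense_world
    clinic = w.places[w.places["kind"] == "clinic"].iloc[0]
    agent = w.agents.iloc[0].copy()
    agent["conditions"] = "hypertension;depression"
    rx = cx.generate_healtherx(agent, clinic, w, catalog)
    services = indicated_services(agent, catalog)
    home = w.places.set_index("place_id").loc[int(agent["household_id"])]
    firsts = {
        s: cx.nearest_resources(w, home, s, 1)["resource_id"].iloc[0]
        for s in services
        if len(cx.nearest_resources(w, home, s, 1))
    }
    head = set(rx.items[: len(firsts)])
    assert set(firsts.values()) <= head


def test_deliver_doses_every_item(dense_world, catalog):
    w = dense_world
    clinic = w.places[w.places["kind"] == "clinic"].iloc[0]
    agent = w.agents.iloc[0].copy()
    agent["conditions"] = "hypertension;diabetes;obesity"
    params = cx.KnowledgeParams()
    for mode, source in DELIVERY_SOURCES.items():
        rx = cx.generate_healtherx(agent, clinic, w, catalog, delivery_mode=mode)
        store = cx.KnowledgeStore(int(agent["agent_id"]), params)
        events = cx.deliver(rx, store, DeliveryConfig(delivery_mode=mode), params)
        assert len(events) == len(rx.items) == 40
        assert all(e[3] == source for e in events)
        for rid in rx.items:
            assert store.entries[rid].rx_derived
            assert store.entries[rid].beta > 0


def test_delivery_mode_strength_ordering(dense_world, catalog):
    """Mean post-delivery beta: physician >= nurse >= clerk on matched stores."""
    w = dense_world
    clinic = w.places[w.places["kind"] == "clinic"].iloc[0]
    agent = w.agents.iloc[0].copy()
    agent["conditions"] = "hypertension;diabetes"
    params = cx.KnowledgeParams()
    means = {}
    for mode in ("physician", "nurse", "clerk"):
        rx = cx.generate_healtherx(agent, clinic, w, catalog, delivery_mode=mode)
        store = cx.KnowledgeStore(int(agent["agent_id"]), params)
        for rid in rx.items:
            store.upsert(rid, 0.3, 0)
        cx.deliver(rx, store, DeliveryConfig(delivery_mode=mode), params)
        means[mode] = np.mean([store.current_beta(r, 0) for r in store.entries])
    assert means["physician"] > means["nurse"] > means["clerk"]


def test_empty_rx_is_noop(dense_world):
    params = cx.KnowledgeParams()
    store = cx.KnowledgeStore(0, params)
    rx = cx.HealtheRx(0, 0, 1, 0, "physician", ())
    events = cx.deliver(rx, store, DeliveryConfig(), params)
    assert events == [] and len(store) == 0


def test_item_at_beta_one_stays_there(dense_world, catalog):
    w = dense_world
    clinic = w.places[w.places["kind"] == "clinic"].iloc[0]
    agent = w.agents.iloc[0]
    params = cx.KnowledgeParams()
    rx = cx.generate_healtherx(agent, clinic, w, catalog)
    store = cx.KnowledgeStore(int(agent["agent_id"]), params)
    store.upsert(rx.items[0], 1.0, 0)
    events = cx.deliver(rx, store, DeliveryConfig(), params)
    assert len(events) == len(rx.items)
    assert store.current_beta(rx.items[0], 0) == 1.0
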