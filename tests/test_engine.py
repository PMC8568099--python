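"""Engine semantics: movement, event causality, determinism, and exact
equivalence with a straight-line reference implementation."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

import crxsim as cx
from crxsim.engine import DecisionParams
from crxsim.intervention import default_condition_catalog

from reference_engine import reference_run


def _tiny_config(seed=21, n_days=2):
    return cx.SimulationConfig(
        n_days=n_days, burn_in_days=1, seed=seed,
        snapshot_hours=(n_days * 24,),
        condition_catalog=default_condition_catalog(),
    )


@pytest.mark.parametrize("seed", [21, 99])
def test_engine_matches_straightline_reference(tiny_world, busy_pool, seed):
    """The optimized engine's full event log must be identical to a naive
    loop-everything implementation consuming the same random stream."""
    world = tiny_world
    cond_rng = np.random.default_rng(555)
    world = cx.World(
        agents=cx.assign_conditions(world.agents, default_condition_catalog(), cond_rng),
        places=world.places, resources=world.resources, frame=world.frame,
    )
    cfg = _tiny_config(seed=seed)
    res = cx.run(world, busy_pool, cfg)
    ref = reference_run(world, busy_pool, cfg)

    pdt.assert_frame_equal(
        res.events_exchange.astype({"giver": int}), ref["exchange"].astype({"giver": int}),
        check_dtype=False,
    )
    pdt.assert_frame_equal(res.events_dosing, ref["dosing"], check_dtype=False)
    pdt.assert_frame_equal(res.events_use, ref["use"], check_dtype=False)
    pdt.assert_frame_equal(res.events_visit, ref["visit"], check_dtype=False)
    pdt.assert_frame_equal(res.healtherx_log, ref["healtherx"], check_dtype=False)
    pdt.assert_frame_equal(res.healtherx_items, ref["healtherx_items"], check_dtype=False)
    for h in res.snapshots:
        pdt.assert_frame_equal(res.snapshots[h], ref["snapshots"][h],
                               check_dtype=False, rtol=1e-12, atol=1e-15)


def test_single_agent_has_no_exchanges(busy_pool):
    cfg = cx.DemographicConfig(n_agents=1, n_households=1, n_workplaces=1,
                               n_schools=1, n_clinics=1, n_resource_sites=3)
    world = cx.generate_world(cfg, seed=1)
    res = cx.run(world, busy_pool, _tiny_config(seed=4, n_days=2))
    assert len(res.events_exchange) == 0


def test_run_is_deterministic(tiny_world, busy_pool):
    r1 = cx.run(tiny_world, busy_pool, _tiny_config(seed=5))
    r2 = cx.run(tiny_world, busy_pool, _tiny_config(seed=5))
    pdt.assert_frame_equal(r1.events_exchange, r2.events_exchange)
    pdt.assert_frame_equal(r1.events_dosing, r2.events_dosing)
    pdt.assert_frame_equal(r1.snapshots[48], r2.snapshots[48])
    r3 = cx.run(tiny_world, busy_pool, _tiny_config(seed=6))
    assert len(r3.events_exchange) != len(r1.events_exchange) or not r3.events_exchange.equals(r1.events_exchange)


def test_exchange_causality_and_dose_matching(small_world, small_pool):
    """Givers and receivers of every exchange are co-located; every Peer
    dose has a matching exchange; clinical doses match visits."""
    cfg = cx.SimulationConfig(n_days=3, burn_in_days=1, seed=8,
                              snapshot_hours=(72,))
    res = cx.run(small_world, small_pool, cfg)
    ex = res.events_exchange
    if len(ex):
        # receiver is at the logged place; matching giver presence is implied
        # by the same-group construction, spot-check via dosing join
        peer = res.events_dosing[res.events_dosing["source"] == "Peer"]
        transmitted = ex[ex["resource_id"] >= 0]
        assert len(peer) == len(transmitted)
        merged = peer.merge(
            transmitted, left_on=["hour", "agent_id", "resource_id"],
            right_on=["hour", "receiver", "resource_id"], how="left")
        assert merged["giver"].notna().all()
    clinical = res.events_dosing[res.events_dosing["source"].isin(
        ["Doctor", "Nurse", "ClinicalStaff"])]
    visits = res.events_visit
    if len(clinical):
        hours_with_rx = set(zip(res.healtherx_log["hour"], res.healtherx_log["agent_id"]))
        assert set(zip(clinical["hour"], clinical["agent_id"])) <= hours_with_rx
        assert set(zip(res.healtherx_log["hour"], res.healtherx_log["agent_id"])) <= set(
            zip(visits["hour"], visits["agent_id"]))


def test_run_spans_expected_hours(small_world, small_pool):
    cfg = cx.SimulationConfig(n_days=3, burn_in_days=1, seed=9, snapshot_hours=(72,))
    res = cx.run(small_world, small_pool, cfg)
    for df in (res.events_exchange, res.events_dosing, res.events_visit):
        if len(df):
            assert df["hour"].between(0, 71).all()
    assert res.events_dosing.loc[res.events_dosing["hour"] < 24, "burn_in"].all()


def test_decide_ab_arithmetic_and_bruteforce(small_world, rng):
    """A/B: score beta*exp(-d/d0)*gamma against threshold; argmax equals
    exhaustive enumeration."""
    dp = DecisionParams(distance_scale_km=2.0)
    # forced arithmetic example: beta=.8, delta=.8, gamma=.9 -> 0.576
    d = -2.0 * np.log(0.8)
    assert 0.8 * dp.delta(d) * 0.9 == pytest.approx(0.576, abs=1e-12)
    assert 0.576 > 0.5 and not 0.576 > 0.6  # A at alpha=.5, B at alpha=.6

    params = cx.KnowledgeParams()
    store = cx.KnowledgeStore(0, params)
    world = small_world
    res = world.resources
    svc = res["service_type"].iloc[0]
    cands = res[res["service_type"] == svc]
    for rid in cands["resource_id"].head(10):
        store.upsert(int(rid), float(rng.uniform(0.2, 0.9)), 0)
    act = cx.ActivityDef("x", "x", "health_maintenance", "low", "AB",
                         frozenset([svc]), "service_site")
    agent = world.agents.iloc[0]
    out = cx.decide_AB(int(agent["agent_id"]), act, store, world, dp, t=0)
    # brute force over candidates
    places = world.places.set_index("place_id")
    home = places.loc[int(agent["household_id"])]
    best, best_s = None, -1.0
    for rid in store.entries:
        row = res.set_index("resource_id").loc[rid]
        p = places.loc[int(row["place_id"])]
        dd = float(np.hypot(p["x"] - home["x"], p["y"] - home["y"]))
        s = store.current_beta(rid, 0) * np.exp(-dd / 2.0) * float(row["inertia"])
        if s > best_s:
            best, best_s = rid, s
    expected = (best, best_s) if best_s > float(agent["activation"]) else None
    if expected is None:
        assert out is None
    else:
        assert out is not None and out[0] == expected[0]
        assert out[1] == pytest.approx(expected[1], rel=1e-12)


def test_empty_candidate_set_is_decision_B(small_world):
    params = cx.KnowledgeParams()
    store = cx.KnowledgeStore(0, params)  # empty store
    act = cx.ActivityDef("x", "x", "health_maintenance", "low", "AB",
                         frozenset(["fitness"]), "service_site")
    assert cx.decide_AB(0, act, store, small_world, DecisionParams()) is None
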