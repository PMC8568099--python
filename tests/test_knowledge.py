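"""Knowledge dynamics: dosing boosts, decay modes, seeding, capped memory."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crxsim as cx
from crxsim.knowledge import KnowledgeStore, snapshot_frame

PARAMS = cx.KnowledgeParams()

# Hand-evaluated: lambda*beta^eps*(1-beta)+beta at beta=0.5, lambda=0.991
HAND_ORACLE = {
    "Doctor": 0.978621450982261,
    "Nurse": 0.9465696042236664,
    "ClinicalStaff": 0.9166641737582155,
    "Use": 0.9313578041132295,
    "Peer": 0.7655318753433666,
    "None": 0.74775,
}


@pytest.mark.parametrize("source,expected", sorted(HAND_ORACLE.items()))
def test_boost_matches_hand_evaluation(source, expected):
    assert cx.boost(0.5, source, PARAMS) == pytest.approx(expected, abs=1e-12)


def test_boost_fixed_points():
    for source in ("Doctor", "Nurse", "ClinicalStaff", "Use", "Peer"):
        assert cx.boost(0.0, source, PARAMS) == 0.0
        assert cx.boost(1.0, source, PARAMS) == 1.0


@settings(max_examples=2000, deadline=None, derandomize=True)
@given(
    beta=st.floats(0.0, 1.0, allow_nan=False),
    source=st.sampled_from(["Doctor", "Nurse", "ClinicalStaff", "Use", "Peer", "None"]),
    lam=st.floats(0.991, 0.9994),
)
def test_boost_preserves_unit_interval_and_monotone(beta, source, lam):
    p = cx.KnowledgeParams(lambda_decay=lam)
    out = cx.boost(beta, source, p)
    assert 0.0 <= out <= 1.0
    assert out >= beta


def test_source_influence_ordering():
    """Doctor > Nurse > ClinicalStaff > Peer, and Use > ClinicalStaff, at
    every interior beta (stronger sources have smaller exponents)."""
    rng = np.random.default_rng(42)
    betas = rng.uniform(1e-6, 1 - 1e-6, 1000)
    for b in betas:
        d = cx.boost(b, "Doctor", PARAMS)
        nrs = cx.boost(b, "Nurse", PARAMS)
        cs = cx.boost(b, "ClinicalStaff", PARAMS)
        pr = cx.boost(b, "Peer", PARAMS)
        use = cx.boost(b, "Use", PARAMS)
        assert d > nrs > cs > pr
        assert use > cs


def test_unknown_source_rejected():
    with pytest.raises(KeyError):
        cx.boost(0.5, "Influencer", PARAMS)


def test_decay_modes():
    assert cx.decay(0.5, 0, PARAMS) == 0.5
    assert cx.decay(0.5, 1, PARAMS) == pytest.approx(0.4955, abs=1e-12)
    printed = cx.KnowledgeParams(decay_mode="as_printed")
    # the printed functional form with eps_None=1 *raises* beta
    assert cx.decay(0.5, 1, printed) == pytest.approx(0.74775, abs=1e-12)


def test_geometric_decay_composes():
    b = 0.7
    stepped = b
    for _ in range(30):
        stepped = cx.decay(stepped, 1, PARAMS)
    assert cx.decay(b, 30, PARAMS) == pytest.approx(stepped, abs=1e-12)


def test_lambda_outside_allowable_range_rejected():
    with pytest.raises(ValueError):
        cx.KnowledgeParams(lambda_decay=0.95)


def test_store_capacity_and_min_eviction(rng):
    """Dosing 500 distinct resources never exceeds capacity; every eviction
    removes the current minimum-beta entry."""
    params = cx.KnowledgeParams(capacity=200)
    store = KnowledgeStore(0, params)
    betas = rng.uniform(0, 1, 500)
    for rid, b in enumerate(betas):
        before = {r: store.current_beta(r, 0) for r in store.entries}
        evicted = store.upsert(rid, float(b), 0)
        assert len(store) <= 200
        if evicted is not None:
            assert before[evicted] == min(before.values())
            assert evicted not in store.entries
        elif len(before) == 200:
            # discarded: incoming beta did not beat the minimum
            assert b <= min(before.values())
            assert rid not in store.entries


def test_upsert_semantics():
    params = cx.KnowledgeParams(capacity=3)
    s = KnowledgeStore(0, params)
    assert s.upsert(7, 0.5, 0) is None and len(s) == 1
    s.upsert(8, 0.2, 0)
    s.upsert(9, 0.8, 0)
    # at capacity: losing insert is discarded
    assert s.upsert(10, 0.1, 0) is None
    assert 10 not in s.entries
    # winning insert evicts the minimum (rid 8)
    assert s.upsert(11, 0.9, 0) == 8
    assert len(s) == 3 and 8 not in s.entries
    # replacing an existing entry ORs the provenance flag
    s.upsert(7, 0.6, 0, rx_flag=True)
    s.upsert(7, 0.65, 0, rx_flag=False)
    assert s.entries[7].rx_derived


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 30), st.floats(0, 1),
                          st.sampled_from(["up", "dose", "decay"])), max_size=60))
def test_beta_stays_in_unit_interval_under_any_op_sequence(ops):
    params = cx.KnowledgeParams(capacity=10)
    s = KnowledgeStore(0, params)
    t = 0
    for rid, val, kind in ops:
        t += 1
        if kind == "up":
            s.upsert(rid, val, t)
        elif kind == "dose":
            s.dose(rid, "Peer", t)
        for r in s.entries:
            assert 0.0 <= s.current_beta(r, t) <= 1.0
        assert len(s) <= 10


def test_seeding_counts_and_strata(small_world, rng):
    sp = cx.SeedingParams()
    params = cx.KnowledgeParams()
    places = small_world.places.set_index("place_id")
    res_xy = places.loc[small_world.resources["place_id"], ["x", "y"]].to_numpy(float)
    rids = small_world.resources["resource_id"].to_numpy()
    for i in range(40):
        agent = small_world.agents.iloc[i]
        store = cx.seed_knowledge(agent, small_world, sp, params, rng)
        home = places.loc[int(agent["household_id"])]
        d = np.hypot(res_xy[:, 0] - home["x"], res_xy[:, 1] - home["y"])
        strata = {
            "low": set(rids[d < sp.low_radius_km]),
            "mid": set(rids[(d >= sp.low_radius_km) & (d < sp.mid_radius_km)]),
            "far": set(rids[d >= sp.mid_radius_km]),
        }
        seeded = set(store.entries)
        n_low = len(seeded & strata["low"])
        n_mid = len(seeded & strata["mid"])
        n_far = len(seeded & strata["far"])
        assert n_low <= min(100, len(strata["low"]))
        assert n_mid <= min(5, len(strata["mid"]))
        assert 1 <= n_far <= min(5, len(strata["far"])) or len(strata["far"]) == 0
        for r in seeded:
            e = store.entries[r]
            assert 0.1 <= e.beta <= 0.5
            assert not e.rx_derived


def test_seeding_empty_world(rng):
    cfg = cx.DemographicConfig(n_agents=1, n_households=1, n_workplaces=1,
                               n_schools=1, n_clinics=1, n_resource_sites=0)
    # resource_sites floor at 10 in resolved counts, so build explicit empty world
    w = cx.generate_world(cfg, seed=0)
    w.resources = w.resources.iloc[0:0]
    store = cx.seed_knowledge(w.agents.iloc[0], w, cx.SeedingParams(),
                              cx.KnowledgeParams(), rng)
    assert len(store) == 0


def test_snapshot_frame_applies_decay():
    params = cx.KnowledgeParams()
    s = KnowledgeStore(3, params)
    s.upsert(1, 0.8, 0)
    snap = snapshot_frame([s], t=10)
    assert snap.loc[0, "beta"] == pytest.approx(0.8 * 0.991**10, abs=1e-12)
    assert snap.loc[0, "agent_id"] == 3


def test_beta_trajectory_shape():
    """Jumps exactly at dose hours, monotone geometric decline between."""
    import pandas as pd

    params = cx.KnowledgeParams()
    doses = pd.DataFrame({"hour": [5, 20, 21], "source": ["Doctor", "Peer", "Use"]})
    traj = cx.beta_trajectory(doses, params, t_end=40)
    b = traj["beta"].to_numpy()
    assert (b[:5] == 0).all()
    jump_hours = {5, 20, 21}
    for t in range(1, 41):
        if t in jump_hours:
            assert b[t] > b[t - 1] * 0.991
        elif b[t - 1] > 0:
            assert b[t] == pytest.approx(b[t - 1] * 0.991, rel=1e-12)
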