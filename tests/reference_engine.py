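"""Straight-line reference simulation used as an oracle for the engine.

This is a deliberately naive, loop-everything implementation of the hourly
step semantics and the canonical randomness protocol documented in
``crxsim.engine``: scalar uniform draws, per-agent Python loops, pandas
lookups, no caching or vectorization. It shares only the low-level
primitives (knowledge store mechanics, schedule pools, referral-list
generation) with the engine; the simulation loop itself is written
independently so that a mismatch in movement, dosing, exchange, decision
or draw ordering shows up as a differing event log.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from crxsim import knowledge as kn
from crxsim import schedules as sch
from crxsim.intervention import generate_healtherx
from crxsim.world import World


def reference_run(world: World, pool: sch.SchedulePool, config):
    """Naive re-implementation of ``crxsim.engine.run`` for tiny worlds."""
    rng = np.random.default_rng(config.seed)
    agents = world.agents
    n = len(agents)
    n_hours = config.n_days * 24
    burn_hours = config.burn_in_days * 24
    kp = config.knowledge
    catalog = pool.catalog
    places = world.places.set_index("place_id")
    resources = world.resources.set_index("resource_id")

    # seeding, agents in id order (same primitive, fresh pandas path)
    stores = {}
    for i in range(n):
        stores[i] = kn.seed_knowledge(agents.iloc[i], world, config.seeding, kp, rng)

    cur_act = {i: "sleeping" for i in range(n)}
    cur_place = {i: int(agents.iloc[i]["household_id"]) for i in range(n)}
    today = {}
    dosed_today = set()

    ex_rows, do_rows, us_rows, vi_rows = [], [], [], []
    rx_rows, rx_item_rows = [], []
    snapshots = {}
    snap_hours = set(config.resolved_snapshot_hours())
    rx_seq = 0
    mode = config.delivery.delivery_mode
    source = config.delivery.mode_sources[mode]
    d0 = config.decision.distance_scale_km
    m_cap = config.contacts_per_agent_hour
    radius = config.out_of_home_radius_km

    nonhh = world.places[world.places["kind"] != "household"].sort_values("place_id")
    clinics = world.places[world.places["kind"] == "clinic"].sort_values("place_id")

    def home_xy(i):
        h = places.loc[int(agents.iloc[i]["household_id"])]
        return float(h["x"]), float(h["y"])

    for h in range(n_hours):
        hod = h % 24
        if hod == 0:
            day = h // 24
            day_type = "weekday" if day % 7 < 5 else "weekend"
            for i in range(n):
                today[i] = sch.draw_daily_schedule(agents.iloc[i], day_type, pool, rng)
            dosed_today = set()

        # step 1: movement
        pending = {}
        for i in range(n):
            code = today[i].hourly_activities[hod]
            act = catalog[code]
            if act.decision_type == "AB":
                pending[i] = act
                continue
            cur_act[i] = code
            pol = act.location_policy
            hid = int(agents.iloc[i]["household_id"])
            if pol == "home":
                cur_place[i] = hid
            elif pol == "work":
                w = int(agents.iloc[i]["workplace_id"])
                cur_place[i] = w if w >= 0 else hid
            elif pol == "school":
                s = int(agents.iloc[i]["school_id"])
                cur_place[i] = s if s >= 0 else hid
            elif pol == "clinic":
                if len(clinics):
                    hx, hy = home_xy(i)
                    d = np.hypot(clinics["x"].to_numpy() - hx, clinics["y"].to_numpy() - hy)
                    k = np.lexsort((clinics["place_id"].to_numpy(), d))[0]
                    cur_place[i] = int(clinics["place_id"].to_numpy()[k])
                else:
                    cur_place[i] = hid
            elif pol == "out_of_home":
                hx, hy = home_xy(i)
                d = np.hypot(nonhh["x"].to_numpy() - hx, nonhh["y"].to_numpy() - hy)
                cand = nonhh["place_id"].to_numpy()[d <= radius]
                if len(cand):
                    u = rng.random()
                    cur_place[i] = int(cand[int(u * len(cand))])
                else:
                    cur_place[i] = hid
            else:  # service_site without a decision: stay home
                cur_place[i] = hid

        # step 2: clinic dosing
        for i in range(n):
            code = cur_act[i]
            if code not in config.delivery.trigger_activity_codes:
                continue
            pid = cur_place[i]
            if places.loc[pid]["kind"] != "clinic":
                continue
            vi_rows.append((h, i, pid))
            if i in dosed_today:
                continue
            dosed_today.add(i)
            clinic_row = dict(places.loc[pid])
            clinic_row["place_id"] = pid
            rx = generate_healtherx(agents.iloc[i], clinic_row, world,
                                    config.condition_catalog, rx_id=rx_seq,
                                    hour=h, delivery_mode=mode)
            rx_rows.append((rx_seq, i, pid, h, mode, len(rx.items)))
            for rank, rid in enumerate(rx.items):
                rx_item_rows.append((rx_seq, rank, rid))
            rx_seq += 1
            for rid in rx.items:
                stores[i].dose(rid, source, h, rx_flag=True)
                do_rows.append((h, i, rid, source))

        # step 3: exchange — pass one: fire draws for all active groups
        occupied = sorted(set(cur_place.values()))
        group_fires = []  # (members, [(receiver, fires list)])
        for pid in occupied:
            members = sorted(i for i in range(n) if cur_place[i] == pid)
            if len(members) < 2:
                continue
            elig = [i for i in members
                    if sch.p_score(catalog[cur_act[i]], pool) > 0.0]
            if not elig:
                continue
            k = min(m_cap, len(members) - 1)
            recs = []
            for i in elig:
                p = sch.p_score(catalog[cur_act[i]], pool)
                fires = [rng.random() < p for _ in range(k)]
                recs.append((i, fires))
            group_fires.append((members, recs))
        # pass two: giver sampling and peer doses
        for members, recs in group_fires:
            size = len(members)
            for receiver, fires in recs:
                c = sum(fires)
                if c == 0:
                    continue
                pos = members.index(receiver)
                idx = list(range(size - 1))
                for j in range(c):
                    r = j + int(rng.random() * (size - 1 - j))
                    idx[j], idx[r] = idx[r], idx[j]
                    gsel = idx[j]
                    giver = members[gsel if gsel < pos else gsel + 1]
                    g = stores[giver]
                    if len(g) == 0:
                        ex_rows.append((h, giver, receiver, cur_place[receiver], -1))
                        continue
                    top = g.top_entry(h)
                    ex_rows.append((h, giver, receiver, cur_place[receiver], top[0]))
                    stores[receiver].dose(top[0], "Peer", h, rx_flag=top[2])
                    do_rows.append((h, receiver, top[0], "Peer"))

        # step 4: A/B decisions
        for i in sorted(pending):
            act = pending[i]
            store = stores[i]
            here = places.loc[cur_place[i]]
            ox, oy = float(here["x"]), float(here["y"])
            best, best_score = None, -1.0
            for rid in store.entries:
                row = resources.loc[rid]
                if row["service_type"] not in act.mapped_services:
                    continue
                p = places.loc[int(row["place_id"])]
                d = math.hypot(float(p["x"]) - ox, float(p["y"]) - oy)
                b = store.current_beta(rid, h)
                score = b * math.exp(-d / d0) * float(row["inertia"])
                if score > best_score or (score == best_score and (best is None or rid < best)):
                    best, best_score = rid, score
            if best is not None and best_score > float(agents.iloc[i]["activation"]):
                cur_act[i] = act.activity_code
                cur_place[i] = int(resources.loc[best]["place_id"])
                store.dose(best, "Use", h, rx_flag=False)
                us_rows.append((h, i, best, cur_place[i]))
                do_rows.append((h, i, best, "Use"))
            # else: keep previous activity/location

        if (h + 1) in snap_hours:
            snapshots[h + 1] = kn.snapshot_frame(stores, h + 1)

    def frame(rows, cols):
        df = pd.DataFrame(rows, columns=cols)
        df["burn_in"] = df["hour"] < burn_hours if len(df) else pd.Series(dtype=bool)
        return df

    return {
        "exchange": frame(ex_rows, ["hour", "giver", "receiver", "place_id", "resource_id"]),
        "dosing": frame(do_rows, ["hour", "agent_id", "resource_id", "source"]),
        "use": frame(us_rows, ["hour", "agent_id", "resource_id", "place_id"]),
        "visit": frame(vi_rows, ["hour", "agent_id", "clinic_id"]),
        "healtherx": pd.DataFrame(rx_rows, columns=["rx_id", "agent_id", "clinic_id",
                                                    "hour", "mode", "n_items"]),
        "healtherx_items": pd.DataFrame(rx_item_rows, columns=["rx_id", "rank", "resource_id"]),
        "snapshots": snapshots,
        "stores": stores,
    }
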