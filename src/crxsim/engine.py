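"""Hourly time-stepped simulation of movement, dosing, information exchange
and resource-use decisions.

Each simulated hour the engine (1) moves agents to their activity's
location, (2) issues and delivers a referral list to agents presenting at a
clinic, (3) lets co-located agents exchange resource information, (4)
resolves use/continue (A/B) decisions for health-maintenance activities and
(5) accounts for knowledge decay (lazily under geometric decay). Runs
default to 28 days with the first 14 flagged as burn-in.

Canonical randomness protocol
-----------------------------
All stochastic choices consume uniform doubles from a single seeded
``numpy.random.Generator`` in a fixed documented order, so that an
independently written straight-line implementation reproduces the event
log exactly:

1. initial seeding: agents in id order (see :func:`crxsim.knowledge.seed_knowledge`);
2. at each day boundary: one uniform per agent in id order (template index
   = floor(u * n_matched), templates sorted by id);
3. movement: one uniform per agent with an out-of-home activity, agents in
   id order (index into the household's candidate places, sorted by id;
   no uniform if the candidate list is empty);
4. exchange, two passes per hour over places in ascending id order
   (groups with >= 2 occupants and >= 1 eligible receiver only):
   pass one draws k = min(m, group_size - 1) fire-test uniforms per
   eligible receiver (receivers in id order, receiver-major); a slot fires
   iff u < p(receiver's current activity). Pass two, in the same order,
   draws c_i uniforms for a partial Fisher-Yates sample of the c_i distinct
   givers for each receiver with c_i > 0 fires (and, under the
   beta_weighted share policy, one extra uniform per transmitted resource).
5. A/B decisions and clinic dosing consume no randomness.

Discrete draws are floor(u * n); `Generator.random(n)` yields the same
stream as n scalar draws, which is what makes the vectorized engine and
the scalar reference comparable.
"""

from __future__ import annotations

from array import array
from dataclasses import dataclass, field
from math import exp, hypot

import numpy as np
import pandas as pd

from . import knowledge as kn
from . import schedules as sch
from .intervention import (
    ConditionCatalog,
    DeliveryConfig,
    HealtheRx,
    default_condition_catalog,
    indicated_services,
)
from .world import ConfigurationError, World

__all__ = [
    "DecisionParams",
    "SimulationConfig",
    "RunResult",
    "run",
    "decide_AB",
]


@dataclass
class DecisionParams:
    """Parameters of the binary use/continue decision.

    score(j) = beta_ij * delta_ij * gamma_j with delta = exp(-d / d0), a
    distance factor in (0, 1] that shrinks with travel effort; the agent
    uses the best-scoring known matching resource iff the score exceeds
    their activation threshold alpha_i.
    """

    distance_scale_km: float = 2.0

    def __post_init__(self):
        if self.distance_scale_km <= 0:
            raise ConfigurationError("distance scale d0 must be > 0")

    def delta(self, d_km: float) -> float:
        return exp(-d_km / self.distance_scale_km)


@dataclass
class SimulationConfig:
    n_days: int = 28
    burn_in_days: int = 14
    seed: int = 0
    knowledge: kn.KnowledgeParams = field(default_factory=kn.KnowledgeParams)
    seeding: kn.SeedingParams = field(default_factory=kn.SeedingParams)
    delivery: DeliveryConfig = field(default_factory=DeliveryConfig)
    decision: DecisionParams = field(default_factory=DecisionParams)
    contacts_per_agent_hour: int = 10  # m: max sampled givers per receiver-hour
    share_policy: str = "top_beta"  # top_beta | beta_weighted
    shares_per_exchange: int = 1  # k resources transmitted per fired exchange
    out_of_home_radius_km: float = 5.0
    snapshot_hours: tuple[int, ...] | None = None  # default: weekly boundaries
    condition_catalog: ConditionCatalog | None = None
    assign_conditions_seed_offset: int = 1_000_003

    def validate(self) -> None:
        if self.n_days <= self.burn_in_days:
            raise ConfigurationError("n_days must exceed burn_in_days")
        if self.contacts_per_agent_hour < 1:
            raise ConfigurationError("contact cap m must be >= 1")
        if self.shares_per_exchange < 1:
            raise ConfigurationError("shares per exchange must be >= 1")
        if self.share_policy not in ("top_beta", "beta_weighted"):
            raise ConfigurationError(f"unknown share_policy {self.share_policy!r}")

    def resolved_snapshot_hours(self) -> tuple[int, ...]:
        if self.snapshot_hours is not None:
            return tuple(sorted(self.snapshot_hours))
        n_hours = self.n_days * 24
        return tuple(h for h in range(168, n_hours + 1, 168))


@dataclass
class RunResult:
    """Event logs, weekly knowledge snapshots and run metadata."""

    events_exchange: pd.DataFrame  # hour, giver, receiver, place_id, resource_id, burn_in
    events_dosing: pd.DataFrame  # hour, agent_id, resource_id, source, burn_in
    events_use: pd.DataFrame  # hour, agent_id, resource_id, place_id, burn_in
    events_visit: pd.DataFrame  # hour, agent_id, clinic_id, burn_in
    healtherx_log: pd.DataFrame  # rx_id, agent_id, clinic_id, hour, mode, n_items
    healtherx_items: pd.DataFrame  # rx_id, rank, resource_id
    snapshots: dict[int, pd.DataFrame]  # hour -> knowledge snapshot frame
    seed: int = 0
    config: SimulationConfig | None = None
    n_agents: int = 0
    work_fallbacks: int = 0

    def write(self, out_dir) -> None:
        import os

        import yaml

        os.makedirs(out_dir, exist_ok=True)
        self.events_exchange.to_csv(os.path.join(out_dir, "events_exchange.csv"), index=False)
        self.events_dosing.to_csv(os.path.join(out_dir, "events_dosing.csv"), index=False)
        self.events_use.to_csv(os.path.join(out_dir, "events_use.csv"), index=False)
        self.events_visit.to_csv(os.path.join(out_dir, "events_visit.csv"), index=False)
        self.healtherx_log.to_csv(os.path.join(out_dir, "healtherx_log.csv"), index=False)
        self.healtherx_items.to_csv(os.path.join(out_dir, "healtherx_items.csv"), index=False)
        for hour, snap in self.snapshots.items():
            snap.to_csv(os.path.join(out_dir, f"knowledge_h{hour:04d}.csv"), index=False)
        with open(os.path.join(out_dir, "run_meta.yaml"), "w") as fh:
            yaml.safe_dump({"seed": self.seed, "n_agents": self.n_agents,
                            "work_fallbacks": self.work_fallbacks}, fh)


def decide_AB(agent_id: int, activity: sch.ActivityDef, store: kn.KnowledgeStore,
              world: World, dp: DecisionParams, t: int = 0,
              origin_xy: tuple[float, float] | None = None,
              activation: float | None = None):
    """Resolve one use/continue decision (standalone, table-backed variant).

    Returns (resource_id, score) on an A decision, None on B. The engine
    uses an equivalent array-backed fast path; both pick the argmax of
    beta * exp(-d/d0) * gamma over known resources matching the activity's
    services, ties toward the smaller resource_id.
    """
    if activity.decision_type != "AB":
        raise ValueError("activity does not require an A/B decision")
    res = world.resources.set_index("resource_id")
    places = world.places.set_index("place_id")
    if origin_xy is None:
        agent = world.agents.loc[world.agents["agent_id"] == agent_id].iloc[0]
        home = places.loc[int(agent["household_id"])]
        origin_xy = (float(home["x"]), float(home["y"]))
        activation = float(agent["activation"]) if activation is None else activation
    best, best_score = None, -1.0
    for rid in store.entries:
        if rid not in res.index:
            continue
        row = res.loc[rid]
        if row["service_type"] not in activity.mapped_services:
            continue
        p = places.loc[int(row["place_id"])]
        d = hypot(p["x"] - origin_xy[0], p["y"] - origin_xy[1])
        score = store.current_beta(rid, t) * dp.delta(d) * float(row["inertia"])
        if score > best_score or (score == best_score and (best is None or rid < best)):
            best, best_score = rid, score
    if best is not None and best_score > activation:
        return best, best_score
    return None


class _RaggedIndex:
    """Flat array + offsets per key, for vectorized ragged lookups."""

    __slots__ = ("flat", "offsets", "lengths")

    def __init__(self, lists):
        self.lengths = np.array([len(x) for x in lists], dtype=np.int64)
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)))
        self.flat = (
            np.concatenate([np.asarray(x, dtype=np.int64) for x in lists if len(x)])
            if self.lengths.sum()
            else np.empty(0, dtype=np.int64)
        )


def _rx_items_fast(agent, services, svc_arrays, home_xy) -> tuple[int, ...]:
    """Round-robin nearest-first 40-item fill (array fast path).

    Mirrors :func:`crxsim.intervention.generate_healtherx` exactly:
    per-service ranking ascending (distance, resource_id), then round-robin
    across the sorted service list with de-duplication, truncated at 40.
    """
    ranked = []
    for s in services:
        arr = svc_arrays.get(s)
        if arr is None:
            ranked.append([])
            continue
        rids, xs, ys = arr
        d = np.hypot(xs - home_xy[0], ys - home_xy[1])
        order = np.lexsort((rids, d))[:40]
        ranked.append(rids[order].tolist())
    items, seen = [], set()
    depth = 0
    while len(items) < 40 and any(depth < len(r) for r in ranked):
        for r in ranked:
            if depth < len(r) and r[depth] not in seen:
                items.append(r[depth])
                seen.add(r[depth])
                if len(items) == 40:
                    break
        depth += 1
    return tuple(items)


def run(world: World, pool: sch.SchedulePool, config: SimulationConfig,
        stores: dict[int, kn.KnowledgeStore] | None = None) -> RunResult:
    """Execute a full simulation; returns event logs and snapshots.

    If ``stores`` is given the initial-seeding draws are skipped (used by
    tests that pre-seed identical stores into two implementations).
    Agents' conditions/preferred language are filled from the condition
    catalog (with a seed derived from the run seed) unless already present.
    """
    config.validate()
    n = len(world.agents)
    if n == 0:
        raise ConfigurationError("cannot simulate an empty world")
    if not (world.agents["agent_id"].to_numpy() == np.arange(n)).all():
        raise ConfigurationError("agent_id must be contiguous 0..n-1 in row order")
    rng = np.random.default_rng(config.seed)
    n_hours = config.n_days * 24
    burn_hours = config.burn_in_days * 24
    kp = config.knowledge
    catalog = config.condition_catalog or default_condition_catalog()

    agents = world.agents
    if (agents["conditions"] == "").all() and (agents["preferred_language"] == "").all():
        from .intervention import assign_conditions

        cond_rng = np.random.default_rng(
            (config.seed + config.assign_conditions_seed_offset) % (2**31)
        )
        agents = assign_conditions(agents, catalog, cond_rng)

    # ---- static arrays ----
    places = world.places
    px = places["x"].to_numpy(float)
    py = places["y"].to_numpy(float)
    place_ids = places["place_id"].to_numpy()
    pid_pos = {int(p): i for i, p in enumerate(place_ids)}

    res = world.resources
    n_res = int(res["resource_id"].max()) + 1 if len(res) else 0
    res_place = np.full(n_res, -1, dtype=np.int64)
    res_gamma = np.zeros(n_res)
    res_x = np.zeros(n_res)
    res_y = np.zeros(n_res)
    res_service: dict[int, str] = {}
    for r in res.itertuples(index=False):
        rid = int(r.resource_id)
        res_place[rid] = int(r.place_id)
        res_gamma[rid] = float(r.inertia)
        res_x[rid] = px[pid_pos[int(r.place_id)]]
        res_y[rid] = py[pid_pos[int(r.place_id)]]
        res_service[rid] = r.service_type
    svc_arrays: dict[str, tuple] = {}
    for s, grp in res.groupby("service_type"):
        rids = grp["resource_id"].to_numpy(np.int64)
        pos = np.array([pid_pos[int(p)] for p in grp["place_id"]])
        svc_arrays[s] = (rids, px[pos], py[pos])

    household = agents["household_id"].to_numpy(np.int64)
    workplace = agents["workplace_id"].to_numpy(np.int64)
    school = agents["school_id"].to_numpy(np.int64)
    activation = agents["activation"].to_numpy(float)
    home_pos = np.array([pid_pos[int(h)] for h in household])
    home_x, home_y = px[home_pos], py[home_pos]

    # ---- activity catalog arrays ----
    codes = sorted(pool.catalog)
    code_idx = {c: i for i, c in enumerate(codes)}
    acts = [pool.catalog[c] for c in codes]
    p_of_act = np.array([sch.p_score(a, pool) for a in acts])
    is_ab = np.array([a.decision_type == "AB" for a in acts])
    policy = [a.location_policy for a in acts]
    trigger = np.array([a.activity_code in config.delivery.trigger_activity_codes for a in acts])
    mapped_sets = [frozenset(a.mapped_services) for a in acts]
    sleep_idx = code_idx.get("sleeping", 0)
    _POLICY_CODE = {"home": 0, "work": 1, "school": 2, "out_of_home": 3,
                    "service_site": 4, "clinic": 5}
    pol_arr = np.array([_POLICY_CODE[p] for p in policy], dtype=np.int64)
    kind_of_place = {int(p): k for p, k in zip(places["place_id"], places["kind"])}

    # ---- schedule templates ----
    tmpl_mat = np.array(
        [[code_idx[c] for c in t.hourly_activities] for t in pool.templates],
        dtype=np.int64,
    )
    tmpl_row = {t.template_id: i for i, t in enumerate(pool.templates)}
    key_cache: dict[tuple, tuple] = {}
    matched_wd, matched_we = [], []
    for a in agents.itertuples(index=False):
        key = (str(sch.age_band(int(a.age))), a.sex, a.race, a.ethnicity)
        if key not in key_cache:
            wd = np.array([tmpl_row[t.template_id] for t in pool.matched_templates(key, "weekday")])
            we = np.array([tmpl_row[t.template_id] for t in pool.matched_templates(key, "weekend")])
            key_cache[key] = (wd, we)
        wd, we = key_cache[key]
        matched_wd.append(wd)
        matched_we.append(we)
    ragged_wd = _RaggedIndex(matched_wd)
    ragged_we = _RaggedIndex(matched_we)

    # ---- out-of-home candidates and nearest clinic, per household ----
    nonhh_mask = (places["kind"] != "household").to_numpy()
    nonhh_ids = place_ids[nonhh_mask]
    nonhh_x, nonhh_y = px[nonhh_mask], py[nonhh_mask]
    clinic_mask = (places["kind"] == "clinic").to_numpy()
    clinic_ids = place_ids[clinic_mask]
    clinic_x, clinic_y = px[clinic_mask], py[clinic_mask]
    uniq_hh = np.unique(household)
    hh_cand: dict[int, np.ndarray] = {}
    hh_clinic: dict[int, int] = {}
    r2 = config.out_of_home_radius_km
    for hid in uniq_hh:
        hx, hy = px[pid_pos[int(hid)]], py[pid_pos[int(hid)]]
        d = np.hypot(nonhh_x - hx, nonhh_y - hy)
        hh_cand[int(hid)] = nonhh_ids[d <= r2]  # sorted: nonhh_ids ascending
        dc = np.hypot(clinic_x - hx, clinic_y - hy)
        # nearest clinic, ties toward the smaller place id (lexsort order)
        hh_clinic[int(hid)] = int(clinic_ids[np.lexsort((clinic_ids, dc))[0]]) if len(clinic_ids) else -1
    cand_ragged = _RaggedIndex([hh_cand[int(h)] for h in household])
    agent_clinic = np.array([hh_clinic[int(h)] for h in household], dtype=np.int64)

    # ---- initial state ----
    agent_rows = agents.to_dict("records")
    if stores is None:
        # prefill the household->distance-strata cache in one vectorized pass
        sp = config.seeding
        dist_cache = kn.household_distance_strata(world, sp)
        stores = {}
        for i, row in enumerate(agent_rows):
            stores[i] = kn.seed_knowledge(row, world, sp, kp, rng,
                                          _dist_cache=dist_cache)
    cur_act = np.full(n, sleep_idx, dtype=np.int64)
    cur_place = household.copy()
    today_tmpl = np.zeros(n, dtype=np.int64)
    dosed_today = np.zeros(n, dtype=bool)
    rx_items_cache: dict[int, tuple[int, ...]] = {}

    # ---- event logs (compact typed arrays) ----
    ex_h, ex_g, ex_r, ex_p, ex_res = (array("q") for _ in range(5))
    do_h, do_a, do_r = array("q"), array("q"), array("q")
    do_s: list[str] = []
    us_h, us_a, us_r, us_p = (array("q") for _ in range(4))
    vi_h, vi_a, vi_c = (array("q") for _ in range(3))
    rx_log: list[tuple] = []
    rx_items_rows: list[tuple] = []
    snapshots: dict[int, pd.DataFrame] = {}
    snap_hours = set(config.resolved_snapshot_hours())
    rx_seq = 0
    work_fallbacks = 0

    m_cap = config.contacts_per_agent_hour
    k_shares = config.shares_per_exchange
    beta_weighted = config.share_policy == "beta_weighted"
    mode = config.delivery.delivery_mode
    dose_source = config.delivery.mode_sources[mode]
    d0 = config.decision.distance_scale_km

    for h in range(n_hours):
        burn = h < burn_hours
        hod = h % 24
        if hod == 0:
            day = h // 24
            ragged = ragged_wd if day % 7 < 5 else ragged_we
            u = rng.random(n)
            today_tmpl = ragged.flat[
                ragged.offsets[:-1] + np.floor(u * ragged.lengths).astype(np.int64)
            ]
            dosed_today[:] = False

        # ---- step 1: movement ----
        act_now = tmpl_mat[today_tmpl, hod]
        pending = is_ab[act_now]
        moved = ~pending
        new_act = np.where(moved, act_now, cur_act)
        new_place = cur_place.copy()
        apol = np.where(moved, pol_arr[act_now], -1)
        new_place[apol == 0] = household[apol == 0]
        wmask = apol == 1
        if wmask.any():
            has_w = workplace[wmask] >= 0
            tgt = np.where(has_w, workplace[wmask], household[wmask])
            work_fallbacks += int((~has_w).sum())
            new_place[wmask] = tgt
        smask = apol == 2
        if smask.any():
            has_s = school[smask] >= 0
            new_place[smask] = np.where(has_s, school[smask], household[smask])
        cmask = apol == 5
        if cmask.any():
            new_place[cmask] = np.where(agent_clinic[cmask] >= 0,
                                        agent_clinic[cmask], household[cmask])
        omask = apol == 3
        if omask.any():
            oi = np.flatnonzero(omask)  # ascending agent id: canonical order
            lens = cand_ragged.lengths[oi]
            drawable = lens > 0
            uo = np.empty(len(oi))
            uo[drawable] = rng.random(int(drawable.sum()))
            tgt = household[oi].copy()
            di = np.flatnonzero(drawable)
            tgt[di] = cand_ragged.flat[
                cand_ragged.offsets[oi[di]]
                + np.floor(uo[di] * lens[di]).astype(np.int64)
            ]
            new_place[oi] = tgt
        # policy 4 (service_site) without an AB decision: stay home
        svc_mask = apol == 4
        if svc_mask.any():
            new_place[svc_mask] = household[svc_mask]
        cur_act, cur_place = new_act, new_place

        # ---- step 2: clinic dosing ----
        at_clinic = trigger[cur_act]
        if at_clinic.any():
            for i in np.flatnonzero(at_clinic):
                pid = int(cur_place[i])
                if kind_of_place.get(pid) != "clinic":
                    continue
                vi_h.append(h); vi_a.append(i); vi_c.append(pid)
                if dosed_today[i]:
                    continue
                dosed_today[i] = True
                items = rx_items_cache.get(i)
                if items is None:
                    services = indicated_services(agent_rows[i], catalog)
                    items = _rx_items_fast(agent_rows[i], services, svc_arrays,
                                           (home_x[i], home_y[i]))
                    rx_items_cache[i] = items
                rx = HealtheRx(rx_seq, i, pid, h, mode, items)
                rx_log.append((rx_seq, i, pid, h, mode, len(items)))
                rx_items_rows.extend((rx_seq, rank, rid) for rank, rid in enumerate(items))
                rx_seq += 1
                store = stores[i]
                for rid in items:
                    store.dose(rid, dose_source, h, rx_flag=True)
                    do_h.append(h); do_a.append(i); do_r.append(rid)
                    do_s.append(dose_source)

        # ---- step 3: co-located exchange (two passes, canonical order) ----
        order = np.lexsort((np.arange(n), cur_place))
        sorted_places = cur_place[order]
        bounds = np.flatnonzero(np.concatenate(([True], np.diff(sorted_places) != 0, [True])))
        p_agent = p_of_act[cur_act]
        sizes = np.diff(bounds)
        elig_sorted = (p_agent[order] > 0.0).astype(np.int64)
        n_elig = np.add.reduceat(elig_sorted, bounds[:-1])
        active = np.flatnonzero((sizes >= 2) & (n_elig > 0))
        groups = []  # (members ascending, eligible positions, k, p of eligible)
        total_draws = 0
        for gi in active:
            s, e = bounds[gi], bounds[gi + 1]
            members = order[s:e]
            pm = p_agent[members]
            elig = np.flatnonzero(pm > 0.0)
            k = min(m_cap, e - s - 1)
            groups.append((members, elig, k, pm[elig]))
            total_draws += len(elig) * k
        if total_draws:
            u_fire = rng.random(total_draws)
            off = 0
            fired = []  # (members, receiver_pos, fire_count rows)
            for members, elig, k, pe in groups:
                blk = u_fire[off: off + len(elig) * k].reshape(len(elig), k)
                off += len(elig) * k
                fires = blk < pe[:, None]
                cs = fires.sum(axis=1)
                if cs.any():
                    fired.append((members, elig[cs > 0], cs[cs > 0]))
            pid_of = cur_place
            for members, epos, cs in fired:
                mlist = members.tolist()
                size = len(mlist)
                for pos, c in zip(epos.tolist(), cs.tolist()):
                    receiver = mlist[pos]
                    # sample c distinct co-located others (partial Fisher-Yates)
                    idx = list(range(size - 1))
                    rstore = stores[receiver]
                    place = int(pid_of[receiver])
                    for j in range(int(c)):
                        r = j + int(rng.random() * (size - 1 - j))
                        idx[j], idx[r] = idx[r], idx[j]
                        gsel = idx[j]
                        giver = mlist[gsel if gsel < pos else gsel + 1]
                        gstore = stores[giver]
                        if len(gstore) == 0:
                            ex_h.append(h); ex_g.append(giver); ex_r.append(receiver)
                            ex_p.append(place); ex_res.append(-1)
                            continue
                        if beta_weighted:
                            shared = []
                            ents = sorted(gstore.entries)
                            betas = np.array([gstore.current_beta(rr, h) for rr in ents])
                            csum = np.cumsum(betas)
                            for _ in range(k_shares):
                                uu = rng.random() * csum[-1]
                                shared_rid = ents[int(np.searchsorted(csum, uu, side="right"))]
                                shared.append((shared_rid, gstore.entries[shared_rid].rx_derived))
                        else:
                            if k_shares == 1:
                                top = gstore.top_entry(h)
                                shared = [(top[0], top[2])]
                            else:
                                shared = [(rid, rx) for rid, _, rx in gstore.top_entries(h, k_shares)]
                        for rid, rx_flag in shared:
                            ex_h.append(h); ex_g.append(giver); ex_r.append(receiver)
                            ex_p.append(place); ex_res.append(rid)
                            rstore.dose(rid, "Peer", h, rx_flag=rx_flag)
                            do_h.append(h); do_a.append(receiver); do_r.append(rid)
                            do_s.append("Peer")

        # ---- step 4: A/B decisions ----
        if pending.any():
            for i in np.flatnonzero(pending):
                act = acts[act_now[i]]
                mapped = mapped_sets[act_now[i]]
                store = stores[i]
                ox, oy = px[pid_pos[int(cur_place[i])]], py[pid_pos[int(cur_place[i])]]
                best, best_score = -1, -1.0
                lam = kp.lambda_decay
                geom = kp.decay_mode == "geometric"
                for rid, e in store.entries.items():
                    if res_service.get(rid) not in mapped:
                        continue
                    if geom:
                        b = e.beta * lam ** (h - e.last_update)
                    else:
                        b = store.current_beta(rid, h)
                    d = hypot(res_x[rid] - ox, res_y[rid] - oy)
                    score = b * exp(-d / d0) * res_gamma[rid]
                    if score > best_score or (score == best_score and rid < best):
                        best, best_score = rid, score
                if best >= 0 and best_score > activation[i]:
                    cur_act[i] = act_now[i]
                    cur_place[i] = res_place[best]
                    store.dose(best, "Use", h, rx_flag=False)
                    us_h.append(h); us_a.append(i); us_r.append(best)
                    us_p.append(int(res_place[best]))
                    do_h.append(h); do_a.append(i); do_r.append(best)
                    do_s.append("Use")
                # B: previous activity/location already in cur_act/cur_place

        # ---- step 5: decay bookkeeping (lazy) + snapshots ----
        if (h + 1) in snap_hours:
            snapshots[h + 1] = kn.snapshot_frame(stores, h + 1)

    def _ev(cols: dict) -> pd.DataFrame:
        df = pd.DataFrame({k: np.asarray(v) for k, v in cols.items()})
        if len(df):
            df["burn_in"] = df["hour"] < burn_hours
        else:
            df["burn_in"] = pd.Series(dtype=bool)
        return df

    return RunResult(
        events_exchange=_ev({"hour": ex_h, "giver": ex_g, "receiver": ex_r,
                             "place_id": ex_p, "resource_id": ex_res}),
        events_dosing=_ev({"hour": do_h, "agent_id": do_a, "resource_id": do_r,
                           "source": np.array(do_s, dtype=object)}),
        events_use=_ev({"hour": us_h, "agent_id": us_a, "resource_id": us_r,
                        "place_id": us_p}),
        events_visit=_ev({"hour": vi_h, "agent_id": vi_a, "clinic_id": vi_c}),
        healtherx_log=pd.DataFrame(rx_log, columns=["rx_id", "agent_id", "clinic_id",
                                                    "hour", "mode", "n_items"]),
        healtherx_items=pd.DataFrame(rx_items_rows, columns=["rx_id", "rank", "resource_id"]),
        snapshots=snapshots,
        seed=config.seed,
        config=config,
        n_agents=n,
        work_fallbacks=work_fallbacks,
    )
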